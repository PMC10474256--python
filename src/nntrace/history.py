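"""Layer records, nomenclature and the queryable ModelHistory container.

Default layer names follow ``{layer_type}_{layer_type_num}_{layer_total_num}``
(e.g. ``relu_3_6`` is the third ReLU layer and sixth layer overall), with a
``:{pass}`` suffix for layers executed more than once.  Numbering follows
programmatic execution order, which topologically sorts feedforward edges.
Layers are additionally addressable by the module(s) whose returned tensor
they produce (``features.12``), at every nesting level for which that holds.
"""
from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable

import numpy as np

from .trace import OpRecord, TraceSession

#: canonical layer-type token per routine name
TYPE_ALIASES = {
    "true_divide": "divide",
    "absolute": "abs",
    "amax": "max",
    "amin": "min",
    "concat": "concatenate",
}

FLAG_NAMES = (
    "is_input", "is_output", "is_buffer", "is_internally_generated",
    "is_bool_terminal", "is_branch_start",
)


def layer_type_token(op_name: str) -> str:
    return TYPE_ALIASES.get(op_name, op_name).replace("_", "")


@dataclass
class LayerEntry:
    """Full metadata for one executed tensor operation (one graph node)."""

    rec_index: int
    op_name: str
    layer_type: str
    label: str = ""                # group label, e.g. cos_1_2
    layer_type_num: int = 0
    layer_total_num: int = 0
    pass_num: int = 1
    pass_count: int = 1
    same_layer_id: Any = None
    module_stack: list = field(default_factory=list)
    module_addresses: list = field(default_factory=list)
    shape: tuple = ()
    dtype: str = ""
    nbytes: int = 0
    param_shapes: list = field(default_factory=list)
    param_count: int = 0
    param_bytes: int = 0
    param_keys: tuple = ()
    duration: float = 0.0
    saved_activation: np.ndarray | None = None
    dist_from_input: int | None = None
    dist_to_output: int | None = None
    in_place: bool = False
    output_index: int | None = None
    is_input: bool = False
    is_output: bool = False
    is_buffer: bool = False
    is_internally_generated: bool = False
    is_bool_terminal: bool = False
    is_branch_start: bool = False
    _parents: list = field(default_factory=list)    # [(rec index, pos label)]
    _children: list = field(default_factory=list)
    _record: OpRecord | None = None
    _raw_stack: list = field(default_factory=list)
    _history: "ModelHistory | None" = None

    # -- user-facing convenience ---------------------------------------
    @property
    def label_w_pass(self) -> str:
        if self.pass_count > 1:
            return f"{self.label}:{self.pass_num}"
        return self.label

    @property
    def parents(self) -> list:
        h = self._history
        return [(h._by_rec[i].label_w_pass, pos) for i, pos in self._parents
                if i in h._by_rec]

    @property
    def children(self) -> list:
        h = self._history
        return [(h._by_rec[i].label_w_pass, pos) for i, pos in self._children
                if i in h._by_rec]

    @property
    def parent_layers(self) -> list["LayerEntry"]:
        h = self._history
        return [h._by_rec[i] for i, _ in self._parents if i in h._by_rec]

    @property
    def child_layers(self) -> list["LayerEntry"]:
        h = self._history
        return [h._by_rec[i] for i, _ in self._children if i in h._by_rec]

    @property
    def flags(self) -> dict:
        return {name: getattr(self, name) for name in FLAG_NAMES}

    def to_dict(self) -> dict:
        return {
            "label": self.label_w_pass,
            "layer_label": self.label,
            "layer_type": self.layer_type,
            "layer_type_num": self.layer_type_num,
            "layer_total_num": self.layer_total_num,
            "pass_num": self.pass_num,
            "pass_count": self.pass_count,
            "parents": [list(p) for p in self.parents],
            "children": [list(c) for c in self.children],
            "flags": {k: bool(v) for k, v in self.flags.items() if v},
            "in_place": bool(self.in_place),
            "module_stack": list(self.module_stack),
            "module_addresses": list(self.module_addresses),
            "tensor_shape": list(self.shape),
            "tensor_dtype": self.dtype,
            "tensor_fsize": int(self.nbytes),
            "param_shapes": [list(s) for s in self.param_shapes],
            "param_count": int(self.param_count),
            "param_fsize": int(self.param_bytes),
            "duration": float(self.duration),
            "dist_from_input": self.dist_from_input,
            "dist_to_output": self.dist_to_output,
            "has_saved_activation": self.saved_activation is not None,
        }

    def __repr__(self):
        return f"LayerEntry({self.label_w_pass or self.op_name})"


@dataclass
class RolledNode:
    """A layer collapsed across passes, with per-pass edge annotations."""

    label: str
    layer_type: str
    pass_count: int
    rec_indices: list
    incoming: dict = field(default_factory=dict)  # (src label, pos) -> [(src pass, dst pass)]
    outgoing: dict = field(default_factory=dict)  # (dst label, pos) -> [(src pass, dst pass)]

    def in_passes(self, src_label: str, pos: str) -> list:
        return sorted(dp for _, dp in self.incoming.get((src_label, pos), []))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "layer_type": self.layer_type,
            "pass_count": self.pass_count,
            "incoming": [
                {"source": src, "arg_pos": pos, "pass_pairs": sorted(pairs)}
                for (src, pos), pairs in sorted(self.incoming.items())],
            "outgoing": [
                {"target": dst, "arg_pos": pos, "pass_pairs": sorted(pairs)}
                for (dst, pos), pairs in sorted(self.outgoing.items())],
        }


class ModelHistory:
    """The complete, queryable record of one forward pass."""

    def __init__(self, model_name: str = "model"):
        self.model_name = model_name
        self.entries: list[LayerEntry] = []
        self.rolled_nodes: list[RolledNode] = []
        self.elapsed = 0.0
        self.n_operations = 0
        self.n_skipped_calls = 0
        self.tensor_fsize_total = 0
        self.total_param_count = 0
        self.total_param_fsize = 0
        self.module_call_counts: dict[str, int] = {}
        self.module_types: dict[str, str] = {}
        self._param_arrays: dict[str, np.ndarray] = {}
        self._by_rec: dict[int, LayerEntry] = {}
        self._lookup: dict[str, LayerEntry] = {}
        self._index_entries: list[LayerEntry] = []
        self._saved_subset = False

    # ------------------------------------------------------------------
    @classmethod
    def from_session(cls, session: TraceSession, model_name: str | None = None
                     ) -> "ModelHistory":
        h = cls(model_name or session.model_name)
        h.elapsed = session.elapsed
        h.n_skipped_calls = session.n_skipped
        h.module_call_counts = dict(session.module_call_counts)
        h.module_types = dict(session.module_types)
        h._param_arrays = dict(session.param_arrays)
        for rec in session.records:
            internal = rec.is_internal_origin or (
                rec.func is not None and not rec.tensor_parents
                and not rec.is_input and not rec.is_buffer)
            e = LayerEntry(
                rec_index=rec.index,
                op_name=rec.op_name,
                layer_type=layer_type_token(rec.op_name),
                shape=rec.shape, dtype=rec.dtype, nbytes=rec.nbytes,
                param_shapes=[s for _, s, _ in rec.param_refs],
                param_count=sum(n for _, _, n in rec.param_refs),
                param_bytes=sum(
                    n * session.param_arrays[k].itemsize
                    for k, _, n in rec.param_refs),
                param_keys=tuple(sorted(k for k, _, _ in rec.param_refs)),
                duration=rec.duration,
                saved_activation=rec.saved,
                in_place=rec.in_place,
                output_index=rec.output_index,
                is_input=rec.is_input, is_output=rec.is_output,
                is_buffer=rec.is_buffer, is_internally_generated=internal,
                _parents=list(rec.tensor_parents),
                _record=rec,
                _raw_stack=list(rec.module_stack),
                _history=h,
            )
            h.entries.append(e)
            h._by_rec[rec.index] = e
        h.rebuild_children()
        return h

    def rebuild_children(self) -> None:
        for e in self.entries:
            e._children = []
        for e in self.entries:
            for idx, pos in e._parents:
                parent = self._by_rec.get(idx)
                if parent is not None:
                    parent._children.append((e.rec_index, pos))

    # ------------------------------------------------------------------
    def finalize(self) -> None:
        """Build lookup tables and model-level totals."""
        self._lookup = {}
        for e in self.entries:
            self._lookup[e.label_w_pass] = e
            self._lookup.setdefault(e.label, e)
            self._lookup.setdefault(f"{e.layer_type}_{e.layer_type_num}", e)
        for e in self.entries:
            for addr in e.module_addresses:
                self._lookup.setdefault(addr, e)
                base = addr.split(":")[0]
                self._lookup.setdefault(base, e)
        ops = [e for e in self.entries if e._record is not None
               and e._record.func is not None and not e.is_output]
        self.n_operations = len(ops)
        self.tensor_fsize_total = sum(e.nbytes for e in ops)
        keys = sorted({k for e in self.entries for k in e.param_keys})
        self.total_param_count = sum(
            int(self._param_arrays[k].size) for k in keys)
        self.total_param_fsize = sum(
            int(self._param_arrays[k].nbytes) for k in keys)
        if self._saved_subset:
            self._index_entries = [e for e in self.entries
                                   if e.saved_activation is not None]
        else:
            self._index_entries = list(self.entries)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._index_entries)

    def __iter__(self) -> Iterable[LayerEntry]:
        return iter(self._index_entries)

    def __getitem__(self, key) -> LayerEntry:
        return resolve_layer_key(self, key)

    def __contains__(self, key) -> bool:
        try:
            resolve_layer_key(self, key)
            return True
        except (KeyError, IndexError):
            return False

    def __str__(self) -> str:
        return summarize_model(self)

    __repr__ = __str__

    # ------------------------------------------------------------------
    def layer_labels(self, with_passes: bool = True) -> list[str]:
        return [e.label_w_pass if with_passes else e.label
                for e in self.entries]

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "n_layers": len(self.entries),
            "n_operations": self.n_operations,
            "tensor_fsize_total": int(self.tensor_fsize_total),
            "total_param_count": int(self.total_param_count),
            "total_param_fsize": int(self.total_param_fsize),
            "elapsed": float(self.elapsed),
            "entries": [e.to_dict() for e in self.entries],
            "rolled_graph": [n.to_dict() for n in self.rolled_nodes],
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=kw.pop("indent", 1))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def save_activation_archive(self, directory) -> dict:
        """Write one .npy per saved layer plus a JSON manifest; returns it."""
        import os
        os.makedirs(directory, exist_ok=True)
        manifest = {}
        for e in self.entries:
            if e.saved_activation is None:
                continue
            fname = e.label_w_pass.replace(":", "+") + ".npy"
            np.save(os.path.join(directory, fname), e.saved_activation)
            manifest[e.label_w_pass] = {
                "file": fname, "shape": list(e.shape), "dtype": e.dtype,
                "fsize": int(e.nbytes)}
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        return manifest


# ----------------------------------------------------------------------
# nomenclature
# ----------------------------------------------------------------------

def _groups_in_execution_order(history: ModelHistory) -> list[list[LayerEntry]]:
    seen: dict[Any, list[LayerEntry]] = {}
    order: list[list[LayerEntry]] = []
    for e in history.entries:
        key = e.same_layer_id if e.same_layer_id is not None else ("solo", e.rec_index)
        if key not in seen:
            seen[key] = []
            order.append(seen[key])
        seen[key].append(e)
    return order


def assign_layer_labels(history: ModelHistory) -> ModelHistory:
    """Give every entry its default ``{type}_{type_num}_{total_num}`` label."""
    type_counts: dict[str, int] = {}
    for total_num, members in enumerate(_groups_in_execution_order(history), 1):
        ltype = members[0].layer_type
        type_counts[ltype] = type_counts.get(ltype, 0) + 1
        type_num = type_counts[ltype]
        label = f"{ltype}_{type_num}_{total_num}"
        for p, e in enumerate(sorted(members, key=lambda m: m.rec_index), 1):
            e.label = label
            e.layer_type_num = type_num
            e.layer_total_num = total_num
            e.pass_num = p
            e.pass_count = len(members)
            e.same_layer_id = label
    return history


def assign_module_addresses(history: ModelHistory) -> ModelHistory:
    """Finalize module stacks/addresses, pass-qualifying reused modules."""
    counts = history.module_call_counts

    def fmt(addr: str, ncall: int) -> str:
        return f"{addr}:{ncall}" if counts.get(addr, 1) > 1 else addr

    for e in history.entries:
        e.module_stack = [fmt(a, n) for a, n in e._raw_stack]
        if e._record is not None:
            e.module_addresses = [fmt(a, n)
                                  for a, n in e._record.module_output_addresses]
    return history


def resolve_layer_key(history: ModelHistory, key) -> LayerEntry:
    """Fetch a layer by label, truncated label, pass label, module address
    or integer ordinal (negative allowed)."""
    if isinstance(key, (int, np.integer)):
        try:
            return history._index_entries[key]
        except IndexError:
            raise IndexError(
                f"layer index {key} out of range for {len(history._index_entries)}"
                " indexable layers") from None
    if not isinstance(key, str):
        raise KeyError(f"unsupported layer key type: {type(key)!r}")
    entry = history._lookup.get(key)
    if entry is not None:
        return entry
    near = difflib.get_close_matches(key, list(history._lookup), n=3)
    hint = f"; near misses: {', '.join(near)}" if near else ""
    raise KeyError(f"no layer matching {key!r}{hint}")


def select_layers(history: ModelHistory,
                  predicate: Callable[[LayerEntry], bool]) -> list[LayerEntry]:
    """Entries satisfying ``predicate``, in execution order."""
    return [e for e in history.entries if predicate(e)]


def _human_bytes(n: float) -> str:
    for unit in ("B", "KB", "MB", "GB"):
        if abs(n) < 1024 or unit == "GB":
            return f"{n:.1f} {unit}" if unit != "B" else f"{int(n)} B"
        n /= 1024
    return f"{n:.1f} GB"


def summarize_model(history: ModelHistory) -> str:
    lines = [
        f"ModelHistory for {history.model_name}:",
        f"  layers: {len(history)}",
        f"  tensor operations: {history.n_operations} "
        f"({_human_bytes(history.tensor_fsize_total)} of computed tensors)",
        f"  trainable parameters: {history.total_param_count} "
        f"({_human_bytes(history.total_param_fsize)})",
        f"  forward pass time: {history.elapsed * 1000:.2f} ms",
    ]
    return "\n".join(lines)
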