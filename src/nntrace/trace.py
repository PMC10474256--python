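"""Transient instrumentation of the host tensor framework.

During a :class:`TraceSession`, every public tensor-returning callable in
the wrapped namespaces (numpy, numpy.linalg, numpy.random, and the
package's functional layer ops) is replaced by a logging wrapper.  The
wrapper records one :class:`OpRecord` per output tensor of each outermost
call, tags the produced tensors with barcodes so later calls can recover
their producers, and leaves every routine object untouched after teardown.

Only the outermost wrapped call is logged: composite routines implemented
in terms of other wrapped routines appear as a single user-facing node and
their wall-clock self-time is not double counted.
"""
from __future__ import annotations

import itertools
import time
import types
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

import numpy as np

from . import functional

TENSOR_TYPES = (np.ndarray, np.generic)

#: Marker attribute carried by installed wrappers (used by restoration sweeps).
WRAP_ATTR = "__nntrace_wrapped__"

# Routines that must never be wrapped: serialization, printing, RNG state
# management, error-state plumbing, and introspection helpers whose wrapping
# would either recurse into the logger or corrupt interpreter state.
DENYLIST: dict[str, set] = {
    "numpy": {
        "save", "savez", "savez_compressed", "savetxt", "load", "loadtxt",
        "genfromtxt", "fromfile", "frombuffer", "fromregex", "memmap",
        "array2string", "array_repr", "array_str", "base_repr", "binary_repr",
        "set_printoptions", "get_printoptions", "printoptions",
        "seterr", "geterr", "seterrcall", "geterrcall", "errstate",
        "show_config", "show_runtime", "info", "get_include",
        "getbufsize", "setbufsize", "typename", "mintypecode",
        "promote_types", "result_type", "min_scalar_type", "can_cast",
        "common_type", "issubdtype", "isdtype", "iterable", "isscalar",
        "shares_memory", "may_share_memory", "get_array_wrap",
        "add_docstring", "add_newdoc", "deprecate", "deprecate_with_doc",
        "safe_eval", "datetime_data", "frompyfunc", "copyto", "place", "put",
        "putmask", "fill_diagonal",
    },
    "numpy.linalg": set(),
    "numpy.random": {
        "seed", "get_state", "set_state", "default_rng", "set_bit_generator",
        "get_bit_generator", "shuffle",
    },
    "nntrace.functional": set(),
}


def _namespaces() -> list[tuple[str, types.ModuleType]]:
    return [
        ("numpy", np),
        ("numpy.linalg", np.linalg),
        ("numpy.random", np.random),
        ("nntrace.functional", functional),
    ]


def eligible_routines(ns_name: str, module: types.ModuleType) -> list[str]:
    """Names in ``module`` that the session will wrap."""
    deny = DENYLIST.get(ns_name, set())
    names = []
    for name in dir(module):
        if name.startswith("_") or name in deny:
            continue
        try:
            obj = getattr(module, name)
        except AttributeError:  # lazily-removed numpy aliases
            continue
        if not callable(obj) or isinstance(obj, type):
            continue
        if isinstance(obj, types.ModuleType):
            continue
        names.append(name)
    return names


@dataclass
class TensorTag:
    """Opaque barcode linking a live tensor to the record that produced it."""
    barcode: int
    producer: int  # index into TraceSession.records


@dataclass
class OpRecord:
    """One logged output tensor of one tensor operation."""
    index: int
    op_name: str
    func: Callable | None
    duration: float = 0.0
    arg_slots: tuple = ()
    kwarg_slots: dict = field(default_factory=dict)
    tensor_parents: list = field(default_factory=list)   # [(record index, pos label)]
    literal_args: tuple = ()                             # canonical (pos, repr)
    param_refs: list = field(default_factory=list)       # [(key, shape, numel)]
    output_index: int | None = None
    num_outputs: int = 1
    shape: tuple = ()
    dtype: str = ""
    nbytes: int = 0
    module_stack: list = field(default_factory=list)     # [(address, call number)]
    module_output_addresses: list = field(default_factory=list)
    rng_state: Any = None
    in_place: bool = False
    is_input: bool = False
    is_output: bool = False
    is_buffer: bool = False
    is_internal_origin: bool = False
    saved: np.ndarray | None = None


def _canon_literal(obj) -> str:
    """Canonical text form of a non-tensor argument (grouping signature)."""
    if isinstance(obj, float):
        return repr(float(obj))
    if isinstance(obj, (list, tuple)):
        inner = ",".join(_canon_literal(o) for o in obj)
        return f"({inner})" if isinstance(obj, tuple) else f"[{inner}]"
    if isinstance(obj, np.dtype):
        return f"dtype:{obj}"
    return repr(obj)


class TraceError(RuntimeError):
    pass


def _output_identity(x):
    """The 'function' of an output entry: passes its tensor through."""
    return np.asarray(x)


_ACTIVE: "TraceSession | None" = None


class TraceSession:
    """State for one instrumented forward pass."""

    def __init__(self, save_activations: bool = True):
        self.save_activations = save_activations
        self.records: list[OpRecord] = []
        self.tags: dict[int, TensorTag] = {}
        self._pin: list = []                 # strong refs keep id()s unique
        self.params: dict[int, str] = {}
        self.param_arrays: dict[str, np.ndarray] = {}
        self.buffers: dict[int, str] = {}
        self._buffer_records: dict[int, int] = {}
        self.module_stack: list[tuple[str, int]] = []
        self.module_call_counts: dict[str, int] = {}
        self.module_types: dict[str, str] = {}
        self.wrapped_registry: list[tuple[types.ModuleType, str, Callable]] = []
        self.hook_handles: list = []
        self.depth = 0
        self.suspended = False
        self.n_skipped = 0
        self.model_name = "model"
        self.elapsed = 0.0
        self._barcodes = itertools.count(1)

    # ------------------------------------------------------------------
    # registration of model state
    # ------------------------------------------------------------------
    def register_model(self, model) -> None:
        self.model_name = type(model).__name__
        for key, arr in model.named_parameters():
            self.params[id(arr)] = key
            self.param_arrays[key] = arr
            self._pin.append(arr)
        for key, arr in model.named_buffers():
            self.buffers[id(arr)] = key
            self._pin.append(arr)
        for addr, mod in model.named_modules():
            if addr:
                self.module_types[addr] = type(mod).__name__

    # ------------------------------------------------------------------
    # record construction
    # ------------------------------------------------------------------
    def _new_record(self, **kw) -> OpRecord:
        rec = OpRecord(index=len(self.records), **kw)
        self.records.append(rec)
        return rec

    def _tag(self, arr, rec_index: int) -> None:
        self.tags[id(arr)] = TensorTag(next(self._barcodes), rec_index)
        self._pin.append(arr)

    def _save(self, arr):
        return np.array(arr, copy=True) if self.save_activations else None

    def _origin_record(self, op_name: str, arr, **flags) -> int:
        rec = self._new_record(
            op_name=op_name, func=None,
            shape=tuple(np.shape(arr)), dtype=str(np.asarray(arr).dtype),
            nbytes=int(np.asarray(arr).nbytes),
            module_stack=list(self.module_stack),
            saved=self._save(arr),
            **flags,
        )
        self._tag(arr, rec.index)
        return rec.index

    def add_input(self, arr) -> int:
        if not isinstance(arr, TENSOR_TYPES):
            raise TraceError(f"model input must be an array, got {type(arr)!r}")
        return self._origin_record("input", arr, is_input=True)

    def add_output(self, arr) -> int:
        parents = []
        slot = self._slot(arr, "arg0", parents)
        rec = self._new_record(
            op_name="output", func=_output_identity,
            arg_slots=(slot,), tensor_parents=parents,
            shape=tuple(np.shape(arr)), dtype=str(np.asarray(arr).dtype),
            nbytes=int(np.asarray(arr).nbytes),
            saved=self._save(arr),
            is_output=True,
        )
        return rec.index

    # ------------------------------------------------------------------
    # argument walking
    # ------------------------------------------------------------------
    def _slot(self, obj, pos: str, parents: list, literals: list | None = None):
        if isinstance(obj, TENSOR_TYPES):
            oid = id(obj)
            if oid in self.params:
                return ("param", self.params[oid])
            if oid in self.buffers:
                idx = self._buffer_records.get(oid)
                if idx is None:
                    idx = self._origin_record("buffer", obj, is_buffer=True)
                    self._buffer_records[oid] = idx
                parents.append((idx, pos))
                return ("tensor", idx)
            if oid in self.tags:
                idx = self.tags[oid].producer
                parents.append((idx, pos))
                return ("tensor", idx)
            # Unknown array: constant generated inside the model.
            idx = self._origin_record("constant", obj, is_internal_origin=True)
            parents.append((idx, pos))
            return ("tensor", idx)
        if isinstance(obj, (list, tuple)) and any(
                isinstance(e, TENSOR_TYPES) for e in obj):
            slots = tuple(self._slot(e, f"{pos}[{j}]", parents, literals)
                          for j, e in enumerate(obj))
            return ("seq", type(obj).__name__, slots)
        if literals is not None:
            literals.append((pos, _canon_literal(obj)))
        return ("literal", obj)

    # ------------------------------------------------------------------
    # the logging path (called by wrappers for outermost calls only)
    # ------------------------------------------------------------------
    def log_call(self, op_name, func, args, kwargs, out, duration, rng_state):
        # Normalize scalar outputs to fresh 0-d arrays: numpy caches scalar
        # singletons, which would break barcode uniqueness.
        if isinstance(out, np.generic):
            out = np.asarray(out)
            outs: list[tuple[int | None, np.ndarray]] = [(None, out)]
        elif isinstance(out, np.ndarray):
            outs = [(None, out)]
        elif isinstance(out, (list, tuple)):
            conv = [np.asarray(o) if isinstance(o, np.generic) else o for o in out]
            out = type(out)(conv)
            outs = [(i, o) for i, o in enumerate(conv)
                    if isinstance(o, np.ndarray)]
        else:
            self.n_skipped += 1
            return out

        if not outs:
            self.n_skipped += 1
            return out

        parents: list[tuple[int, str]] = []
        literals: list[tuple[str, str]] = []
        arg_ids = set()

        def note_ids(obj):
            if isinstance(obj, TENSOR_TYPES):
                arg_ids.add(id(obj))
            elif isinstance(obj, (list, tuple)):
                for e in obj:
                    note_ids(e)

        for a in args:
            note_ids(a)
        for v in kwargs.values():
            note_ids(v)

        out_dest = kwargs.get("out")
        arg_slots = tuple(self._slot(a, f"arg{i}", parents, literals)
                          for i, a in enumerate(args))
        kwarg_slots = {}
        for k, v in kwargs.items():
            if k == "out" and isinstance(v, TENSOR_TYPES):
                # Destination buffer, not a data parent.
                kwarg_slots[k] = ("outdest",)
                continue
            kwarg_slots[k] = self._slot(v, k, parents, literals)

        param_refs = []
        seen_params = set()

        def collect_params(slot):
            if slot[0] == "param" and slot[1] not in seen_params:
                seen_params.add(slot[1])
                arr = self.param_arrays[slot[1]]
                param_refs.append((slot[1], tuple(arr.shape), int(arr.size)))
            elif slot[0] == "seq":
                for s in slot[2]:
                    collect_params(s)

        for s in arg_slots:
            collect_params(s)
        for s in kwarg_slots.values():
            collect_params(s)

        created = []
        n_real = len(outs)
        for out_idx, arr in outs:
            mutated = arr is out_dest or (
                out_dest is not None and isinstance(out_dest, (list, tuple))
                and any(arr is d for d in out_dest))
            if id(arr) in arg_ids and not mutated:
                # Pass-through (e.g. asarray on an already-tracked tensor).
                continue
            rec = self._new_record(
                op_name=op_name, func=func, duration=duration,
                arg_slots=arg_slots, kwarg_slots=kwarg_slots,
                tensor_parents=list(parents), literal_args=tuple(literals),
                param_refs=list(param_refs),
                output_index=out_idx, num_outputs=n_real,
                shape=tuple(arr.shape), dtype=str(arr.dtype),
                nbytes=int(arr.nbytes),
                module_stack=list(self.module_stack),
                rng_state=rng_state, in_place=bool(mutated),
                saved=self._save(arr),
            )
            created.append((arr, rec.index))

        if not created:
            self.n_skipped += 1
            return out
        for arr, idx in created:
            self._tag(arr, idx)  # in-place mutation re-tags with a fresh barcode
        return out

    # ------------------------------------------------------------------
    # module hooks
    # ------------------------------------------------------------------
    def module_enter(self, address: str) -> None:
        n = self.module_call_counts.get(address, 0) + 1
        self.module_call_counts[address] = n
        self.module_stack.append((address, n))

    def module_exit(self, address: str, output) -> None:
        if self.module_stack and self.module_stack[-1][0] == address:
            _, ncall = self.module_stack.pop()
        else:  # defensive: unbalanced hook firing
            ncall = self.module_call_counts.get(address, 1)
        for arr in _flatten_tensors(output):
            tag = self.tags.get(id(arr))
            if tag is not None:
                self.records[tag.producer].module_output_addresses.append(
                    (address, ncall))


def _flatten_tensors(obj) -> Iterable:
    if isinstance(obj, TENSOR_TYPES):
        yield obj
    elif isinstance(obj, (list, tuple)):
        for e in obj:
            yield from _flatten_tensors(e)


# ----------------------------------------------------------------------
# wrapping / restoration
# ----------------------------------------------------------------------

class _LoggingWrapper:
    """Callable stand-in for one framework routine during a session.

    Attribute access (e.g. ufunc methods like ``reduce``) is delegated to
    the original routine so framework internals keep working; such method
    calls bypass logging, which only matters inside nested calls that are
    suppressed anyway.
    """

    __slots__ = ("_op_name", "_func")

    def __init__(self, op_name: str, func: Callable):
        object.__setattr__(self, "_op_name", op_name)
        object.__setattr__(self, "_func", func)

    def __call__(self, *args, **kwargs):
        sess = _ACTIVE
        func = self._func
        if sess is None or sess.suspended:
            return func(*args, **kwargs)
        if sess.depth > 0:  # nested call inside another wrapped routine
            sess.depth += 1
            try:
                return func(*args, **kwargs)
            finally:
                sess.depth -= 1
        sess.suspended = True
        try:
            rng_state = np.random.get_state()
        finally:
            sess.suspended = False
        sess.depth += 1
        t0 = time.perf_counter()
        try:
            out = func(*args, **kwargs)
        finally:
            sess.depth -= 1
        duration = time.perf_counter() - t0
        sess.suspended = True
        try:
            out = sess.log_call(self._op_name, func, args, kwargs, out,
                                duration, rng_state)
        finally:
            sess.suspended = False
        return out

    def __getattr__(self, name):
        if name == WRAP_ATTR:
            return self._func
        return getattr(self._func, name)

    def __repr__(self):
        return f"<nntrace wrapper for {self._op_name}>"


def _make_wrapper(op_name: str, func: Callable) -> Callable:
    return _LoggingWrapper(op_name, func)


def wrap_framework_functions(session: TraceSession) -> int:
    """Install logging wrappers over every eligible routine; returns count."""
    if session.wrapped_registry:
        raise TraceError("session already has wrapped routines installed")
    cache: dict[int, Callable] = {}
    count = 0
    try:
        for ns_name, module in _namespaces():
            for name in eligible_routines(ns_name, module):
                orig = getattr(module, name)
                if hasattr(orig, WRAP_ATTR):  # alias of an already-wrapped routine
                    continue
                wrapper = cache.get(id(orig))
                if wrapper is None:
                    wrapper = _make_wrapper(name, orig)
                    cache[id(orig)] = wrapper
                    count += 1
                session.wrapped_registry.append((module, name, orig))
                setattr(module, name, wrapper)
    except Exception:
        restore_framework_functions(session)
        raise
    return count


def restore_framework_functions(session: TraceSession) -> None:
    """Return every wrapped routine to its original definition (idempotent)."""
    while session.wrapped_registry:
        module, name, orig = session.wrapped_registry.pop()
        setattr(module, name, orig)


def residual_wrapper_count() -> int:
    """Namespace sweep: number of attributes still bound to logging wrappers."""
    n = 0
    for ns_name, module in _namespaces():
        for name in dir(module):
            if name.startswith("_"):
                continue
            try:
                obj = getattr(module, name)
            except AttributeError:
                continue
            if hasattr(obj, WRAP_ATTR):
                n += 1
    return n


def attach_module_hooks(session: TraceSession, model) -> list:
    """Forward hooks that push/pop module addresses around each module call."""
    handles = []
    for address, mod in model.named_modules():
        if not address:
            continue

        def pre(module, args, _addr=address):
            if _ACTIVE is session:
                session.module_enter(_addr)

        def post(module, args, out, _addr=address):
            if _ACTIVE is session:
                session.module_exit(_addr, out)

        handles.append(mod.register_forward_pre_hook(pre))
        handles.append(mod.register_forward_hook(post))
    session.hook_handles = handles
    return handles


def remove_module_hooks(session: TraceSession) -> None:
    for h in session.hook_handles:
        h.remove()
    session.hook_handles = []


# ----------------------------------------------------------------------
# traced forward pass
# ----------------------------------------------------------------------

def run_traced_forward(model, inputs: Sequence[np.ndarray],
                       save_activations: bool = True):
    """Run one forward pass under full instrumentation.

    Returns ``(model_output, session)``.  The framework is guaranteed to be
    restored (and the session deactivated) even if the model raises.
    """
    global _ACTIVE
    if _ACTIVE is not None:
        raise TraceError("a trace session is already active")
    session = TraceSession(save_activations=save_activations)
    session.register_model(model)
    wrap_framework_functions(session)
    attach_module_hooks(session, model)
    _ACTIVE = session
    t0 = time.perf_counter()
    try:
        session.suspended = True
        for arr in inputs:
            session.add_input(arr)
        session.suspended = False
        out = model(*inputs)
        session.suspended = True
        for arr in _flatten_tensors(out):
            session.add_output(arr)
        session.suspended = False
    finally:
        _ACTIVE = None
        restore_framework_functions(session)
        remove_module_hooks(session)
    session.elapsed = time.perf_counter() - t0
    return out, session
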