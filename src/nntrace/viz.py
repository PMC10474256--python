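"""Graph visualization: DOT source for rolled/unrolled computational graphs.

Visual code: inputs green, outputs red, parameterized layers gray; ellipses
for free-standing ops, rectangles for ops that realize a bottom-level
module; dashed outlines for internally generated tensors; light gray for
buffers; yellow for the Boolean terminal of an if-test plus a bold IF mark
at the inferred branch start; argument-position labels on non-commutative
multi-parent edges; "In n"/"Out n" pass annotations on rolled edges that
differ across passes.  Modules nested deeper than ``nesting_depth`` are
collapsed into single nodes.

The DOT text is produced by the package's own serializer; rendering to an
image is attempted only if a ``dot`` executable is on PATH, otherwise the
source is still written and a warning is issued.
"""
from __future__ import annotations

import re
import shutil
import subprocess
import warnings
from dataclasses import dataclass
from typing import Optional

from .history import ModelHistory, _human_bytes

__all__ = ["VisOptions", "render_graph", "collapse_modules_at_depth"]

STYLE = {
    "input_fill": "#98fb98",        # pale green
    "output_fill": "#ff9999",       # light red
    "param_fill": "#c8c8c8",        # gray: op has trainable parameters
    "plain_fill": "#ffffff",
    "buffer_fill": "#f2f2f2",       # light gray buffers
    "buffer_font": "#666666",
    "bool_fill": "#ffff99",         # yellow boolean terminal
    "module_node_fill": "#dbe7f5",  # collapsed module
    "box_color": "#4477aa",
    "fontname": "Helvetica",
    "rankdir": "TB",
}

COMMUTATIVE = {
    "add", "multiply", "maximum", "minimum", "logaddexp", "hypot",
    "equal", "notequal", "logicaland", "logicalor", "logicalxor",
}


@dataclass
class VisOptions:
    nesting_depth: Optional[int] = None   # None = unlimited
    rolled: bool = False
    orientation: str = "TB"
    format: str = "dot"

    def __post_init__(self):
        if self.nesting_depth is not None and self.nesting_depth < 1:
            raise ValueError("nesting_depth must be >= 1 (or None for unlimited)")


def _fmt_passes(passes) -> str:
    ps = sorted(set(passes))
    if len(ps) > 1 and ps == list(range(ps[0], ps[-1] + 1)):
        return f"{ps[0]}-{ps[-1]}"
    return ",".join(str(p) for p in ps)


def _fmt_argpos(pos: str) -> str:
    m = re.match(r"arg(\d+)(.*)", pos)
    if m:
        return f"arg {m.group(1)}{m.group(2)}"
    return pos


# ----------------------------------------------------------------------
# module collapsing
# ----------------------------------------------------------------------

def collapse_modules_at_depth(history: ModelHistory, depth: Optional[int],
                              rolled: bool = False) -> dict:
    """View of the graph with modules deeper than ``depth`` collapsed.

    Returns ``{"nodes": {...}, "edges": {...}, "boxes": {...}}`` where each
    node is either a layer or a collapsed module, each edge maps to the set
    of underlying annotated edges, and boxes describe the visible module
    hierarchy (only multi-member modules get a surrounding box).
    """
    if rolled:
        units = []
        for node in history.rolled_nodes:
            first = history._by_rec[node.rec_indices[0]]
            units.append((node.label, first.module_stack, first, node))
    else:
        units = [(e.label_w_pass, e.module_stack, e, None)
                 for e in history.entries]

    nodes: dict = {}
    node_of: dict = {}
    for uid, stack, entry, rolled_node in units:
        if depth is not None and len(stack) >= depth:
            nid = stack[depth - 1]
            boxes = stack[:depth - 1]
            if nid not in nodes:
                nodes[nid] = {"kind": "module", "boxes": boxes,
                              "entries": [], "address": nid}
            nodes[nid]["entries"].append(entry)
        else:
            nid = uid
            nodes[nid] = {"kind": "layer", "boxes": list(stack),
                          "entry": entry, "rolled_node": rolled_node}
        node_of[uid] = nid

    edges: dict = {}
    if rolled:
        for node in history.rolled_nodes:
            dst = node_of[node.label]
            for (src_label, pos), pairs in node.incoming.items():
                src = node_of[src_label]
                if src == dst:
                    continue
                edges.setdefault((src, dst), []).append((src_label, node.label,
                                                         pos, pairs))
    else:
        for e in history.entries:
            dst = node_of[e.label_w_pass]
            for idx, pos in e._parents:
                p = history._by_rec.get(idx)
                if p is None:
                    continue
                src = node_of[p.label_w_pass]
                if src == dst:
                    continue
                edges.setdefault((src, dst), []).append(
                    (p.label_w_pass, e.label_w_pass, pos, None))

    # visible boxes: prefixes of node box-chains with >= 2 distinct members
    members: dict = {}
    for nid, node in nodes.items():
        for i, addr in enumerate(node["boxes"]):
            members.setdefault(addr, set()).add(nid)
    boxes = {}
    for nid, node in nodes.items():
        for i, addr in enumerate(node["boxes"]):
            if len(members[addr]) < 2:
                continue
            parent = None
            for up in reversed(node["boxes"][:i]):
                if len(members[up]) >= 2:
                    parent = up
                    break
            base = addr.split(":")[0]
            boxes[addr] = {"parent": parent,
                           "label": f"{addr} ({history.module_types.get(base, 'Module')})"}
    for node in nodes.values():
        node["boxes"] = [b for b in node["boxes"] if b in boxes]
    return {"nodes": nodes, "edges": edges, "boxes": boxes}


# ----------------------------------------------------------------------
# DOT serialization
# ----------------------------------------------------------------------

def _esc(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


class _Ids:
    def __init__(self):
        self.map: dict = {}
        self.used: set = set()

    def __call__(self, name: str) -> str:
        if name in self.map:
            return self.map[name]
        base = re.sub(r"[^0-9A-Za-z_]", "_", name) or "n"
        nid = base
        k = 1
        while nid in self.used:
            nid = f"{base}_{k}"
            k += 1
        self.used.add(nid)
        self.map[name] = nid
        return nid


def _layer_node_attrs(entry, rolled_node, history) -> dict:
    lines = []
    name = entry.label if rolled_node is not None else entry.label_w_pass
    if rolled_node is not None and rolled_node.pass_count > 1:
        name += f" (×{rolled_node.pass_count})"
    if entry.is_branch_start:
        lines.append("IF")
    lines.append(name)
    shape_txt = "×".join(str(s) for s in entry.shape) or "scalar"
    lines.append(f"{shape_txt} {entry.dtype} ({_human_bytes(entry.nbytes)})")
    if entry.param_shapes:
        ps = ", ".join(str(tuple(s)) for s in entry.param_shapes)
        lines.append(f"params: {ps}")
    if rolled_node is not None:
        addrs = sorted({a.split(":")[0]
                        for idx in rolled_node.rec_indices
                        for a in history._by_rec[idx].module_addresses})
    else:
        addrs = entry.module_addresses
    if addrs:
        lines.append("@ " + ", ".join(addrs))
    attrs = {
        "label": "\n".join(lines),
        "shape": "box" if entry.module_addresses else "oval",
        "style": "filled",
        "fillcolor": STYLE["plain_fill"],
        "fontname": STYLE["fontname"],
    }
    if entry.param_shapes:
        attrs["fillcolor"] = STYLE["param_fill"]
    if entry.is_input:
        attrs["fillcolor"] = STYLE["input_fill"]
    if entry.is_output:
        attrs["fillcolor"] = STYLE["output_fill"]
    if entry.is_buffer:
        attrs["fillcolor"] = STYLE["buffer_fill"]
        attrs["fontcolor"] = STYLE["buffer_font"]
    if entry.is_bool_terminal:
        attrs["fillcolor"] = STYLE["bool_fill"]
    if entry.is_internally_generated:
        attrs["style"] = "filled,dashed"
    if entry.is_branch_start:
        attrs["fontname"] = STYLE["fontname"] + "-Bold"
    return attrs


def _module_node_attrs(node, history) -> dict:
    addr = node["address"]
    base = addr.split(":")[0]
    cls = history.module_types.get(base, "Module")
    n = len(node["entries"])
    return {
        "label": f"{addr}\n{cls} ({n} ops)",
        "shape": "box3d",
        "style": "filled",
        "fillcolor": STYLE["module_node_fill"],
        "fontname": STYLE["fontname"],
    }


def _edge_label(history, details, rolled: bool) -> str:
    parts = []
    for src_label, dst_label, pos, pairs in details:
        seg = []
        dst_entry = history._lookup.get(dst_label.split(":")[0]) \
            if not rolled else None
        if rolled:
            src_node = next((n for n in history.rolled_nodes
                             if n.label == src_label), None)
            dst_node = next((n for n in history.rolled_nodes
                             if n.label == dst_label), None)
            if dst_node is not None and dst_node.pass_count > 1:
                in_passes = {dp for _, dp in pairs}
                if len(in_passes) < dst_node.pass_count:
                    seg.append(f"In {_fmt_passes(in_passes)}")
            if src_node is not None and src_node.pass_count > 1:
                out_passes = {sp for sp, _ in pairs}
                if len(out_passes) < src_node.pass_count:
                    seg.append(f"Out {_fmt_passes(out_passes)}")
            dst_entry = dst_node and history._by_rec[dst_node.rec_indices[0]]
        else:
            dst_entry = history._lookup.get(dst_label)
        if (dst_entry is not None and len(dst_entry._parents) >= 2
                and dst_entry.layer_type not in COMMUTATIVE):
            seg.append(_fmt_argpos(pos))
        if seg:
            parts.append(" ".join(seg))
    return "; ".join(dict.fromkeys(parts))


def render_graph(history: ModelHistory, options: VisOptions | None = None,
                 out_path=None) -> str:
    """Emit DOT source for the history's graph; optionally write/render it."""
    options = options or VisOptions()
    view = collapse_modules_at_depth(history, options.nesting_depth,
                                     rolled=options.rolled)
    ids = _Ids()
    lines = ["digraph model {"]
    header = (f"{history.model_name}\n"
              f"{history.n_operations} tensor operations "
              f"({_human_bytes(history.tensor_fsize_total)})\n"
              f"{history.total_param_count} params "
              f"({_human_bytes(history.total_param_fsize)})")
    lines.append(f'  label="{_esc(header)}"; labelloc=t; labeljust=l;')
    lines.append(f"  rankdir={options.orientation or STYLE['rankdir']};")
    lines.append(f'  node [fontname="{STYLE["fontname"]}"];')

    # group nodes by their innermost visible box
    by_box: dict = {}
    for nid, node in view["nodes"].items():
        inner = node["boxes"][-1] if node["boxes"] else None
        by_box.setdefault(inner, []).append((nid, node))

    def node_stmt(nid, node, indent):
        if node["kind"] == "module":
            attrs = _module_node_attrs(node, history)
        else:
            attrs = _layer_node_attrs(node["entry"], node.get("rolled_node"),
                                      history)
        attr_txt = ", ".join(f'{k}="{_esc(str(v))}"' for k, v in attrs.items())
        return f'{indent}{ids(nid)} [{attr_txt}];'

    children: dict = {}
    roots = []
    for addr, box in view["boxes"].items():
        if box["parent"] is None:
            roots.append(addr)
        else:
            children.setdefault(box["parent"], []).append(addr)

    def emit_box(addr, indent):
        box = view["boxes"][addr]
        lines.append(f"{indent}subgraph cluster_{ids('box_' + addr)} {{")
        lines.append(f'{indent}  label="{_esc(box["label"])}"; '
                     f'color="{STYLE["box_color"]}"; style=rounded;')
        for nid, node in by_box.get(addr, []):
            lines.append(node_stmt(nid, node, indent + "  "))
        for sub in children.get(addr, []):
            emit_box(sub, indent + "  ")
        lines.append(f"{indent}}}")

    for nid, node in by_box.get(None, []):
        lines.append(node_stmt(nid, node, "  "))
    for addr in roots:
        emit_box(addr, "  ")

    for (src, dst), details in view["edges"].items():
        label = _edge_label(history, details, options.rolled)
        attr = f' [label="{_esc(label)}"]' if label else ""
        lines.append(f"  {ids(src)} -> {ids(dst)}{attr};")
    lines.append("}")
    source = "\n".join(lines) + "\n"

    if out_path is not None:
        dot_path = str(out_path)
        if not dot_path.endswith(".dot") and options.format == "dot":
            dot_path += ".dot"
        if options.format == "dot":
            with open(dot_path, "w") as fh:
                fh.write(source)
        else:
            dot_exe = shutil.which("dot")
            if dot_exe is None:
                warnings.warn(
                    "no graphviz 'dot' executable found; writing DOT source "
                    "only", RuntimeWarning, stacklevel=2)
                with open(dot_path + ".dot" if not dot_path.endswith(".dot")
                          else dot_path, "w") as fh:
                    fh.write(source)
            else:
                proc = subprocess.run(
                    [dot_exe, f"-T{options.format}", "-o", dot_path],
                    input=source.encode(), capture_output=True)
                if proc.returncode != 0:
                    warnings.warn(
                        f"dot rendering failed: {proc.stderr.decode()[:200]}",
                        RuntimeWarning, stacklevel=2)
    return source
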