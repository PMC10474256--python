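"""Post-processing of the raw operation log into the final annotated graph.

Applied in order: orphan trimming, input/output distances, conditional-branch
inference, module-containment repair for internally generated tensors,
recurrent-layer identification, and rolling of multi-pass layers.

Recurrence follows three conventions: (1) operations applying the same
trainable parameters more than once are always passes of one layer; (2)
identical operations adjacent to different passes of such a layer are merged
recursively; (3) parameter-free operation sequences that repeat back-to-back
(XYZXYZXYZ) form a loop, but separated repetitions (XYZAXYZBXYZ) do not.
"""
from __future__ import annotations

from collections import deque
from typing import Iterable

import numpy as np

from .history import LayerEntry, ModelHistory, RolledNode

__all__ = [
    "trim_orphans", "compute_graph_distances", "infer_conditional_branches",
    "fix_internal_module_containment", "identify_repeated_layers", "roll_graph",
    "descends_from_input", "reaches_output",
]


# ----------------------------------------------------------------------
# reachability helpers (hand-rolled BFS; tests cross-check with networkx)
# ----------------------------------------------------------------------

def _bfs(history: ModelHistory, seeds: Iterable[int], direction: str) -> dict:
    """Edge-count distances from ``seeds`` following children ('down') or
    parents ('up')."""
    dist = {idx: 0 for idx in seeds}
    queue = deque(dist)
    while queue:
        idx = queue.popleft()
        entry = history._by_rec.get(idx)
        if entry is None:
            continue
        nbrs = entry._children if direction == "down" else entry._parents
        for nxt, _ in nbrs:
            if nxt not in dist and nxt in history._by_rec:
                dist[nxt] = dist[idx] + 1
                queue.append(nxt)
    return dist


def descends_from_input(history: ModelHistory) -> dict:
    seeds = [e.rec_index for e in history.entries if e.is_input]
    return _bfs(history, seeds, "down")


def reaches_output(history: ModelHistory) -> dict:
    seeds = [e.rec_index for e in history.entries if e.is_output]
    return _bfs(history, seeds, "up")


# ----------------------------------------------------------------------
# 1. orphan trimming
# ----------------------------------------------------------------------

def trim_orphans(history: ModelHistory) -> ModelHistory:
    """Remove entries that neither descend from any input nor reach any
    output.  Dead ends that do descend from the input are kept — they may
    be conditional tests."""
    down = descends_from_input(history)
    up = reaches_output(history)
    keep = [e for e in history.entries
            if e.rec_index in down or e.rec_index in up]
    removed = {e.rec_index for e in history.entries} - {e.rec_index for e in keep}
    history.entries = keep
    history._by_rec = {e.rec_index: e for e in keep}
    for e in keep:  # prune dangling references
        e._parents = [(i, p) for i, p in e._parents if i not in removed]
    history.rebuild_children()
    return history


# ----------------------------------------------------------------------
# 2. graph distances
# ----------------------------------------------------------------------

def compute_graph_distances(history: ModelHistory) -> ModelHistory:
    down = descends_from_input(history)
    up = reaches_output(history)
    for e in history.entries:
        e.dist_from_input = down.get(e.rec_index)
        e.dist_to_output = up.get(e.rec_index)
    return history


# ----------------------------------------------------------------------
# 3. conditional-branch inference
# ----------------------------------------------------------------------

def infer_conditional_branches(history: ModelHistory) -> ModelHistory:
    """Flag childless single-element Boolean entries as if-test terminals and
    mark, walking their ancestry backwards, the first ancestor that also
    leads to the model output as the start of the if branch."""
    up = reaches_output(history)
    for e in history.entries:
        if e._children or not e.dtype.startswith("bool"):
            continue
        if int(np.prod(e.shape, dtype=np.int64)) != 1:
            continue
        e.is_bool_terminal = True
        frontier = [i for i, _ in e._parents]
        seen = set(frontier)
        while frontier:
            hits = sorted(i for i in frontier if i in up)
            if hits:
                history._by_rec[hits[0]].is_branch_start = True
                break
            nxt = []
            for idx in frontier:
                parent = history._by_rec.get(idx)
                if parent is None:
                    continue
                for i, _ in parent._parents:
                    if i not in seen:
                        seen.add(i)
                        nxt.append(i)
            frontier = nxt
    return history


# ----------------------------------------------------------------------
# 4. module containment repair for internally generated tensors
# ----------------------------------------------------------------------

def fix_internal_module_containment(history: ModelHistory) -> ModelHistory:
    """Give tensors not descended from the model input the module stack of
    their nearest input-descended descendant (found by forward search)."""
    down = descends_from_input(history)
    for e in history.entries:
        if e.rec_index in down or e.is_input or e.is_buffer or e.is_output:
            continue
        frontier = [i for i, _ in e._children]
        seen = set(frontier)
        while frontier:
            hits = sorted(i for i in frontier if i in down)
            if hits:
                e._raw_stack = list(history._by_rec[hits[0]]._raw_stack)
                break
            nxt = []
            for idx in frontier:
                child = history._by_rec.get(idx)
                if child is None:
                    continue
                for i, _ in child._children:
                    if i not in seen:
                        seen.add(i)
                        nxt.append(i)
            frontier = nxt
        # no input-descended descendant: leave the stack as recorded
    return history


# ----------------------------------------------------------------------
# 5. recurrent-layer identification
# ----------------------------------------------------------------------

def _signature(e: LayerEntry) -> tuple:
    """Op identity used for grouping: routine name, parameter identity,
    canonicalized non-tensor arguments, and (for tuple-returning ops) the
    output position, so sibling outputs of one call never count as
    repetitions of each other."""
    return (e.op_name, e.param_keys, tuple(sorted(e._record.literal_args)),
            e.output_index)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if rb < ra:
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True

    def groups(self) -> dict:
        out: dict = {}
        for i in self.parent:
            out.setdefault(self.find(i), []).append(i)
        for members in out.values():
            members.sort()
        return out


def identify_repeated_layers(history: ModelHistory) -> ModelHistory:
    ops = [e for e in history.entries
           if e._record is not None and e._record.func is not None
           and not e.is_output]
    uf = _UnionFind([e.rec_index for e in ops])
    by_rec = {e.rec_index: e for e in ops}
    sig = {e.rec_index: _signature(e) for e in ops}

    # Condition 1: shared trainable parameters are always one layer.
    buckets: dict = {}
    for e in ops:
        if e.param_keys:
            buckets.setdefault((e.op_name, e.param_keys), []).append(e.rec_index)
    for members in buckets.values():
        for i in members[1:]:
            uf.union(members[0], i)

    # Condition 2: identical ops adjacent to different passes of a grouped
    # layer are merged, recursively to fixpoint.
    changed = True
    while changed:
        changed = False
        for members in list(uf.groups().values()):
            if len(members) < 2:
                continue
            for direction in ("up", "down"):
                nb_buckets: dict = {}
                for m in members:
                    entry = by_rec.get(m)
                    if entry is None:
                        continue
                    edges = entry._parents if direction == "up" else entry._children
                    for idx, _ in edges:
                        if idx in by_rec:
                            nb_buckets.setdefault(sig[idx], {}) \
                                .setdefault(m, set()).add(idx)
                for per_member in nb_buckets.values():
                    if len(per_member) < 2:
                        continue
                    all_nb = sorted(set().union(*per_member.values()))
                    for i in all_nb[1:]:
                        if uf.union(all_nb[0], i):
                            changed = True

    # Condition 3: back-to-back repeating parameter-free blocks.  Blocks are
    # grown greedily in execution order; earliest start wins, then largest
    # coverage, then the shortest period (most passes).
    seq = list(ops)
    sizes = {root: len(m) for root, m in uf.groups().items()}

    def free(e: LayerEntry) -> bool:
        return not e.param_keys and sizes[uf.find(e.rec_index)] == 1

    sigs = [sig[e.rec_index] for e in seq]
    i = 0
    n = len(seq)
    while i < n:
        best = None
        for period in range(1, (n - i) // 2 + 1):
            reps = 1
            while (i + (reps + 1) * period <= n
                   and sigs[i:i + period] == sigs[i + reps * period:
                                                  i + (reps + 1) * period]):
                reps += 1
            if reps < 2:
                continue
            block = seq[i:i + period * reps]
            if not all(free(e) for e in block):
                continue
            cand = (period * reps, -period, period, reps)
            if best is None or cand > best:
                best = cand
        if best is None:
            i += 1
            continue
        _, _, period, reps = best
        for j in range(period):
            anchor = seq[i + j].rec_index
            for r in range(1, reps):
                uf.union(anchor, seq[i + r * period + j].rec_index)
        i += period * reps

    # Materialize group ids and pass numbers (labels assigned later).
    for root, members in uf.groups().items():
        for p, idx in enumerate(members, 1):
            e = by_rec[idx]
            e.same_layer_id = ("group", root)
            e.pass_num = p
            e.pass_count = len(members)
    return history


# ----------------------------------------------------------------------
# 6. rolled graph
# ----------------------------------------------------------------------

def roll_graph(history: ModelHistory) -> list[RolledNode]:
    """One node per layer; edges annotated with the passes they serve.
    Requires labels to be assigned."""
    nodes: dict[str, RolledNode] = {}
    for e in history.entries:
        node = nodes.get(e.label)
        if node is None:
            node = RolledNode(label=e.label, layer_type=e.layer_type,
                              pass_count=e.pass_count, rec_indices=[])
            nodes[e.label] = node
        node.rec_indices.append(e.rec_index)
    for e in history.entries:
        for idx, pos in e._parents:
            src = history._by_rec.get(idx)
            if src is None:
                continue
            pair = (src.pass_num, e.pass_num)
            nodes[e.label].incoming.setdefault((src.label, pos), []).append(pair)
            nodes[src.label].outgoing.setdefault((e.label, pos), []).append(pair)
    history.rolled_nodes = list(nodes.values())
    return history.rolled_nodes
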