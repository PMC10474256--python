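"""Graph post-processing, cross-checked against networkx oracles."""
import networkx as nx
import numpy as np
import pytest

import nntrace
from nntrace import nn
from nntrace.graph import descends_from_input, reaches_output
from nntrace.history import ModelHistory
from nntrace.trace import run_traced_forward


def as_digraph(history) -> nx.DiGraph:
    g = nx.DiGraph()
    for e in history.entries:
        g.add_node(e.rec_index)
        for idx, _ in e._parents:
            g.add_edge(idx, e.rec_index)
    return g


def test_feedforward_chain_trims_nothing(traced):
    history, spec = traced("feedforward")
    assert len(history.entries) == len(spec.ground_truth["entries"])


def test_discarded_internal_chain_is_trimmed():
    model, x, _ = nntrace.make_fixture("orphan", seed=1)
    _, session = run_traced_forward(model, (x,))
    raw = ModelHistory.from_session(session)
    raw_ops = [e.op_name for e in raw.entries]
    assert "rand" in raw_ops and "tanh" in raw_ops  # present before trimming
    history = nntrace.log_forward_pass(model, x, seed=1)
    final_ops = [e.op_name for e in history.entries]
    assert "rand" not in final_ops and "tanh" not in final_ops


@pytest.mark.parametrize("name", ["cond_branch", "orphan", "internal_random",
                                  "nested_blocks"])
def test_every_survivor_descends_from_input_or_reaches_output(traced, name):
    history, _ = traced(name)
    g = as_digraph(history)
    inputs = [e.rec_index for e in history.entries if e.is_input]
    outputs = [e.rec_index for e in history.entries if e.is_output]
    from_input = set().union(*(nx.descendants(g, i) | {i} for i in inputs))
    to_output = set().union(*(nx.ancestors(g, o) | {o} for o in outputs))
    for e in history.entries:
        assert e.rec_index in from_input or e.rec_index in to_output


@pytest.mark.parametrize("name", ["branch_divide", "cond_branch",
                                  "nested_blocks", "fig4a"])
def test_distances_match_networkx_shortest_paths(traced, name):
    history, _ = traced(name)
    g = as_digraph(history)
    inputs = [e.rec_index for e in history.entries if e.is_input]
    outputs = [e.rec_index for e in history.entries if e.is_output]
    for e in history.entries:
        want_in = min((nx.shortest_path_length(g, i, e.rec_index)
                       for i in inputs
                       if nx.has_path(g, i, e.rec_index)), default=None)
        want_out = min((nx.shortest_path_length(g, e.rec_index, o)
                        for o in outputs
                        if nx.has_path(g, e.rec_index, o)), default=None)
        assert e.dist_from_input == want_in
        assert e.dist_to_output == want_out


def test_input_and_output_distances_are_zero(traced):
    history, _ = traced("feedforward")
    assert history["input_1_1"].dist_from_input == 0
    assert history[-1].dist_to_output == 0
    assert history["cos_1_2" if "cos_1_2" in history else "linear_1_2"]


def test_fig4a_first_cos_pass_is_one_step_from_input(traced):
    history, _ = traced("fig4a")
    assert history["cos_1_2:1"].dist_from_input == 1


def test_shortest_path_property_along_every_edge(traced):
    for name in ("fig4a", "nested_blocks", "cond_branch"):
        history, _ = traced(name)
        for e in history.entries:
            for idx, _ in e._parents:
                parent = history._by_rec[idx]
                if parent.dist_from_input is not None:
                    assert e.dist_from_input <= parent.dist_from_input + 1


def test_if_branch_flags_and_ancestry(traced):
    history, _ = traced("cond_branch")
    greater = history["greater_1_4"]
    sub = history["subtract_1_2"]
    assert greater.is_bool_terminal and not greater._children
    assert sub.is_branch_start
    g = as_digraph(history)
    out = next(e.rec_index for e in history.entries if e.is_output)
    # the branch start is an ancestor of both the bool terminal and the output
    assert nx.has_path(g, sub.rec_index, greater.rec_index)
    assert nx.has_path(g, sub.rec_index, out)
    # no other entry is flagged
    assert [e.label for e in history.entries if e.is_bool_terminal] == ["greater_1_4"]
    assert [e.label for e in history.entries if e.is_branch_start] == ["subtract_1_2"]


def test_feedforward_model_has_no_branch_flags(traced):
    history, _ = traced("feedforward")
    assert not any(e.is_bool_terminal or e.is_branch_start
                   for e in history.entries)


class NoiseConsumer(nn.Module):
    def forward(self, x, noise):
        return np.add(x, noise)


class RootNoise(nn.Module):
    """Noise created at the root but consumed inside a submodule, so the
    creation entry's recorded containment must be repaired."""

    def __init__(self):
        super().__init__()
        self.mixer = NoiseConsumer()

    def forward(self, x):
        n = np.random.rand(*x.shape)
        return self.mixer(x, n)


def test_internal_tensor_inherits_consumer_module_stack():
    model = RootNoise()
    x = np.ones((1, 4), dtype=np.float32)
    np.random.seed(0)
    history = nntrace.log_forward_pass(model, x)
    rand = next(e for e in history.entries if e.layer_type == "rand")
    add = next(e for e in history.entries if e.layer_type == "add")
    assert add.module_stack == ["mixer"]
    assert rand.module_stack == ["mixer"]  # propagated backwards
    # brute-force oracle: nearest input-descended descendant's stack
    g = as_digraph(history)
    down = descends_from_input(history)
    dists = nx.single_source_shortest_path_length(g, rand.rec_index)
    best = min((d, i) for i, d in dists.items() if i in down and i != rand.rec_index)
    assert history._by_rec[best[1]].module_stack == rand.module_stack


def test_model_without_internal_tensors_keeps_stacks(traced):
    history, _ = traced("feedforward")
    assert all(e._raw_stack == e._record.module_stack
               for e in history.entries if e._record.func is not None)


def test_xyz_repeating_loop_groups_three_layers_of_three_passes(traced):
    history, _ = traced("xyz_loop")
    groups = {}
    for e in history.entries:
        groups.setdefault(e.label, set()).add(e.pass_num)
    assert groups["cos_1_2"] == {1, 2, 3}
    assert groups["sin_1_3"] == {1, 2, 3}
    assert groups["tanh_1_4"] == {1, 2, 3}


def test_separated_xyz_occurrences_are_not_grouped(traced):
    history, _ = traced("xyz_interrupted")
    assert all(e.pass_count == 1 for e in history.entries)
    assert len({e.label for e in history.entries}) == len(history.entries)


def test_all_distinct_ops_give_singleton_groups(traced):
    history, _ = traced("branch_divide")
    assert all(e.pass_count == 1 for e in history.entries)


@pytest.mark.parametrize("name", ["fig4a", "fig4b", "xyz_loop", "alexnet"])
def test_grouping_conserves_entry_count(traced, name):
    history, _ = traced(name, seed=0 if name == "alexnet" else 1)
    per_group = {}
    for e in history.entries:
        per_group[e.label] = e.pass_count
    assert sum(per_group.values()) == len(history.entries)


@pytest.mark.parametrize("name", ["fig4a", "fig4b", "xyz_loop", "nested_blocks"])
def test_rolled_edges_expand_to_exact_unrolled_adjacency(traced, name):
    history, _ = traced(name)
    unrolled = {(history._by_rec[i].label_w_pass, e.label_w_pass, pos)
                for e in history.entries for i, pos in e._parents}
    expanded = set()
    pass_counts = {n.label: n.pass_count for n in history.rolled_nodes}

    def qualify(label, p):
        return f"{label}:{p}" if pass_counts[label] > 1 else label

    for node in history.rolled_nodes:
        for (src, pos), pairs in node.incoming.items():
            for sp, dp in pairs:
                expanded.add((qualify(src, sp), qualify(node.label, dp), pos))
    assert expanded == unrolled


def test_fig4a_rolled_cos_inputs_differ_across_passes(traced):
    history, _ = traced("fig4a")
    cos = next(n for n in history.rolled_nodes if n.label == "cos_1_2")
    assert cos.in_passes("input_1_1", "arg0") == [1]
    assert cos.in_passes("sin_1_5", "arg0") == [2]


def test_feedforward_rolled_graph_isomorphic_to_unrolled(traced):
    history, _ = traced("feedforward")
    assert len(history.rolled_nodes) == len(history.entries)
    assert all(n.pass_count == 1 for n in history.rolled_nodes)


@pytest.mark.parametrize("name", ["fig4a", "fig4b", "nested_blocks",
                                  "cond_branch", "xyz_loop"])
def test_unrolled_graph_is_acyclic(traced, name):
    history, _ = traced(name)
    assert nx.is_directed_acyclic_graph(as_digraph(history))


def test_execution_order_increases_along_every_edge(traced):
    for name in ("fig4a", "xyz_loop", "nested_blocks"):
        history, _ = traced(name)
        order = {e.rec_index: i for i, e in enumerate(history.entries)}
        for e in history.entries:
            for idx, _ in e._parents:
                assert order[idx] < order[e.rec_index]


def test_layer_numbers_increase_along_edges_of_feedforward_models(traced):
    for name in ("feedforward", "nested_blocks", "branch_divide"):
        history, _ = traced(name)
        for e in history.entries:
            for parent in e.parent_layers:
                assert parent.layer_total_num < e.layer_total_num
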