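"""DOT rendering: visual code, module collapsing, syntactic validity."""
import re

import pytest

import nntrace
from nntrace.viz import VisOptions, collapse_modules_at_depth, render_graph

# ----------------------------------------------------------------------
# independent miniature DOT checker (graphviz bindings are not assumed)
# ----------------------------------------------------------------------

_STMT = re.compile(
    r"""^\s*(?:
        digraph\s+\w+\s*\{ |
        subgraph\s+cluster_\w+\s*\{ |
        \} |
        \w+\s*\[.*\]; |
        \w+\s*->\s*\w+(?:\s*\[.*\])?; |
        (?:label|labelloc|labeljust|rankdir|color|style|node)\s*=?[^;]*;?
    )\s*$""", re.VERBOSE)


def assert_valid_dot(source: str) -> None:
    depth = 0
    assert source.startswith("digraph")
    for raw in source.strip().splitlines():
        line = raw.strip()
        if not line:
            continue
        # statements may carry multiple ';'-separated attribute settings
        assert _STMT.match(line) or all(
            _STMT.match(part.strip() + ";") for part in line.split(";") if part.strip()), \
            f"unparsable DOT statement: {line!r}"
        depth += line.count("{") - line.count("}")
        assert depth >= 0
    assert depth == 0
    # edges reference declared nodes
    declared = set(re.findall(r"^\s*(\w+)\s*\[", source, re.M))
    for src, dst in re.findall(r"^\s*(\w+)\s*->\s*(\w+)", source, re.M):
        assert src in declared and dst in declared


@pytest.mark.parametrize("name", ["feedforward", "fig4a", "cond_branch",
                                  "nested_blocks", "internal_random"])
@pytest.mark.parametrize("rolled", [False, True])
def test_emitted_dot_is_syntactically_valid(traced, name, rolled):
    history, _ = traced(name)
    assert_valid_dot(render_graph(history, VisOptions(rolled=rolled)))


def test_visual_code_for_inputs_outputs_and_internal_tensors(traced):
    history, _ = traced("internal_random")
    src = render_graph(history)
    input_line = next(l for l in src.splitlines() if l.strip().startswith("input_1_1 ["))
    output_line = next(l for l in src.splitlines() if l.strip().startswith("output_1_4 ["))
    rand_line = next(l for l in src.splitlines() if l.strip().startswith("rand_1_2 ["))
    assert "#98fb98" in input_line          # green input
    assert "#ff9999" in output_line         # red output
    assert "dashed" in rand_line            # internally generated


def test_visual_code_for_params_buffers_and_if_branches(traced):
    history, _ = traced("buffer")
    src = render_graph(history)
    assert "#f2f2f2" in src                 # light gray buffer node
    history, _ = traced("cond_branch")
    src = render_graph(history)
    greater = next(l for l in src.splitlines() if "greater_1_4 [" in l)
    sub = next(l for l in src.splitlines() if "subtract_1_2 [" in l)
    assert "#ffff99" in greater             # yellow boolean terminal
    assert "IF" in sub and "Bold" in sub    # bold IF at the branch start
    history, _ = traced("feedforward")
    src = render_graph(history)
    fc = next(l for l in src.splitlines() if "linear_1_2 [" in l)
    assert "#c8c8c8" in fc                  # gray parameterized layer
    assert "params: (10, 10)" in fc


def test_rolled_fig4a_marks_pass_count_and_pass_edges(traced):
    history, _ = traced("fig4a")
    src = render_graph(history, VisOptions(rolled=True))
    assert "linear_1_3 (×2)" in src
    assert 'label="In 1"' in src and 'label="In 2"' in src
    assert 'label="Out 1"' in src and 'label="Out 2"' in src
    # edges identical across passes carry no pass annotation
    cos_to_lin = next(l for l in src.splitlines() if "cos_1_2 -> linear_1_3" in l)
    assert "In" not in cos_to_lin and "Out" not in cos_to_lin


def test_argument_positions_marked_only_for_noncommutative_ops(traced):
    history, _ = traced("branch_divide")
    src = render_graph(history)
    assert 'label="arg 0"' in src and 'label="arg 1"' in src
    history, _ = traced("internal_random")  # add is commutative
    src = render_graph(history)
    assert "arg 0" not in src and "arg 1" not in src


def test_feedforward_node_count_equals_entry_count(traced):
    history, _ = traced("feedforward")
    view = collapse_modules_at_depth(history, None)
    assert len(view["nodes"]) == len(history.entries)


def test_nested_blocks_collapse_to_one_node_per_block_at_depth_1(traced):
    history, _ = traced("nested_blocks")
    view = collapse_modules_at_depth(history, 1)
    module_nodes = {n for n, d in view["nodes"].items() if d["kind"] == "module"}
    assert module_nodes == {"block1", "block2"}
    assert len(view["nodes"]) == 4  # input, block1, block2, output


def test_collapsing_node_count_is_monotone_in_depth(traced):
    history, _ = traced("nested_blocks")
    counts = [len(collapse_modules_at_depth(history, d)["nodes"])
              for d in (1, 2, 3, 4)]
    counts.append(len(collapse_modules_at_depth(history, None)["nodes"]))
    assert counts == sorted(counts)
    assert counts[-1] == len(history.entries)


def test_rolled_and_unrolled_cover_the_same_layer_groups(traced):
    history, _ = traced("fig4b")
    unrolled_groups = {e.label for e in history.entries}
    rolled_groups = {n.label for n in history.rolled_nodes}
    assert unrolled_groups == rolled_groups


def test_graph_header_carries_model_totals(traced):
    history, _ = traced("feedforward")
    src = render_graph(history)
    assert "FeedForward" in src
    assert f"{history.n_operations} tensor operations" in src
    assert f"{history.total_param_count} params" in src


def test_module_boxes_are_emitted_as_clusters(traced):
    history, _ = traced("alexnet", seed=0)
    src = render_graph(history)
    assert "subgraph cluster_" in src
    assert "features (Sequential)" in src
    assert "classifier (Sequential)" in src
    assert_valid_dot(src)


def test_show_model_graph_writes_nonempty_file(tmp_path):
    model, x, _ = nntrace.make_fixture("feedforward", seed=1)
    out = tmp_path / "g.dot"
    src = nntrace.show_model_graph(model, x, out_path=str(out), seed=1)
    assert out.exists() and out.stat().st_size > 0
    assert out.read_text() == src
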