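"""Tracing core: wrapping, logging, barcodes, module hooks, restoration."""
import types

import numpy as np
import pytest

import nntrace
from nntrace import nn
from nntrace.trace import (DENYLIST, TraceSession, WRAP_ATTR, _namespaces,
                           eligible_routines, residual_wrapper_count,
                           restore_framework_functions, run_traced_forward,
                           wrap_framework_functions)


class OneOp(nn.Module):
    def __init__(self, fn_name):
        super().__init__()
        self.fn_name = fn_name

    def forward(self, x):
        return getattr(np, self.fn_name)(x)


def test_wrap_then_restore_is_identity_roundtrip():
    originals = {name: getattr(np, name) for name in ("cos", "add", "matmul")}
    session = TraceSession()
    count = wrap_framework_functions(session)
    assert count > 0
    assert getattr(np.cos, WRAP_ATTR) is originals["cos"]
    restore_framework_functions(session)
    for name, orig in originals.items():
        assert getattr(np, name) is orig
    assert residual_wrapper_count() == 0
    assert session.wrapped_registry == []


def test_restore_is_idempotent_and_stops_logging():
    model = OneOp("cos")
    x = np.ones((1, 3), dtype=np.float32)
    _, session = run_traced_forward(model, (x,))
    n = len(session.records)
    restore_framework_functions(session)  # second teardown: no-op
    model(x)  # forward after restoration
    assert len(session.records) == n
    assert residual_wrapper_count() == 0


def test_wrapped_count_matches_independent_introspection():
    """The number of wrapped routines equals an independent namespace scan
    for tensor-returning callables."""
    expected_objs = set()
    for ns_name, module in _namespaces():
        deny = DENYLIST.get(ns_name, set())
        for name in dir(module):
            if name.startswith("_") or name in deny:
                continue
            try:
                obj = getattr(module, name)
            except AttributeError:
                continue
            if (callable(obj) and not isinstance(obj, type)
                    and not isinstance(obj, types.ModuleType)):
                expected_objs.add(id(obj))
    session = TraceSession()
    try:
        count = wrap_framework_functions(session)
    finally:
        restore_framework_functions(session)
    assert count == len(expected_objs) > 100


def test_elementwise_op_appends_exactly_one_record():
    x = np.linspace(0, 1, 5, dtype=np.float32).reshape(1, 5)
    _, session = run_traced_forward(OneOp("cos"), (x,))
    cos_records = [r for r in session.records if r.op_name == "cos"]
    assert len(cos_records) == 1
    # input entry + cos + output entry
    assert [r.op_name for r in session.records] == ["input", "cos", "output"]


def test_division_records_numerator_and_denominator_positions(traced):
    history, _ = traced("branch_divide")
    div = history["divide_1_4"]
    positions = dict((pos, lbl) for lbl, pos in div.parents)
    assert positions == {"arg0": "cos_1_2", "arg1": "exp_1_3"}


def test_tensor_from_shape_constant_is_internally_generated(traced):
    history, _ = traced("internal_random")
    rand = history["rand_1_2"]
    assert rand.is_internally_generated
    assert rand.parents == []


def test_durations_are_nonnegative(traced):
    history, _ = traced("fig4b")
    assert all(e.duration >= 0 for e in history.entries)


def test_flat_module_records_single_element_stack():
    class Wrapped(nn.Module):
        def __init__(self):
            super().__init__()
            self.act = nn.ReLU()

        def forward(self, x):
            return self.act(x)

    x = np.ones((1, 4), dtype=np.float32)
    _, session = run_traced_forward(Wrapped(), (x,))
    relu = next(r for r in session.records if r.op_name == "relu")
    assert [a for a, _ in relu.module_stack] == ["act"]


def test_nested_module_stack_records_both_levels(traced):
    history, _ = traced("alexnet", seed=0)
    conv2 = history["features.3"]
    assert conv2.module_stack == ["features", "features.3"]


def test_reused_module_gets_distinct_pass_annotations(traced):
    history, _ = traced("fig4a")
    addresses = [e.module_addresses for e in history.entries
                 if e.layer_type == "linear"]
    assert addresses == [["fc:1"], ["fc:2"]]


@pytest.mark.parametrize("name", ["branch_divide", "cond_branch", "fig4b",
                                  "nested_blocks", "internal_random"])
def test_traced_output_equals_untraced(name):
    model, x, _ = nntrace.make_fixture(name, seed=4)
    np.random.seed(11)
    reference = np.asarray(model(x))
    np.random.seed(11)
    history = nntrace.log_forward_pass(model, x)
    out = history[-1].saved_activation
    np.testing.assert_array_equal(reference, out)


def test_exception_inside_model_still_restores_framework():
    class Boom(nn.Module):
        def forward(self, x):
            y = np.cos(x)
            raise RuntimeError("boom")

    with pytest.raises(RuntimeError, match="boom"):
        run_traced_forward(Boom(), (np.ones(3, dtype=np.float32),))
    assert residual_wrapper_count() == 0
    # the framework is usable for a fresh session afterwards
    _, session = run_traced_forward(OneOp("sin"),
                                    (np.ones(3, dtype=np.float32),))
    assert any(r.op_name == "sin" for r in session.records)


def test_identity_model_yields_input_and_output_entries(traced):
    history, _ = traced("identity")
    assert [e.layer_type for e in history.entries] == ["input", "output"]
    assert history["output_1_2"].parents == [("input_1_1", "arg0")]


def test_barcode_soundness_every_parent_resolves_to_earlier_record(traced):
    for name in ("fig4a", "nested_blocks", "tuple_output", "inplace"):
        history, _ = traced(name)
        order = {e.rec_index: i for i, e in enumerate(history.entries)}
        for e in history.entries:
            for idx, _ in e._parents:
                assert idx in history._by_rec
                assert order[idx] < order[e.rec_index]


def test_inplace_mutation_creates_entry_with_fresh_barcode(traced):
    history, _ = traced("inplace")
    add = history["add_1_3"]
    assert add.in_place
    assert add.parents == [("cos_1_2", "arg0")]
    # the downstream consumer sees the mutated entry, not the original
    assert history["sin_1_4"].parents == [("add_1_3", "arg0")]


def test_tuple_returning_op_yields_one_entry_per_tensor(traced):
    history, _ = traced("tuple_output")
    splits = [e for e in history.entries if e.layer_type == "split"]
    assert [e.output_index for e in splits] == [0, 1]
    assert splits[0].label != splits[1].label
    assert history["add_1_4"].parents == [("split_1_2", "arg0"),
                                          ("split_2_3", "arg1")]


def test_buffer_participating_in_op_becomes_origin_entry(traced):
    history, _ = traced("buffer")
    buf = history["buffer_1_2"]
    assert buf.is_buffer and not buf.is_internally_generated
    assert ("buffer_1_2", "arg1") in history["subtract_1_3"].parents


def test_nested_sessions_are_rejected():
    class Nested(nn.Module):
        def forward(self, x):
            run_traced_forward(OneOp("cos"), (x,))
            return x

    with pytest.raises(nntrace.trace.TraceError
                       if hasattr(nntrace, "trace") else RuntimeError):
        run_traced_forward(Nested(), (np.ones(2, dtype=np.float32),))
    assert residual_wrapper_count() == 0
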