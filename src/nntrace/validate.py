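"""Algorithmic verification of saved activations.

Each layer's routine is re-executed on the saved values of its parent
layers (with the RNG state captured at logging time restored, so stochastic
layers replay exactly) and the result must match the saved activation.  As
a counter-check, random substitute parent values must change the output —
unless the operation is input-insensitive (e.g. multiplication by zero),
detected structurally or by two distinct substitutes agreeing.

The walk starts from the model outputs and every childless entry (so that
dead-end conditional-test chains are covered too) and recurses to parents
until only parentless origin layers remain.
"""
from __future__ import annotations

import json
import zlib
from collections import deque

import numpy as np

from .history import LayerEntry, ModelHistory

__all__ = ["validate_layer", "validate_history", "validate_saved_activations",
           "ValidationError"]

RTOL = 1e-5
ATOL = 1e-8


class ValidationError(RuntimeError):
    pass


def _matches(a: np.ndarray, b: np.ndarray) -> bool:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if a.dtype.kind in "fc" or b.dtype.kind in "fc":
        return bool(np.allclose(a, b, rtol=RTOL, atol=ATOL))
    return bool(np.array_equal(a, b))


def _max_dev(a, b) -> float:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return float("inf")
    try:
        return float(np.max(np.abs(a.astype(np.float64) - b.astype(np.float64)))) \
            if a.size else 0.0
    except (TypeError, ValueError):
        return float("nan")


def _build_arg(slot, entry: LayerEntry, history: ModelHistory, parent_value):
    kind = slot[0]
    if kind == "tensor":
        return parent_value(slot[1])
    if kind == "param":
        return history._param_arrays[slot[1]]
    if kind == "literal":
        return slot[1]
    if kind == "seq":
        ctor = tuple if slot[1] == "tuple" else list
        return ctor(_build_arg(s, entry, history, parent_value) for s in slot[2])
    if kind == "outdest":
        return np.empty(entry.shape, dtype=entry.dtype)
    raise ValidationError(f"unknown argument slot {slot!r}")


def _reexecute(entry: LayerEntry, history: ModelHistory, parent_value):
    rec = entry._record
    if rec.rng_state is not None:
        np.random.set_state(rec.rng_state)
    args = [_build_arg(s, entry, history, parent_value) for s in rec.arg_slots]
    kwargs = {k: _build_arg(s, entry, history, parent_value)
              for k, s in rec.kwarg_slots.items()}
    out = rec.func(*args, **kwargs)
    if entry.output_index is not None:
        out = out[entry.output_index]
    return np.asarray(out)


def _substitute(parent_saved: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random stand-in drawn standard-normal, scaled to the saved parent's
    spread so re-execution stays in a numerically plausible range."""
    saved = np.asarray(parent_saved)
    if saved.dtype.kind == "b":
        return rng.random(saved.shape) < 0.5
    scale = float(np.std(saved)) if saved.size else 1.0
    if not np.isfinite(scale) or scale == 0.0:
        scale = 1.0
    loc = float(np.mean(saved)) if saved.size else 0.0
    vals = rng.standard_normal(saved.shape) * scale + loc
    if saved.dtype.kind in "iu":
        vals = np.rint(vals)
    return vals.astype(saved.dtype, copy=False)


def _structurally_insensitive(entry: LayerEntry) -> bool:
    """Cheap syntactic checks for ops whose output ignores tensor inputs."""
    if int(np.prod(entry.shape, dtype=np.int64)) == 0:
        return True
    if entry.op_name in ("multiply", "mul"):
        for _, rep in entry._record.literal_args:
            if rep in ("0", "0.0", "-0.0"):
                return True
    return False


def _sub_rng(seed: int, label: str, draw: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(label.encode()), draw]))


def validate_layer(history: ModelHistory, target, seed: int = 0,
                   report: dict | None = None) -> bool:
    """Re-execute one layer on its parents' saved values.

    True iff the saved activation is reproduced within tolerance and random
    substitute parents change the output (unless input-insensitive).
    Origin layers (inputs, buffers, constants) pass trivially.
    """
    entry = history[target] if not isinstance(target, LayerEntry) else target
    label = entry.label_w_pass
    rec = entry._record
    if rec is None or rec.func is None:
        if report is not None:
            report[label] = {"passed": True, "check": "origin", "max_dev": 0.0}
        return True
    if entry.saved_activation is None:
        raise ValidationError(f"no saved activation for layer {label!r}")
    parent_saved = {}
    for idx, _ in rec.tensor_parents:
        p = history._by_rec.get(idx)
        if p is None or p.saved_activation is None:
            pname = p.label_w_pass if p is not None else f"#{idx}"
            raise ValidationError(
                f"validating {label!r} requires the saved activation of its "
                f"parent {pname!r}")
        parent_saved[idx] = p.saved_activation

    def from_saved(idx):
        return np.array(parent_saved[idx], copy=True)

    out = _reexecute(entry, history, from_saved)
    if not _matches(out, entry.saved_activation):
        if report is not None:
            report[label] = {"passed": False, "check": "recompute",
                             "max_dev": _max_dev(out, entry.saved_activation)}
        return False

    ok = True
    check = None
    if parent_saved:  # perturbation counter-check
        def from_random(draw):
            def get(idx):
                return _substitute(parent_saved[idx], _sub_rng(seed, label + str(idx), draw))
            return get

        out_r1 = _reexecute(entry, history, from_random(1))
        if _matches(out_r1, entry.saved_activation):
            if not _structurally_insensitive(entry):
                out_r2 = _reexecute(entry, history, from_random(2))
                if not _matches(out_r1, out_r2):
                    ok = False
                    check = "perturbation"
            # else: input-insensitive special case, counter-check skipped
    if report is not None:
        report[label] = {"passed": ok, "check": check,
                         "max_dev": _max_dev(out, entry.saved_activation)}
    return ok


def validate_history(history: ModelHistory, seed: int = 0):
    """Walk the saved graph from the outputs (and dead ends) back to the
    origin layers, validating every layer.  Returns (ok, report)."""
    report: dict = {}
    queue = deque(e.rec_index for e in history.entries
                  if e.is_output or not e._children)
    visited = set(queue)
    ok = True
    while queue:
        idx = queue.popleft()
        entry = history._by_rec.get(idx)
        if entry is None:
            continue
        if not validate_layer(history, entry, seed=seed, report=report):
            ok = False
        for p, _ in entry._parents:
            if p not in visited:
                visited.add(p)
                queue.append(p)
    return ok, report


def validate_saved_activations(model, x, seed: int = 0,
                               return_report: bool = False,
                               report_path=None):
    """Trace ``model`` on ``x`` with all activations saved, then verify every
    saved activation by re-execution.  Returns True/False (and the per-layer
    report if requested)."""
    from .api import log_forward_pass
    history = log_forward_pass(model, x, which_layers="all", seed=seed)
    ok, report = validate_history(history, seed=seed)
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump({"passed": ok, "layers": report}, fh, indent=1)
    if return_report:
        return ok, report
    return ok
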