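"""User-facing entry points.

``log_forward_pass`` traces one forward pass of a model on an example
input and returns the finalized :class:`~nntrace.history.ModelHistory`;
``get_model_metadata`` does the same without retaining activations;
``show_model_graph`` renders the graph and discards everything else;
``validate_saved_activations`` checks saved activations by re-execution.
All randomized behavior flows from the single ``seed`` argument.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import graph as _graph
from . import history as _history
from . import viz as _viz
from .history import ModelHistory
from .trace import run_traced_forward
from .validate import validate_saved_activations  # re-export  # noqa: F401

__all__ = [
    "ConfigOptions", "log_forward_pass", "get_model_metadata",
    "show_model_graph", "validate_saved_activations", "set_seed", "seed",
]

Selector = Union[str, Sequence[str], Callable, None]


@dataclass
class ConfigOptions:
    """Bundle of tracing options (every field has a function-argument twin)."""
    which_layers: Selector = "all"
    visualize: str = "none"          # none | unrolled | rolled
    seed: Optional[int] = None
    save_activations: bool = True
    nesting_depth: Optional[int] = None
    vis_outpath: Optional[str] = None
    activations_dir: Optional[str] = None


def set_seed(n: int) -> None:
    """Seed the global RNG that stochastic layers draw from."""
    np.random.seed(n)


seed = set_seed


def _as_inputs(x) -> tuple:
    if isinstance(x, (list, tuple)):
        return tuple(np.asarray(a) for a in x)
    return (np.asarray(x),)


def _postprocess(session, model) -> ModelHistory:
    h = ModelHistory.from_session(session, model_name=type(model).__name__)
    _graph.trim_orphans(h)
    _graph.compute_graph_distances(h)
    _graph.infer_conditional_branches(h)
    _graph.fix_internal_module_containment(h)
    _graph.identify_repeated_layers(h)
    _history.assign_layer_labels(h)
    _history.assign_module_addresses(h)
    h.finalize()
    _graph.roll_graph(h)
    return h


def _entry_matches(e, token: str) -> bool:
    if token in (e.label_w_pass, e.label, f"{e.layer_type}_{e.layer_type_num}",
                 e.layer_type):
        return True
    for addr in e.module_addresses:
        if token in (addr, addr.split(":")[0]):
            return True
    return False


def _filter_saved(h: ModelHistory, which_layers: Selector) -> None:
    if which_layers == "all":
        return
    if which_layers is None or (not callable(which_layers)
                                and len(which_layers) == 0):
        for e in h.entries:
            e.saved_activation = None
        h._saved_subset = True
        h.finalize()
        return
    if callable(which_layers):
        keep = {e.rec_index for e in h.entries if which_layers(e)}
    else:
        tokens = list(which_layers)
        keep = set()
        for token in tokens:
            hits = {e.rec_index for e in h.entries if _entry_matches(e, token)}
            if not hits:
                raise KeyError(f"which_layers selector {token!r} matches no layer")
            keep |= hits
    for e in h.entries:
        if e.rec_index not in keep:
            e.saved_activation = None
    h._saved_subset = True
    h.finalize()


def log_forward_pass(model, x, which_layers: Selector = "all",
                     visualize: str = "none",
                     nesting_depth: Optional[int] = None,
                     seed: Optional[int] = None,
                     vis_outpath=None) -> ModelHistory:
    """Trace one forward pass and return its full queryable history.

    ``which_layers`` controls only which activation payloads are retained;
    metadata is always recorded for every layer.  ``visualize`` may be
    "none", "unrolled" or "rolled".
    """
    if seed is not None:
        set_seed(seed)
    inputs = _as_inputs(x)
    save = which_layers is not None and (callable(which_layers)
                                         or len(which_layers) > 0)
    _, session = run_traced_forward(model, inputs, save_activations=save)
    h = _postprocess(session, model)
    _filter_saved(h, which_layers)
    if visualize not in ("none", None):
        opts = _viz.VisOptions(nesting_depth=nesting_depth,
                               rolled=(visualize == "rolled"))
        _viz.render_graph(h, opts, out_path=vis_outpath
                          or f"{h.model_name}_graph.dot")
    return h


def get_model_metadata(model, x, seed: Optional[int] = None) -> ModelHistory:
    """Trace a forward pass recording metadata only (no activations kept)."""
    if seed is not None:
        set_seed(seed)
    _, session = run_traced_forward(model, _as_inputs(x),
                                    save_activations=False)
    h = _postprocess(session, model)
    h._saved_subset = False
    h.finalize()
    return h


def show_model_graph(model, x, nesting_depth: Optional[int] = None,
                     rolled: bool = False, out_path="model_graph.dot",
                     seed: Optional[int] = None, format: str = "dot") -> str:
    """Trace, post-process and render the model graph; returns DOT source.

    Activations are not saved and the history is discarded.
    """
    if seed is not None:
        set_seed(seed)
    _, session = run_traced_forward(model, _as_inputs(x),
                                    save_activations=False)
    h = _postprocess(session, model)
    opts = _viz.VisOptions(nesting_depth=nesting_depth, rolled=rolled,
                           format=format)
    return _viz.render_graph(h, opts, out_path=out_path)
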