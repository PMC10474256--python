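"""Programmatically built fixture models with hand-written ground truths.

Each fixture pairs a seeded builder with an expected-graph description
(stored as JSON next to the code) covering node labels, flags, adjacency
with argument positions, pass counts and module addresses, so every stage
of the pipeline is testable without downloads.  The catalog includes the
worked recurrence examples (a shared linear layer applied twice with
matching surrounding ops; a back-to-back repeating cos/relu/multiply block
with a later non-contiguous repetition), conditional-branch and
internally-generated-tensor models, parameter-free loop patterns, and a
standard AlexNet stack.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Callable

import numpy as np

from . import functional as F
from . import nn

__all__ = ["FixtureSpec", "make_fixture", "list_fixtures", "check_ground_truth"]


@dataclass
class FixtureSpec:
    name: str
    description: str
    builder: Callable        # builder(seed) -> (model, example_input)
    input_shape: tuple

    @property
    def ground_truth(self) -> dict:
        path = resources.files("nntrace").joinpath("ground_truth",
                                                   f"{self.name}.json")
        gt = json.loads(path.read_text())
        _check_gt_consistency(gt, self.name)
        return gt


def _check_gt_consistency(gt: dict, name: str) -> None:
    labels = {n["label"] for n in gt["entries"]}
    for src, dst, _ in gt["edges"]:
        if src not in labels or dst not in labels:
            raise ValueError(f"ground truth {name}: edge references unknown "
                             f"node {src!r} -> {dst!r}")
    by_layer: dict = {}
    for n in gt["entries"]:
        by_layer.setdefault(n["label"].split(":")[0], []).append(n)
    for layer in gt.get("layers", []):
        if len(by_layer.get(layer["label"], [])) != layer["passes"]:
            raise ValueError(f"ground truth {name}: pass count mismatch for "
                             f"{layer['label']}")


# ----------------------------------------------------------------------
# model definitions
# ----------------------------------------------------------------------

class Identity(nn.Module):
    def forward(self, x):
        return x


class FeedForward(nn.Module):
    def __init__(self, rng):
        super().__init__()
        self.fc1 = nn.Linear(10, 10, rng)
        self.fc2 = nn.Linear(10, 4, rng)

    def forward(self, x):
        h = self.fc1(x)
        h = F.relu(h)
        return self.fc2(h)


class BranchDivide(nn.Module):
    """Non-commutative division of two branches (argument order matters)."""

    def forward(self, x):
        a = np.cos(x)
        b = np.exp(x)
        return np.divide(a, b)


class InternalRandom(nn.Module):
    """Noise generated inside the model and added to the main path."""

    def forward(self, x):
        n = np.random.rand(*x.shape)
        return np.add(x, n)


class OrphanOps(nn.Module):
    """Creates and discards an internal tensor chain (orphan operations)."""

    def forward(self, x):
        y = np.cos(x)
        junk = np.random.rand(2, 2)
        np.tanh(junk)
        return y


class WithBuffer(nn.Module):
    def __init__(self, rng):
        super().__init__()
        self.register_buffer(
            "mu", rng.standard_normal((1, 6), dtype=np.float32))

    def forward(self, x):
        return np.subtract(x, self.mu)


class CondBranch(nn.Module):
    """If-test on a single Boolean: mean(x - 5) > 3 (always False for
    inputs in [0, 1), so the traced branch is stable across seeds)."""

    def forward(self, x):
        t = np.subtract(x, 5.0)
        m = np.mean(t)
        c = np.greater(m, 3.0)
        if c:
            return np.sin(t)
        return np.cos(t)


class InPlaceOp(nn.Module):
    def forward(self, x):
        y = np.cos(x)
        np.add(y, 1.0, out=y)
        return np.sin(y)


class TupleOutput(nn.Module):
    def forward(self, x):
        a, b = np.split(x, 2, axis=1)
        return np.add(a, b)


class ZeroMultiply(nn.Module):
    """Multiplication by zero: an input-insensitive op for validation."""

    def forward(self, x):
        y = np.multiply(x, 0.0)
        return np.add(y, 1.0)


class Fig4A(nn.Module):
    """Shared fully-connected parameters applied twice, with the same
    cosine before and the same addition after each pass, and a sine
    between the passes."""

    def __init__(self, rng):
        super().__init__()
        self.fc = nn.Linear(4, 4, rng)

    def forward(self, x):
        y = np.cos(x)
        y = self.fc(y)
        y = np.add(y, 1.0)
        y = np.sin(y)
        y = np.cos(y)
        y = self.fc(y)
        y = np.add(y, 1.0)
        return y


class Fig4B(nn.Module):
    """cos/relu/multiply twice back-to-back, a tangent, then the same
    three ops once more (not contiguous, so not grouped)."""

    def forward(self, x):
        for _ in range(2):
            x = np.cos(x)
            x = F.relu(x)
            x = np.multiply(x, 2.0)
        x = np.tan(x)
        x = np.cos(x)
        x = F.relu(x)
        x = np.multiply(x, 2.0)
        return x


class XYZLoop(nn.Module):
    """XYZXYZXYZ: a parameter-free loop repeated back-to-back."""

    def forward(self, x):
        for _ in range(3):
            x = np.cos(x)
            x = np.sin(x)
            x = np.tanh(x)
        return x


class XYZInterrupted(nn.Module):
    """XYZAXYZBXYZ: the XYZ repetitions are separated, hence not grouped."""

    def forward(self, x):
        x = np.cos(x); x = np.sin(x); x = np.tanh(x)
        x = np.floor(x)
        x = np.cos(x); x = np.sin(x); x = np.tanh(x)
        x = np.ceil(x)
        x = np.cos(x); x = np.sin(x); x = np.tanh(x)
        return x


class InceptionBlock(nn.Module):
    def __init__(self, rng, ch):
        super().__init__()
        self.branch1 = nn.Conv2d(ch, ch // 2, 1, rng)
        self.branch2 = nn.Sequential(
            nn.Conv2d(ch, ch // 2, 3, rng, padding=1), nn.ReLU())

    def forward(self, x):
        a = self.branch1(x)
        b = self.branch2(x)
        return np.concatenate([a, b], axis=1)


class NestedBlocks(nn.Module):
    """Two inception-style blocks with parallel convolutional branches."""

    def __init__(self, rng):
        super().__init__()
        self.block1 = InceptionBlock(rng, 4)
        self.block2 = InceptionBlock(rng, 4)

    def forward(self, x):
        return self.block2(self.block1(x))


class AlexNet(nn.Module):
    """The classic five-conv/three-linear stack with nested features /
    avgpool / classifier modules (randomly initialized)."""

    def __init__(self, rng, num_classes=1000):
        super().__init__()
        self.features = nn.Sequential(
            nn.Conv2d(3, 64, 11, rng, stride=4, padding=2),
            nn.ReLU(),
            nn.MaxPool2d(3, 2),
            nn.Conv2d(64, 192, 5, rng, padding=2),
            nn.ReLU(),
            nn.MaxPool2d(3, 2),
            nn.Conv2d(192, 384, 3, rng, padding=1),
            nn.ReLU(),
            nn.Conv2d(384, 256, 3, rng, padding=1),
            nn.ReLU(),
            nn.Conv2d(256, 256, 3, rng, padding=1),
            nn.ReLU(),
            nn.MaxPool2d(3, 2),
        )
        self.avgpool = nn.AvgPool2d(6)
        self.classifier = nn.Sequential(
            nn.Dropout(0.5),
            nn.Linear(256 * 6 * 6, 4096, rng),
            nn.ReLU(),
            nn.Dropout(0.5),
            nn.Linear(4096, 4096, rng),
            nn.ReLU(),
            nn.Linear(4096, num_classes, rng),
        )

    def forward(self, x):
        x = self.features(x)
        x = self.avgpool(x)
        x = np.reshape(x, (x.shape[0], -1))
        return self.classifier(x)


# ----------------------------------------------------------------------
# catalog
# ----------------------------------------------------------------------

def _normal_input(shape):
    def make(rng):
        return rng.standard_normal(shape, dtype=np.float32)
    return make


def _uniform_input(shape):
    def make(rng):
        return rng.random(shape, dtype=np.float32)
    return make


_CATALOG: dict[str, tuple] = {}


def _register(name, description, model_cls, input_shape, needs_rng=True,
              input_maker=None):
    maker = input_maker or _normal_input(input_shape)

    def builder(seed: int):
        rng = np.random.default_rng(seed)
        model = model_cls(rng) if needs_rng else model_cls()
        return model, maker(rng)

    _CATALOG[name] = (FixtureSpec(name, description, builder, input_shape),)


_register("identity", "model returning its input unchanged", Identity,
          (1, 4), needs_rng=False)
_register("feedforward", "linear-relu-linear chain", FeedForward, (1, 10))
_register("branch_divide", "two branches joined by non-commutative division",
          BranchDivide, (1, 6), needs_rng=False)
_register("internal_random", "internally generated noise added to the input",
          InternalRandom, (1, 6), needs_rng=False)
_register("orphan", "discarded internal tensor chain", OrphanOps, (1, 6),
          needs_rng=False)
_register("buffer", "non-trainable buffer participating in an op", WithBuffer,
          (1, 6))
_register("cond_branch", "if-then branch evaluated on a single Boolean",
          CondBranch, (1, 16), needs_rng=False,
          input_maker=_uniform_input((1, 16)))
_register("inplace", "operation mutating its input tensor in place",
          InPlaceOp, (1, 6), needs_rng=False)
_register("tuple_output", "op returning a tuple of tensors", TupleOutput,
          (1, 8), needs_rng=False)
_register("zero_multiply", "input-insensitive multiply-by-zero", ZeroMultiply,
          (1, 6), needs_rng=False)
_register("fig4a", "shared linear layer applied twice with matching "
          "surrounding ops", Fig4A, (1, 4))
_register("fig4b", "contiguous cos/relu/multiply repetition plus a separated "
          "later one", Fig4B, (1, 8), needs_rng=False)
_register("xyz_loop", "XYZXYZXYZ parameter-free loop", XYZLoop, (1, 16),
          needs_rng=False)
_register("xyz_interrupted", "XYZAXYZBXYZ separated repetitions",
          XYZInterrupted, (1, 64), needs_rng=False)
_register("nested_blocks", "two inception-style blocks with parallel "
          "branches", NestedBlocks, (1, 4, 8, 8))
_register("alexnet", "standard AlexNet stack at 224x224 input", AlexNet,
          (1, 3, 224, 224))


def list_fixtures() -> list[str]:
    return sorted(_CATALOG)


def make_fixture(name: str, seed: int = 0):
    """Build a catalog model: returns ``(model, example_input, spec)``."""
    if name not in _CATALOG:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{', '.join(list_fixtures())}")
    (spec,) = _CATALOG[name]
    model, x = spec.builder(seed)
    return model, x, spec


# ----------------------------------------------------------------------
# ground-truth comparison
# ----------------------------------------------------------------------

def check_ground_truth(history, gt: dict) -> list[str]:
    """Compare a post-processed history against a hand-written ground
    truth; returns a list of mismatch descriptions (empty = equal)."""
    problems = []
    got_labels = [e.label_w_pass for e in history.entries]
    want_labels = [n["label"] for n in gt["entries"]]
    if got_labels != want_labels:
        problems.append(f"entry labels differ:\n got {got_labels}\nwant {want_labels}")
        return problems
    for e, node in zip(history.entries, gt["entries"]):
        lbl = node["label"]
        if e.layer_type != node["type"]:
            problems.append(f"{lbl}: type {e.layer_type} != {node['type']}")
        want_flags = set(node.get("flags", []))
        for flag, value in e.flags.items():
            if bool(value) != (flag in want_flags):
                problems.append(f"{lbl}: flag {flag} is {bool(value)}, "
                                f"expected {flag in want_flags}")
        if sorted(e.module_addresses) != sorted(node.get("modules", [])):
            problems.append(f"{lbl}: module addresses {e.module_addresses} != "
                            f"{node.get('modules', [])}")
        if "module_stack" in node and list(e.module_stack) != node["module_stack"]:
            problems.append(f"{lbl}: module stack {e.module_stack} != "
                            f"{node['module_stack']}")
        if bool(e.param_shapes) != node.get("params", False):
            problems.append(f"{lbl}: has-params {bool(e.param_shapes)} != "
                            f"{node.get('params', False)}")
        if "in_place" in node and bool(e.in_place) != node["in_place"]:
            problems.append(f"{lbl}: in_place {e.in_place} != {node['in_place']}")
        if "shape" in node and list(e.shape) != node["shape"]:
            problems.append(f"{lbl}: shape {list(e.shape)} != {node['shape']}")
    got_edges = {(p, e.label_w_pass, pos)
                 for e in history.entries for p, pos in e.parents}
    want_edges = {tuple(edge) for edge in gt["edges"]}
    if got_edges != want_edges:
        problems.append(f"edges differ:\n extra {sorted(got_edges - want_edges)}"
                        f"\n missing {sorted(want_edges - got_edges)}")
    got_passes = {e.label: e.pass_count for e in history.entries}
    for layer in gt.get("layers", []):
        if got_passes.get(layer["label"]) != layer["passes"]:
            problems.append(f"{layer['label']}: pass count "
                            f"{got_passes.get(layer['label'])} != {layer['passes']}")
    return problems
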