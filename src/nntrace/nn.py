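"""Minimal neural-network module system over numpy arrays.

Provides the containment structure the tracer instruments: nested, named
modules with trainable parameters, non-trainable buffers, and forward
pre/post hooks that fire when a tensor enters or leaves a module.  Layer
forwards call into :mod:`nntrace.functional` (or numpy directly) so that
every tensor operation is visible to the tracing layer.
"""
from __future__ import annotations

from typing import Callable, Iterator, Tuple

import numpy as np

from . import functional as F

__all__ = [
    "Module", "Sequential", "Linear", "Conv2d", "ReLU", "MaxPool2d",
    "AvgPool2d", "Dropout", "HookHandle",
]


class HookHandle:
    """Removable registration of a forward hook."""

    def __init__(self, hooks: list, fn: Callable):
        self._hooks = hooks
        self._fn = fn

    def remove(self) -> None:
        if self._fn in self._hooks:
            self._hooks.remove(self._fn)


class Module:
    """Base class for model components.

    Submodules are auto-registered on attribute assignment; parameters and
    buffers are registered explicitly.  Calling a module runs its forward
    pre-hooks, ``forward``, then its forward post-hooks.
    """

    def __init__(self):
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_pre_hooks", [])
        object.__setattr__(self, "_post_hooks", [])

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- registration ----------------------------------------------------
    def register_parameter(self, name: str, array: np.ndarray) -> np.ndarray:
        self._parameters[name] = array
        object.__setattr__(self, name, array)
        return array

    def register_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        self._buffers[name] = array
        object.__setattr__(self, name, array)
        return array

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name, module)
        return module

    # -- traversal -------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[Tuple[str, "Module"]]:
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, p in self._parameters.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    # -- hooks -----------------------------------------------------------
    def register_forward_pre_hook(self, fn: Callable) -> HookHandle:
        self._pre_hooks.append(fn)
        return HookHandle(self._pre_hooks, fn)

    def register_forward_hook(self, fn: Callable) -> HookHandle:
        self._post_hooks.append(fn)
        return HookHandle(self._post_hooks, fn)

    # -- execution -------------------------------------------------------
    def forward(self, *args):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        for fn in list(self._pre_hooks):
            fn(self, args)
        out = self.forward(*args)
        for fn in list(self._post_hooks):
            fn(self, args, out)
        return out


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        for i, mod in enumerate(modules):
            self.add_module(str(i), mod)

    def forward(self, x):
        for mod in self._modules.values():
            x = mod(x)
        return x

    def __iter__(self):
        return iter(self._modules.values())


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    scale = np.sqrt(2.0 / max(fan_in, 1))
    return (rng.standard_normal(shape) * scale).astype(np.float32)


class Linear(Module):
    """Affine map ``x @ W.T + b`` with W of shape (out_features, in_features)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.register_parameter("weight", _kaiming(rng, (out_features, in_features), in_features))
        if bias:
            self.register_parameter("bias", np.zeros(out_features, dtype=np.float32))
        else:
            self.bias = None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = padding
        k = kernel_size
        fan_in = in_channels * k * k
        self.register_parameter("weight", _kaiming(rng, (out_channels, in_channels, k, k), fan_in))
        if bias:
            self.register_parameter("bias", np.zeros(out_channels, dtype=np.float32))
        else:
            self.bias = None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride if stride is not None else kernel_size

    def forward(self, x):
        return F.maxpool2d(x, self.kernel_size, stride=self.stride)


class AvgPool2d(Module):
    """Adaptive average pooling to a fixed output spatial size."""

    def __init__(self, output_size: int):
        super().__init__()
        self.output_size = output_size

    def forward(self, x):
        return F.avgpool2d(x, self.output_size)


class Dropout(Module):
    """Inverted dropout; stochastic by default (draws from the global RNG)."""

    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p

    def forward(self, x):
        return F.dropout(x, self.p)
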