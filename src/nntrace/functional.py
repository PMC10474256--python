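"""Composite layer operations, each logged as a single graph node.

These functions form the layer-level vocabulary of the host framework: the
tracer wraps this namespace alongside numpy's, and because only the
outermost wrapped call is logged, a convolution appears as one ``conv2d``
node rather than its im2col constituents.

Conventions: activations are (N, C, H, W) or (N, features) float arrays;
``dropout`` draws its mask from the global ``numpy.random`` state so that a
seeded forward pass is exactly replayable.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["linear", "conv2d", "relu", "maxpool2d", "avgpool2d", "dropout"]


def linear(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    out = np.matmul(x, weight.T)
    if bias is not None:
        out = np.add(out, bias)
    return out


def conv2d(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None = None,
           stride: int = 1, padding: int = 0) -> np.ndarray:
    """2-D cross-correlation; x (N,C,H,W), weight (O,C,kh,kw)."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    kh, kw = weight.shape[2], weight.shape[3]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, Ho, Wo, kh, kw)
    out = np.einsum("nchwij,ocij->nohw", win, weight, optimize=True)
    if bias is not None:
        out = out + bias[None, :, None, None]
    return np.ascontiguousarray(out.astype(x.dtype, copy=False))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0)


def maxpool2d(x: np.ndarray, kernel_size: int, stride: int | None = None) -> np.ndarray:
    stride = stride if stride is not None else kernel_size
    win = sliding_window_view(x, (kernel_size, kernel_size), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    return win.max(axis=(4, 5))


def avgpool2d(x: np.ndarray, output_size: int) -> np.ndarray:
    """Adaptive average pooling; input spatial dims must be divisible."""
    n, c, h, w = x.shape
    fh, fw = h // output_size, w // output_size
    y = x.reshape(n, c, output_size, fh, output_size, fw)
    return y.mean(axis=(3, 5)).astype(x.dtype, copy=False)


def dropout(x: np.ndarray, p: float = 0.5) -> np.ndarray:
    if p <= 0.0:
        return x * 1
    mask = (np.random.random(x.shape) >= p).astype(x.dtype)
    return x * mask / np.asarray(1.0 - p, dtype=x.dtype)
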