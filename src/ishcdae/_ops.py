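"""Batched numpy kernels for the autoencoder: same-padded convolution via
im2col, 2x2 max-pooling with argmax-routed gradients, and value-duplicating
2x2 unpooling. All arrays are (N, C, H, W) float64."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _pad_windows(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-pad spatially by k//2 and expose all kxk windows as a strided
    view of shape (N, C, H, W, k, k) — no data copied beyond the padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    return sliding_window_view(xp, (k, k), axis=(2, 3))


def conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """Stride-1, size-preserving cross-correlation. weight: (Cout, Cin, k, k).

    Returns (y, windows); the strided window view is reused by backward.
    """
    win = _pad_windows(x, weight.shape[-1])
    y = np.einsum("nchwij,ocij->nohw", win, weight, optimize=True)
    y += bias[None, :, None, None]
    return y, win


def conv_backward(dy: np.ndarray, win: np.ndarray, weight: np.ndarray):
    """Gradients of conv_forward.

    The input gradient of a zero-padded stride-1 correlation is the same
    correlation of dy with the spatially flipped, channel-transposed filter
    bank.
    """
    d_weight = np.einsum("nohw,nchwij->ocij", dy, win, optimize=True)
    d_bias = dy.sum(axis=(0, 2, 3))
    dy_win = _pad_windows(dy, weight.shape[-1])
    dx = np.einsum("nohwij,ocij->nchw", dy_win, weight[:, :, ::-1, ::-1],
                   optimize=True)
    return dx, d_weight, d_bias


def maxpool_forward(x: np.ndarray):
    """2x2 max-pooling over disjoint blocks; dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max-pooling requires even spatial dims, got {h}x{w}")
    blocks = (
        x.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = blocks.argmax(axis=-1)
    y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool_backward(dy: np.ndarray, idx: np.ndarray, x_shape):
    n, c, h, w = x_shape
    dblocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dblocks, idx[..., None], dy[..., None], axis=-1)
    return (
        dblocks.reshape(n, c, h // 2, w // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h, w)
    )


def unpool_forward(x: np.ndarray) -> np.ndarray:
    """Duplicate every value into a constant 2x2 block (no max locations kept)."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def unpool_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h2, w2 = dy.shape
    return dy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


def activation_forward(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "tanh":
        return np.tanh(x)
    if kind == "linear":
        return x
    raise ValueError(f"unknown activation: {kind!r}")


def activation_backward(dy: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed through the post-activation value y
    if kind == "relu":
        return dy * (y > 0)
    if kind == "tanh":
        return dy * (1.0 - y * y)
    if kind == "linear":
        return dy
    raise ValueError(f"unknown activation: {kind!r}")
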