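"""Convolution, pooling and resampling primitives with custom gradients.

conv2d is im2col + matmul.  The backward pass materializes the column
gradient and scatters it back with a small K*K python loop over fully
vectorized slice-adds (col2im), which is fast for the 1x1/3x3/5x5/7x7
kernels the detector uses.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor, as_tensor

__all__ = [
    "conv2d", "dynamic_conv2d", "conv1d", "avg_pool2d", "upsample_nearest2",
    "global_avg_pool", "global_max_pool",
]


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (int(v), int(v))


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int, ph: int, pw: int):
    """(B,C,H,W) -> columns (B, C, kh, kw, Ho, Wo)."""
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # B,C,Hs,Ws,kh,kw
    win = win[:, :, ::sh, ::sw]
    return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3))


def _col2im(cols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw):
    """Adjoint of _im2col. cols: (B, C, kh, kw, Ho, Wo)."""
    B, C, H, W = x_shape
    Ho, Wo = cols.shape[-2:]
    xp = np.zeros((B, C, H + 2 * ph, W + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        hi = i + sh * Ho
        for j in range(kw):
            wj = j + sw * Wo
            xp[:, :, i:hi:sh, j:wj:sw] += cols[:, :, i, j]
    return xp[:, :, ph:ph + H, pw:pw + W]


def conv_out_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1, padding=0, groups: int = 1) -> Tensor:
    """Cross-correlation of a batch with a shared kernel.

    x: (B, Cin, H, W); weight: (Cout, Cin/groups, kh, kw); bias: (Cout,).
    """
    x, weight = as_tensor(x), as_tensor(weight)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = weight.shape
    if C != Cg * groups:
        raise ValueError(
            f"conv2d: input has {C} channels but weight expects {Cg * groups} "
            f"({Cg} per group x {groups} groups)")
    if Cout % groups:
        raise ValueError("conv2d: output channels not divisible by groups")

    cols = _im2col(x.data, kh, kw, sh, sw, ph, pw)          # B,C,kh,kw,Ho,Wo
    Ho, Wo = cols.shape[-2:]
    L = Ho * Wo
    cols_g = cols.reshape(B, groups, Cg * kh * kw, L)
    w_g = weight.data.reshape(groups, Cout // groups, Cg * kh * kw)
    out = np.einsum("gok,bgkl->bgol", w_g, cols_g, optimize=True)
    out = out.reshape(B, Cout, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, Cout, 1, 1)

    def grad_x(g):
        g_g = g.reshape(B, groups, Cout // groups, L)
        dcols = np.einsum("gok,bgol->bgkl", w_g, g_g, optimize=True)
        dcols = dcols.reshape(B, C, kh, kw, Ho, Wo)
        return _col2im(dcols, (B, C, H, W), kh, kw, sh, sw, ph, pw)

    def grad_w(g):
        g_g = g.reshape(B, groups, Cout // groups, L)
        dw = np.einsum("bgol,bgkl->gok", g_g, cols_g, optimize=True)
        return dw.reshape(Cout, Cg, kh, kw)

    parents = [(x, grad_x), (weight, grad_w)]
    if bias is not None:
        parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor._make(out, parents)


def dynamic_conv2d(x: Tensor, weight: Tensor, stride=1, padding=0) -> Tensor:
    """Convolution where every sample carries its own kernel.

    x: (B, Cin, H, W); weight: (B, Cout, Cin, kh, kw).  Used by the
    expert-kernel layer after per-sample kernel fusion.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    B, C, H, W = x.shape
    Bw, Cout, Cin, kh, kw = weight.shape
    if Bw != B or Cin != C:
        raise ValueError("dynamic_conv2d: weight batch/channel mismatch")

    cols = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    Ho, Wo = cols.shape[-2:]
    L = Ho * Wo
    cols_f = cols.reshape(B, C * kh * kw, L)
    w_f = weight.data.reshape(B, Cout, C * kh * kw)
    out = np.einsum("bok,bkl->bol", w_f, cols_f, optimize=True).reshape(B, Cout, Ho, Wo)

    def grad_x(g):
        g_f = g.reshape(B, Cout, L)
        dcols = np.einsum("bok,bol->bkl", w_f, g_f, optimize=True)
        dcols = dcols.reshape(B, C, kh, kw, Ho, Wo)
        return _col2im(dcols, (B, C, H, W), kh, kw, sh, sw, ph, pw)

    def grad_w(g):
        g_f = g.reshape(B, Cout, L)
        dw = np.einsum("bol,bkl->bok", g_f, cols_f, optimize=True)
        return dw.reshape(B, Cout, C, kh, kw)

    return Tensor._make(out, [(x, grad_x), (weight, grad_w)])


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """1-D cross-correlation over the last axis of a (B, C) vector batch.

    Used by the channel-attention head: the channel response vector is the
    "signal", the k weights slide across neighboring channels.
    """
    x = as_tensor(x)
    B, C = x.shape
    k = weight.shape[-1]
    x4 = x.reshape(B, 1, 1, C)
    w4 = weight.reshape(1, 1, 1, k)
    out = conv2d(x4, w4, bias=None, stride=1, padding=(0, padding))
    out = out.reshape(B, -1)
    if bias is not None:
        out = out + bias
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping average pooling; spatial dims must divide k."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial dims {(H, W)} not divisible by {k}")
    out = x.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5))
    return out


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    x = as_tensor(x)
    B, C, H, W = x.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def grad_fn(g):
        return g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5))

    return Tensor._make(out, [(x, grad_fn)])


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C): spatial mean per channel."""
    return as_tensor(x).mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C): spatial max per channel."""
    x = as_tensor(x)
    B, C = x.shape[:2]
    return x.reshape(B, C, -1).max(axis=2)
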