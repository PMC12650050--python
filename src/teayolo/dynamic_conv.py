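"""Input-conditioned expert-kernel convolution (DynamicConv) and its blocks.

A DynamicConv layer stores M "expert" kernels W_1..W_M of identical shape.
For each input sample, a coefficient generator pools the feature map into a
per-channel descriptor v, routes it through an affine head, and softmax-
normalizes the result into coefficients alpha on the simplex.  The effective
kernel is the convex combination W' = sum_i alpha_i W_i, applied as a
standard convolution, so capacity scales ~M-fold while the per-forward FLOPs
stay those of a single convolution.

The DynamicConv-C3k2 / DynamicConv-C3k blocks mirror the CSP-style C3k2/C3k
topology of the base detector with the bottleneck's second 3x3 convolution
replaced by a DynamicConv layer.

Parameter budget of one DynamicConv layer (bias-free experts, affine router,
per-channel normalization)::

    M * Cout * Cin * K^2 / groups  +  Cin * M + M  +  2 * Cout
"""

from __future__ import annotations

import numpy as np

from .nn.autograd import Tensor, as_tensor, concat
from .nn import functional as F
from .nn.module import (
    Module, ModuleList, Sequential, Parameter, BatchNorm2d, ConvBlock,
    autopad, get_rng, kaiming_conv_weight,
)

__all__ = [
    "pool_descriptor", "route", "fuse_kernels",
    "DynamicConv", "DynamicBottleneck", "DynamicConvC3k", "DynamicConvC3k2",
]


# ---------------------------------------------------------------------------
# functional pieces (exposed for testing against independent oracles)

def pool_descriptor(x) -> Tensor:
    """Global average pooling: (B, Cin, H, W) -> per-sample descriptor (B, Cin)."""
    return F.global_avg_pool(as_tensor(x))


def route(v, router_weight, router_bias) -> Tensor:
    """Softmax of the affine router output: coefficients on the M-simplex.

    v: (B, Cin); router_weight: (M, Cin); router_bias: (M,).
    """
    v = as_tensor(v)
    w = as_tensor(router_weight)
    if v.shape[-1] != w.shape[-1]:
        raise ValueError(
            f"route: descriptor length {v.shape[-1]} does not match router "
            f"input size {w.shape[-1]}")
    logits = v @ w.swapaxes(0, 1) + as_tensor(router_bias)
    return logits.softmax(axis=-1)


def fuse_kernels(experts, alpha) -> Tensor:
    """Convex combination of experts.

    experts: (M, Cout, Cin, K, K); alpha: (B, M) or (M,).
    Returns (B, Cout, Cin, K, K) (or unbatched if alpha is 1-D).
    """
    experts, alpha = as_tensor(experts), as_tensor(alpha)
    m = experts.shape[0]
    if alpha.shape[-1] != m:
        raise ValueError(f"fuse_kernels: got {alpha.shape[-1]} coefficients for {m} experts")
    flat = experts.reshape(m, -1)            # M, P
    fused = alpha @ flat                     # ..., P
    return fused.reshape(tuple(alpha.shape[:-1]) + tuple(experts.shape[1:]))


# ---------------------------------------------------------------------------
# layers

class DynamicConv(Module):
    """Expert-bank convolution block: route -> fuse -> conv -> BN -> SiLU.

    Argument order matches the architecture table: (cin, cout, k, stride).
    """

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding=None, groups: int = 1, num_experts: int = 4,
                 act: bool = True):
        super().__init__()
        if groups != 1:
            raise NotImplementedError("grouped expert convolution is not used by the network")
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = autopad(k, padding)
        self.num_experts = num_experts
        experts = np.stack([kaiming_conv_weight(cout, cin, k, k) for _ in range(num_experts)])
        self.experts = Parameter(experts)            # (M, Cout, Cin, K, K)
        # near-zero router => near-uniform initial routing
        self.router_weight = Parameter(get_rng().normal(0.0, 1e-3, size=(num_experts, cin)).astype(np.float32))
        self.router_bias = Parameter(np.zeros(num_experts, dtype=np.float32))
        self.bn = BatchNorm2d(cout)
        self.act = act

    def coefficients(self, x) -> Tensor:
        return route(pool_descriptor(x), self.router_weight, self.router_bias)

    def forward(self, x):
        x = as_tensor(x)
        alpha = self.coefficients(x)                        # (B, M)
        kernels = fuse_kernels(self.experts, alpha)         # (B, Cout, Cin, K, K)
        y = F.dynamic_conv2d(x, kernels, stride=self.stride, padding=self.padding)
        y = self.bn(y)
        return y.silu() if self.act else y


def dynamic_conv_forward(x, experts, router_weight, router_bias,
                         stride=1, padding=None) -> Tensor:
    """Functional forward of the fused-expert convolution (no norm/activation).

    Exists so the batched implementation can be checked against a per-sample
    fuse-then-convolve oracle.
    """
    x = as_tensor(x)
    k = experts.shape[-1]
    alpha = route(pool_descriptor(x), router_weight, router_bias)
    kernels = fuse_kernels(experts, alpha)
    return F.dynamic_conv2d(x, kernels, stride=stride, padding=autopad(k, padding))


class DynamicBottleneck(Module):
    """Residual unit: 3x3 Conv followed by 3x3 DynamicConv (+ shortcut)."""

    def __init__(self, cin: int, cout: int, shortcut: bool = True,
                 k=(3, 3), e: float = 1.0, num_experts: int = 4):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = ConvBlock(cin, c_, k[0], 1)
        self.cv2 = DynamicConv(c_, cout, k[1], 1, num_experts=num_experts)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class DynamicConvC3k(Module):
    """CSP unit with three 1x1 convs around n dynamic bottlenecks.

    The entry 1x1 compresses channels, the main path runs the bottlenecks,
    the residual branch is a parallel 1x1 projection, and the exit 1x1
    restores the requested output width after concatenation.
    """

    def __init__(self, cin: int, cout: int, n: int = 1, shortcut: bool = True,
                 e: float = 0.5, num_experts: int = 4):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = ConvBlock(cin, c_, 1, 1)
        self.cv2 = ConvBlock(cin, c_, 1, 1)
        self.cv3 = ConvBlock(2 * c_, cout, 1, 1)
        self.m = Sequential([
            DynamicBottleneck(c_, c_, shortcut, e=1.0, num_experts=num_experts)
            for _ in range(n)
        ])

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class DynamicConvC3k2(Module):
    """Two-way CSP block (C3k2 topology) over dynamic units.

    An entry 1x1 conv adjusts channels and is split in two; the second half
    feeds a chain of n units (DynamicConvC3k when ``use_c3k`` else a single
    dynamic bottleneck each), every intermediate output is retained, and an
    exit 1x1 conv consolidates the concatenation back to ``cout`` channels.
    Spatial dimensions are preserved.

    Argument order matches the architecture table:
    (cin, cout, n, use_c3k, expansion).
    """

    def __init__(self, cin: int, cout: int, n: int = 1, use_c3k: bool = False,
                 e: float = 0.5, shortcut: bool = True, num_experts: int = 4):
        super().__init__()
        if not 0 < e <= 1:
            raise ValueError("expansion must be in (0, 1]")
        self.c = int(cout * e)
        self.cv1 = ConvBlock(cin, 2 * self.c, 1, 1)
        self.cv2 = ConvBlock((2 + n) * self.c, cout, 1)
        units = []
        for _ in range(n):
            if use_c3k:
                units.append(DynamicConvC3k(self.c, self.c, 2, shortcut,
                                            num_experts=num_experts))
            else:
                units.append(DynamicBottleneck(self.c, self.c, shortcut, e=1.0,
                                               num_experts=num_experts))
        self.m = ModuleList(units)

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        ys = [a, b]
        for m in self.m:
            ys.append(m(ys[-1]))
        return self.cv2(concat(ys, axis=1))
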