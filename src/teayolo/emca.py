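"""Efficient Mixed-pooling Channel Attention (EMCA).

A channel gate built from the sum of a global-average-pooled and a
global-max-pooled channel descriptor.  A short 1-D convolution of width k
slides across neighboring channels of that descriptor, a sigmoid squashes
the result into (0, 1), and the original feature map is rescaled
channel-wise.  Spatial dimensions and channel count are unchanged and the
head costs exactly k + 1 trainable scalars regardless of channel width.

The neighborhood width follows the adaptive mapping

    k = odd( log2(C) / gamma + b / gamma )

where ``odd`` selects an odd integer (see :func:`kernel_size` for the
rounding policy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, as_tensor
from .nn import functional as F
from .nn.module import Module, Parameter, get_rng

__all__ = ["EmcaConfig", "kernel_size", "mixed_descriptor", "EMCA"]


@dataclass
class EmcaConfig:
    gamma: float = 2.0
    b: float = 1.0
    kernel_size: int | None = None     # explicit override, must be odd
    rounding: str = "floor"            # "floor" (largest odd <= t) or "nearest"


def kernel_size(c: int, gamma: float = 2.0, b: float = 1.0,
                rounding: str = "floor") -> int:
    """Adaptive 1-D kernel width from the channel count.

    ``rounding="floor"`` returns the largest odd integer <= t (the package
    default: it keeps the head at 4 parameters for widths 64-256);
    ``rounding="nearest"`` rounds to the nearest odd integer as in the
    original efficient-channel-attention mapping.
    """
    if c < 2:
        raise ValueError("kernel_size requires at least 2 channels")
    t = math.log2(c) / gamma + b / gamma
    if rounding == "floor":
        k = int(math.floor(t))
        if k % 2 == 0:
            k -= 1
    elif rounding == "nearest":
        k = int(round(t))
        if k % 2 == 0:
            k += 1 if t >= k else -1
    else:
        raise ValueError(f"unknown rounding policy {rounding!r}")
    return max(k, 1)


def mixed_descriptor(x) -> Tensor:
    """Per-channel descriptor y[c] = GAP(x)[c] + GMP(x)[c], shape (B, C)."""
    x = as_tensor(x)
    return F.global_avg_pool(x) + F.global_max_pool(x)


class EMCA(Module):
    """Mixed-pooling channel attention head.

    The constructor takes only the channel count (as in the architecture
    table); gamma/b/rounding or an explicit kernel override come through
    :class:`EmcaConfig`.
    """

    def __init__(self, channels: int, cfg: EmcaConfig | None = None):
        super().__init__()
        cfg = cfg or EmcaConfig()
        self.channels = channels
        if cfg.kernel_size is not None:
            if cfg.kernel_size % 2 != 1 or cfg.kernel_size < 1:
                raise ValueError("kernel_size override must be odd and >= 1")
            self.k = cfg.kernel_size
        else:
            self.k = kernel_size(channels, cfg.gamma, cfg.b, cfg.rounding)
        bound = math.sqrt(1.0 / self.k)
        self.weight = Parameter(get_rng().uniform(-bound, bound, size=self.k).astype(np.float32))
        self.bias = Parameter(np.zeros(1, dtype=np.float32))

    def gates(self, x) -> Tensor:
        """Channel gates in (0, 1), shape (B, C)."""
        y = mixed_descriptor(x)
        z = F.conv1d(y, self.weight, padding=(self.k - 1) // 2)
        return (z + self.bias).sigmoid()

    def forward(self, x):
        x = as_tensor(x)
        w = self.gates(x)
        b, c = w.shape
        return x * w.reshape(b, c, 1, 1)
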