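"""Module/parameter containers, basic layers and the SGD optimizer.

Conventions follow the single-stage-detector lineage: a "Conv" block is a
bias-free convolution + per-channel batch normalization + SiLU activation,
and parameter counts are reported as raw scalar counts (normalization
contributes 2 scalars per channel; running statistics are buffers and are
not counted).
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor
from . import functional as F

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential", "Identity",
    "Conv2d", "BatchNorm2d", "Linear", "ConvBlock", "autopad",
    "SGD", "seed_all", "get_rng",
]

_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the initializer RNG; two builds after the same seed are identical."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    def __init__(self, data, requires_grad: bool = True):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=False)
        # parameters are leaves; requires_grad controls optimizer/grad flow
        self.requires_grad = bool(requires_grad)
        self._parents = ()


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = "", _seen=None):
        # modules may alias submodules (e.g. a head shortcut); count once
        seen = _seen if _seen is not None else set()
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                if id(value) not in seen:
                    seen.add(id(value))
                    yield full, value
            elif isinstance(value, Module):
                if id(value) not in seen:
                    seen.add(id(value))
                    yield from value.named_parameters(full, seen)

    def parameters(self, trainable_only: bool = False):
        for _, p in self.named_parameters():
            if not trainable_only or p.requires_grad:
                yield p

    def num_params(self, trainable_only: bool = False) -> int:
        """Total number of parameter scalars (``trainable_only`` excludes
        frozen parameters such as the fixed DFL projection)."""
        return sum(p.size for p in self.parameters(trainable_only))

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        idx = len(self._items)
        self._items.append(m)
        setattr(self, f"_m{idx}", m)
        return self

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def autopad(k: int, p=None):
    """Same-shape padding for odd kernels (detector convention)."""
    return k // 2 if p is None else p


def kaiming_conv_weight(cout: int, cin_per_group: int, kh: int, kw: int) -> np.ndarray:
    fan_in = cin_per_group * kh * kw
    bound = math.sqrt(1.0 / fan_in)
    return _RNG.uniform(-bound, bound, size=(cout, cin_per_group, kh, kw)).astype(np.float32)


class Conv2d(Module):
    """Raw convolution layer (optionally biased)."""

    def __init__(self, cin: int, cout: int, k=1, stride=1, padding=None,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        kh, kw = (k, k) if isinstance(k, int) else k
        self.stride, self.groups = stride, groups
        self.padding = autopad(kh, padding)
        if cin % groups:
            raise ValueError("in_channels must be divisible by groups")
        self.weight = Parameter(kaiming_conv_weight(cout, cin // groups, kh, kw))
        if bias:
            fan_in = (cin // groups) * kh * kw
            bound = math.sqrt(1.0 / fan_in)
            self.bias = Parameter(_RNG.uniform(-bound, bound, size=cout).astype(np.float32))
        else:
            self.bias = None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mean) / (var + self.eps).sqrt()
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True):
        super().__init__()
        bound = math.sqrt(1.0 / cin)
        self.weight = Parameter(_RNG.uniform(-bound, bound, size=(cout, cin)).astype(np.float32))
        self.bias = Parameter(_RNG.uniform(-bound, bound, size=cout).astype(np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.swapaxes(0, 1)
        if self.bias is not None:
            out = out + self.bias
        return out


class ConvBlock(Module):
    """Detector "Conv": bias-free conv2d + BatchNorm + SiLU (act=False -> none)."""

    def __init__(self, cin: int, cout: int, k=1, stride=1, padding=None,
                 groups: int = 1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.silu() if self.act else x


class SGD:
    """Plain SGD with momentum and decoupled-style weight decay."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
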