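"""Base single-stage-detector blocks the assembled network needs.

These are the building blocks of the underlying detector family (area
attention, hypergraph-based multi-scale fusion, gated full-pipeline
aggregation tunnels, depthwise-separable CSP units, and the decoupled
distribution-focal detection head).  The printed per-row parameter counts of
the architecture table are the normative contract for their configuration;
see docs/methods.md for the conventions that pin each one down.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, as_tensor, concat
from . import functional as F
from .module import (
    Module, ModuleList, Sequential, Parameter, ConvBlock, Conv2d, Linear,
    Identity, get_rng,
)

__all__ = [
    "Bottleneck", "DWConv", "DSConv", "DSBottleneck", "DSC3k",
    "AAttn", "ABlock", "A2C2f",
    "AdaHyperedgeGen", "AdaHGComputation", "C3AH", "FuseModule", "HyperACE",
    "DownsampleConv", "FullPAD_Tunnel", "Upsample", "Concat",
    "DFL", "Detect",
]


class Bottleneck(Module):
    """Standard residual bottleneck: two convs with optional shortcut."""

    def __init__(self, cin, cout, shortcut=True, g=1, k=(3, 3), e=0.5):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = ConvBlock(cin, c_, k[0], 1)
        self.cv2 = ConvBlock(c_, cout, k[1], 1, groups=g)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class DWConv(ConvBlock):
    """Depthwise convolution block (groups = channels)."""

    def __init__(self, cin, cout, k=3, stride=1, act=True):
        super().__init__(cin, cout, k, stride, groups=math.gcd(cin, cout), act=act)


class DSConv(Module):
    """Depthwise-separable conv: plain depthwise (no norm) + pointwise block."""

    def __init__(self, cin, cout, k=3, stride=1):
        super().__init__()
        self.dw = Conv2d(cin, cin, k, stride, padding=k // 2, groups=cin, bias=False)
        self.pw = ConvBlock(cin, cout, 1, 1)

    def forward(self, x):
        return self.pw(self.dw(x))


class DSBottleneck(Module):
    def __init__(self, cin, cout, shortcut=True, e=1.0, k1=3, k2=5):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = DSConv(cin, c_, k1)
        self.cv2 = DSConv(c_, cout, k2)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class DSC3k(Module):
    """C3-style CSP unit over depthwise-separable bottlenecks."""

    def __init__(self, cin, cout, n=2, shortcut=True, e=0.5, k1=3, k2=7):
        super().__init__()
        c_ = int(cout * e)
        self.cv1 = ConvBlock(cin, c_, 1, 1)
        self.cv2 = ConvBlock(cin, c_, 1, 1)
        self.cv3 = ConvBlock(2 * c_, cout, 1, 1)
        self.m = Sequential([DSBottleneck(c_, c_, shortcut, e=1.0, k1=k1, k2=k2)
                             for _ in range(n)])

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


# ---------------------------------------------------------------------------
# area attention

class AAttn(Module):
    """Area attention: multi-head self-attention restricted to contiguous
    token areas, plus a 5x5 depthwise positional conv on the values."""

    def __init__(self, dim: int, num_heads: int, area: int = 1):
        super().__init__()
        self.num_heads, self.area = num_heads, area
        self.head_dim = dim // num_heads
        self.qkv = ConvBlock(dim, dim * 3, 1, act=False)
        self.proj = ConvBlock(dim, dim, 1, act=False)
        self.pe = ConvBlock(dim, dim, 5, 1, groups=dim, act=False)

    def forward(self, x):
        x = as_tensor(x)
        B, C, H, W = x.shape
        N = H * W
        qkv = self.qkv(x).reshape(B, 3, self.num_heads, self.head_dim, N)
        q, k, v = qkv[:, 0], qkv[:, 1], qkv[:, 2]   # (B, h, hd, N)
        a = self.area if N % self.area == 0 else 1
        n = N // a
        # (B, h, hd, N) -> (B*a, h, hd, n)
        def part(t):
            return (t.reshape(B, self.num_heads, self.head_dim, a, n)
                    .transpose(0, 3, 1, 2, 4)
                    .reshape(B * a, self.num_heads, self.head_dim, n))
        qa, ka, va = part(q), part(k), part(v)
        attn = (qa.swapaxes(-1, -2) @ ka) * (self.head_dim ** -0.5)   # (Ba,h,n,n)
        attn = attn.softmax(axis=-1)
        out = va @ attn.swapaxes(-1, -2)                              # (Ba,h,hd,n)
        out = (out.reshape(B, a, self.num_heads, self.head_dim, n)
               .transpose(0, 2, 3, 1, 4)
               .reshape(B, C, H, W))
        vsp = (va.reshape(B, a, self.num_heads, self.head_dim, n)
               .transpose(0, 2, 3, 1, 4)
               .reshape(B, C, H, W))
        return self.proj(out + self.pe(vsp))


class ABlock(Module):
    """Transformer-style block: area attention + conv MLP, both residual."""

    def __init__(self, dim: int, num_heads: int, mlp_ratio: float = 2.0, area: int = 1):
        super().__init__()
        self.attn = AAttn(dim, num_heads, area)
        hidden = int(dim * mlp_ratio)
        self.mlp = Sequential([ConvBlock(dim, hidden, 1),
                               ConvBlock(hidden, dim, 1, act=False)])

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.mlp(x)


class A2C2f(Module):
    """C2f-style aggregation over pairs of area-attention blocks.

    Arguments follow the architecture table: (cin, cout, n, a2, area).
    """

    def __init__(self, cin, cout, n=1, a2=True, area=1, residual=False,
                 mlp_ratio=2.0, e=0.5, shortcut=True):
        super().__init__()
        c_ = int(cout * e)
        if a2 and c_ % 32 != 0:
            raise ValueError("area-attention width must be a multiple of 32")
        num_heads = c_ // 32
        self.cv1 = ConvBlock(cin, c_, 1, 1)
        self.cv2 = ConvBlock((1 + n) * c_, cout, 1)
        self.gamma = Parameter(0.01 * np.ones(cout, dtype=np.float32)) if a2 and residual else None
        if a2:
            self.m = ModuleList([
                Sequential([ABlock(c_, num_heads, mlp_ratio, area) for _ in range(2)])
                for _ in range(n)])
        else:
            self.m = ModuleList([DSC3k(c_, c_, 2, shortcut) for _ in range(n)])

    def forward(self, x):
        y = [self.cv1(x)]
        for m in self.m:
            y.append(m(y[-1]))
        out = self.cv2(concat(y, axis=1))
        if self.gamma is not None:
            b, c = out.shape[:2]
            return x + out * self.gamma.reshape(1, c, 1, 1)
        return out


# ---------------------------------------------------------------------------
# hypergraph-based multi-scale fusion

class AdaHyperedgeGen(Module):
    """Adaptive hyperedge participation: context-conditioned prototypes
    scored against per-node projections, softmax-normalized over nodes."""

    def __init__(self, node_dim: int, num_hyperedges: int, num_heads: int = 4,
                 context: str = "both"):
        super().__init__()
        self.num_hyperedges, self.num_heads = num_hyperedges, num_heads
        self.head_dim = node_dim // num_heads
        self.context = context
        self.prototype_base = Parameter(
            get_rng().normal(0, 0.02, size=(num_hyperedges, node_dim)).astype(np.float32))
        in_dim = 2 * node_dim if context == "both" else node_dim
        self.context_net = Linear(in_dim, num_hyperedges * node_dim)
        self.pre_head_proj = Linear(node_dim, node_dim)

    def forward(self, x):
        # x: (B, N, D)
        B, N, D = x.shape
        if self.context == "both":
            ctx = concat([x.mean(axis=1), x.max(axis=1)], axis=-1)
        elif self.context == "mean":
            ctx = x.mean(axis=1)
        else:
            ctx = x.max(axis=1)
        offsets = self.context_net(ctx).reshape(B, self.num_hyperedges, D)
        prototypes = offsets + self.prototype_base.reshape(1, self.num_hyperedges, D)
        xp = self.pre_head_proj(x)
        xh = xp.reshape(B, N, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)
        ph = prototypes.reshape(B, self.num_hyperedges, self.num_heads,
                                self.head_dim).transpose(0, 2, 3, 1)
        logits = (xh @ ph) * (self.head_dim ** -0.5)      # (B, h, N, M)
        logits = logits.mean(axis=1)                       # (B, N, M)
        return logits.softmax(axis=1)                      # over nodes


class AdaHGComputation(Module):
    """One round of node->hyperedge->node message passing with GELU
    projections and a residual connection, applied over spatial tokens."""

    def __init__(self, embed_dim: int, num_hyperedges: int, num_heads: int,
                 context: str = "both"):
        super().__init__()
        self.edge_generator = AdaHyperedgeGen(embed_dim, num_hyperedges,
                                              num_heads, context)
        self.edge_proj = Linear(embed_dim, embed_dim)
        self.node_proj = Linear(embed_dim, embed_dim)

    def forward(self, x):
        B, C, H, W = x.shape
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)    # (B, N, C)
        A = self.edge_generator(tokens)                       # (B, N, M)
        he = self.edge_proj(A.swapaxes(1, 2) @ tokens).gelu() # (B, M, C)
        upd = self.node_proj(A @ he).gelu()                   # (B, N, C)
        out = tokens + upd
        return out.transpose(0, 2, 1).reshape(B, C, H, W)


class C3AH(Module):
    """CSP wrapper around one adaptive-hypergraph computation."""

    def __init__(self, cin, cout, e=1.0, num_hyperedges=8, context="both"):
        super().__init__()
        c_ = int(cout * e)
        if c_ % 16 != 0:
            raise ValueError("hypergraph width must be a multiple of 16")
        self.cv1 = ConvBlock(cin, c_, 1, 1)
        self.cv2 = ConvBlock(cin, c_, 1, 1)
        self.m = AdaHGComputation(c_, num_hyperedges, c_ // 16, context)
        self.cv3 = ConvBlock(2 * c_, cout, 1)

    def forward(self, x):
        return self.cv3(concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class FuseModule(Module):
    """Align three pyramid levels to the middle stride and merge channels."""

    def __init__(self, c_in: int, channel_adjust: bool = True):
        super().__init__()
        self.conv_out = ConvBlock((4 if channel_adjust else 3) * c_in, c_in, 1)

    def forward(self, xs):
        x1 = F.avg_pool2d(as_tensor(xs[0]), 2)
        x2 = as_tensor(xs[1])
        x3 = F.upsample_nearest2(as_tensor(xs[2]))
        return self.conv_out(concat([x1, x2, x3], axis=1))


class HyperACE(Module):
    """Hypergraph-based adaptive correlation enhancement across scales.

    Arguments follow the architecture table:
    (cin, cout, n, num_hyperedges, dsc3k, shortcut, e1, e2, context).
    """

    def __init__(self, cin, cout, n=1, num_hyperedges=8, dsc3k=True,
                 shortcut=False, e1=0.5, e2=1.0, context="both",
                 channel_adjust=True):
        super().__init__()
        self.c = int(cout * e1)
        self.cv1 = ConvBlock(cin, 3 * self.c, 1, 1)
        self.cv2 = ConvBlock((4 + n) * self.c, cout, 1)
        self.m = ModuleList([
            DSC3k(self.c, self.c, 2, shortcut, k1=3, k2=7) if dsc3k
            else DSBottleneck(self.c, self.c, shortcut)
            for _ in range(n)])
        self.fuse = FuseModule(cin, channel_adjust)
        self.branch1 = C3AH(self.c, self.c, e2, num_hyperedges, context)
        self.branch2 = C3AH(self.c, self.c, e2, num_hyperedges, context)

    def forward(self, xs):
        x = self.fuse(xs)
        y = self.cv1(x)
        ys = [y[:, :self.c], y[:, self.c:2 * self.c], y[:, 2 * self.c:]]
        out1 = self.branch1(ys[1])
        out2 = self.branch2(ys[1])
        for m in self.m:
            ys.append(m(ys[-1]))
        ys[1] = out1
        ys.append(out2)
        return self.cv2(concat(ys, axis=1))


class DownsampleConv(Module):
    """2x average-pool downsample with channel doubling."""

    def __init__(self, cin: int, channel_adjust: bool = True):
        super().__init__()
        self.channel_adjust = (ConvBlock(cin, cin * 2, 1) if channel_adjust
                               else Identity())

    def forward(self, x):
        return self.channel_adjust(F.avg_pool2d(as_tensor(x), 2))


class FullPAD_Tunnel(Module):
    """Gated residual fusion of a pipeline feature with a correlation-
    enhanced feature: out = x0 + gate * x1, gate a learned scalar."""

    def __init__(self):
        super().__init__()
        self.gate = Parameter(np.zeros(1, dtype=np.float32))

    def forward(self, xs):
        return as_tensor(xs[0]) + self.gate.reshape(1, 1, 1, 1) * as_tensor(xs[1])


class Upsample(Module):
    def __init__(self, size=None, scale_factor=2, mode="nearest"):
        super().__init__()
        if size is not None or scale_factor != 2 or mode != "nearest":
            raise NotImplementedError("only nearest x2 upsampling is used")

    def forward(self, x):
        return F.upsample_nearest2(as_tensor(x))


class Concat(Module):
    def __init__(self, axis=1):
        super().__init__()
        self.axis = axis

    def forward(self, xs):
        return concat([as_tensor(x) for x in xs], axis=self.axis)


class DFL(Module):
    """Distribution-focal projection: softmax over reg_max bins -> expected
    offset.  The projection weights are the fixed ramp 0..reg_max-1 and are
    counted as parameters but excluded from gradients."""

    def __init__(self, c1: int = 16):
        super().__init__()
        self.c1 = c1
        self.weight = Parameter(np.arange(c1, dtype=np.float32), requires_grad=False)

    def forward(self, x):
        # x: (B, 4*c1, A) -> (B, 4, A) expected ltrb offsets
        B, _, A = x.shape
        x = x.reshape(B, 4, self.c1, A)
        p = x.softmax(axis=2)
        return (p * self.weight.reshape(1, 1, self.c1, 1)).sum(axis=2)


class Detect(Module):
    """Decoupled three-scale detection head with distribution-focal boxes.

    Per level: a regression branch emitting 4*reg_max bin logits and a
    depthwise-separable classification branch emitting nc class logits.
    """

    def __init__(self, nc: int = 3, ch=(64, 128, 256), reg_max: int = 16,
                 strides=(8, 16, 32)):
        super().__init__()
        self.nc, self.reg_max = nc, reg_max
        self.nl = len(ch)
        self.no = nc + reg_max * 4
        self.strides = tuple(strides)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = ModuleList([
            Sequential([ConvBlock(x, c2, 3), ConvBlock(c2, c2, 3),
                        Conv2d(c2, 4 * reg_max, 1, bias=True)])
            for x in ch])
        self.cv3 = ModuleList([
            Sequential([
                Sequential([DWConv(x, x, 3), ConvBlock(x, c3, 1)]),
                Sequential([DWConv(c3, c3, 3), ConvBlock(c3, c3, 1)]),
                Conv2d(c3, nc, 1, bias=True)])
            for x in ch])
        self.dfl = DFL(reg_max)
        # prior-aware bias init: boxes near 1 cell, rare-class logits
        for branch in self.cv2:
            branch[-1].bias.data[:] = 1.0
        for branch in self.cv3:
            branch[-1].bias.data[:] = -4.0

    def forward(self, xs):
        """Raw per-level maps (B, 4*reg_max + nc, H, W)."""
        return [concat([self.cv2[i](x), self.cv3[i](x)], axis=1)
                for i, x in enumerate(xs)]

    # -- inference decoding ---------------------------------------------------
    def anchor_points(self, shapes):
        """Cell-center anchor points in image pixels per level."""
        pts = []
        for (h, w), s in zip(shapes, self.strides):
            ys, xs_ = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            pts.append(np.stack([(xs_.ravel() + 0.5) * s, (ys.ravel() + 0.5) * s], axis=1))
        return pts

    def decode(self, outputs, conf_threshold=0.25):
        """Decode raw maps into (boxes xyxy, scores, classes) per image."""
        from ..metrics import nms  # local import to avoid a cycle
        B = outputs[0].shape[0]
        results = []
        per_level = []
        for out, s in zip(outputs, self.strides):
            data = out.data if isinstance(out, Tensor) else out
            b, _, h, w = data.shape
            flat = data.reshape(b, self.no, h * w)
            box_logits = Tensor(flat[:, : 4 * self.reg_max])
            ltrb = self.dfl(box_logits).data * s          # (B, 4, A)
            cls = 1.0 / (1.0 + np.exp(-flat[:, 4 * self.reg_max:]))
            anchors = self.anchor_points([(h, w)])[0]      # (A, 2)
            x1 = anchors[None, :, 0] - ltrb[:, 0]
            y1 = anchors[None, :, 1] - ltrb[:, 1]
            x2 = anchors[None, :, 0] + ltrb[:, 2]
            y2 = anchors[None, :, 1] + ltrb[:, 3]
            boxes = np.stack([x1, y1, x2, y2], axis=-1)    # (B, A, 4)
            per_level.append((boxes, cls))
        for i in range(B):
            boxes = np.concatenate([b[i] for b, _ in per_level], axis=0)
            cls = np.concatenate([c[i].T for _, c in per_level], axis=0)  # (A, nc)
            conf = cls.max(axis=1)
            labels = cls.argmax(axis=1)
            keep = conf >= conf_threshold
            boxes, conf, labels = boxes[keep], conf[keep], labels[keep]
            keep = nms(boxes, conf, iou_threshold=0.45)
            results.append((boxes[keep], conf[keep], labels[keep]))
        return results
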