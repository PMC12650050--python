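"""Scale-based Dynamic Loss (SDL) for bounding-box regression.

The complete-IoU (CIoU) loss is split into two complementary terms:

* scale term      L_BS = 1 - IoU + alpha * v   (overlap + aspect consistency)
* localization    L_BL = rho^2(b_p, b_gt) / c^2 (normalized center distance)

with the standard CIoU definitions
v = (4/pi^2) (arctan(w_gt/h_gt) - arctan(w_p/h_p))^2 and
alpha = v / ((1 - IoU) + v).

Each term is weighted by a scale-dependent coefficient.  Let A be the
ground-truth box area mapped to original-image pixels via the
resolution-of-cells factor ROC = (w_o * h_o) / (w_c * h_c).  Below the
small-target bound (81 px^2, the 9x9-pixel infrared-small-target
convention) the base coefficient is

    beta_B = min(A / A_max * delta, delta),      delta in (0, 1]

and above the bound both coefficients become exactly 1, so the loss
degenerates to CIoU for ordinary targets.  Two policies translate beta_B
into the pair (beta_BS, beta_BL):

* ``asymmetric`` (default): beta_BS = beta_B, beta_BL = 2 - beta_B —
  small targets get a relaxed scale constraint and an amplified
  localization constraint, continuous with CIoU at delta = 1.
* ``uniform``: both coefficients equal beta_B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, as_tensor

__all__ = [
    "Box", "ScaleContext", "LossBreakdown",
    "iou", "ciou_terms", "scale_factor", "dynamic_beta", "sdl_total",
    "sdl_loss_tensor", "SMALL_TARGET_AREA",
]

SMALL_TARGET_AREA = 81.0  # px^2, 9x9 small-target bound


@dataclass
class Box:
    """Axis-aligned box, center/size parameterization, pixel units."""
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def xyxy(self):
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass
class ScaleContext:
    """Scale bookkeeping for one feature level.

    wo/ho: original image dims (px); wc/hc: feature-map dims (cells);
    delta: dynamic-amplitude upper bound in (0, 1]; bgt_max: small-target
    area bound in image px^2; policy: "asymmetric" or "uniform";
    gt_frame: coordinate frame of the ground-truth box passed to
    :func:`sdl_total` — "feature" (areas are multiplied by ROC) or "image".
    """
    wo: float
    ho: float
    wc: float
    hc: float
    delta: float = 1.0
    bgt_max: float = SMALL_TARGET_AREA
    policy: str = "asymmetric"
    gt_frame: str = "feature"

    def __post_init__(self):
        if min(self.wo, self.ho, self.wc, self.hc) <= 0:
            raise ValueError("all dimensions must be positive")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")
        if self.policy not in ("asymmetric", "uniform"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass
class LossBreakdown:
    iou: float
    v: float
    alpha_ciou: float
    l_bs: float
    l_bl: float
    beta_bs: float
    beta_bl: float
    total: float


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes."""
    ax1, ay1, ax2, ay2 = a.xyxy
    bx1, by1, bx2, by2 = b.xyxy
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    # rounding can push inter a hair past union for identical boxes
    return min(1.0, max(0.0, inter / union))


def ciou_terms(pred: Box, gt: Box) -> tuple[float, float]:
    """CIoU decomposition: (scale term L_BS, localization term L_BL)."""
    i = iou(pred, gt)
    v = (4.0 / math.pi ** 2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = v / ((1.0 - i) + v) if v > 0 else 0.0
    l_bs = 1.0 - i + alpha * v

    px1, py1, px2, py2 = pred.xyxy
    gx1, gy1, gx2, gy2 = gt.xyxy
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    l_bl = rho2 / (cw ** 2 + ch ** 2)
    return l_bs, l_bl


def ciou_loss(pred: Box, gt: Box) -> float:
    """Plain CIoU loss = L_BS + L_BL."""
    l_bs, l_bl = ciou_terms(pred, gt)
    return l_bs + l_bl


def scale_factor(ctx: ScaleContext) -> float:
    """ROC: original-image area per feature-map cell area."""
    return (ctx.wo * ctx.ho) / (ctx.wc * ctx.hc)


def dynamic_beta(area_gt: float, ctx: ScaleContext) -> tuple[float, float]:
    """Dynamic coefficients (beta_bs, beta_bl) for a ground-truth area.

    ``area_gt`` is measured in the frame declared by ``ctx.gt_frame``:
    feature-scale areas are mapped to image pixels by ROC before the
    small-target comparison.
    """
    if area_gt < 0:
        raise ValueError("area must be non-negative")
    roc = scale_factor(ctx)
    area_img = area_gt * roc if ctx.gt_frame == "feature" else area_gt
    if area_img > ctx.bgt_max:
        return 1.0, 1.0
    beta = min(area_img / ctx.bgt_max * ctx.delta, ctx.delta)
    if ctx.policy == "uniform":
        return beta, beta
    return beta, 2.0 - beta


def sdl_total(pred: Box, gt: Box, ctx: ScaleContext) -> LossBreakdown:
    """Full scale-based dynamic loss for one matched box pair.

    Boxes are in the frame declared by ``ctx.gt_frame``; every intermediate
    quantity is returned for inspection.
    """
    i = iou(pred, gt)
    v = (4.0 / math.pi ** 2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = v / ((1.0 - i) + v) if v > 0 else 0.0
    l_bs, l_bl = ciou_terms(pred, gt)
    beta_bs, beta_bl = dynamic_beta(gt.area, ctx)
    total = beta_bs * l_bs + beta_bl * l_bl
    return LossBreakdown(iou=i, v=v, alpha_ciou=alpha, l_bs=l_bs, l_bl=l_bl,
                         beta_bs=beta_bs, beta_bl=beta_bl, total=total)


# ---------------------------------------------------------------------------
# batched, differentiable path used by the training harness

def sdl_loss_tensor(pred, gt, ctx: ScaleContext, weights=None) -> Tensor:
    """Mean SDL over matched pairs, differentiable w.r.t. predictions.

    pred: Tensor (N, 4) cxcywh; gt: array (N, 4) cxcywh (same frame as
    declared in ctx); weights: optional per-pair weights.
    """
    pred = as_tensor(pred)
    gt = np.asarray(gt, dtype=pred.dtype)
    eps = 1e-9

    pcx, pcy = pred[:, 0], pred[:, 1]
    pw = pred[:, 2].clamp(lo=eps)
    ph = pred[:, 3].clamp(lo=eps)
    gcx, gcy, gw, gh = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]

    px1, px2 = pcx - pw * 0.5, pcx + pw * 0.5
    py1, py2 = pcy - ph * 0.5, pcy + ph * 0.5
    gx1, gx2 = gcx - gw * 0.5, gcx + gw * 0.5
    gy1, gy2 = gcy - gh * 0.5, gcy + gh * 0.5

    iw = (px2.minimum(Tensor(gx2)) - px1.maximum(Tensor(gx1))).clamp(lo=0.0)
    ih = (py2.minimum(Tensor(gy2)) - py1.maximum(Tensor(gy1))).clamp(lo=0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter + eps
    iou_t = (inter / union).clamp(0.0, 1.0)

    atan_g = np.arctan(gw / gh)
    v = ((as_tensor(atan_g) - (pw / ph).arctan()) ** 2) * (4.0 / math.pi ** 2)
    alpha = v / ((1.0 - iou_t) + v + eps)
    l_bs = 1.0 - iou_t + alpha * v

    cw = px2.maximum(Tensor(gx2)) - px1.minimum(Tensor(gx1))
    chh = py2.maximum(Tensor(gy2)) - py1.minimum(Tensor(gy1))
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    l_bl = rho2 / (cw ** 2 + chh ** 2 + eps)

    betas = np.array([dynamic_beta(float(w * h), ctx) for w, h in zip(gt[:, 2], gt[:, 3])],
                     dtype=pred.dtype)
    loss = l_bs * betas[:, 0] + l_bl * betas[:, 1]
    if weights is not None:
        w = np.asarray(weights, dtype=pred.dtype)
        return (loss * w).sum() / (w.sum() + eps)
    return loss.mean()
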