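"""Desk-scale training harness: target assignment, composite detection
loss (scale-based dynamic box loss + BCE classification + distribution-
focal regression), SGD, and the end-to-end smoke run.

The assigner is a simple anchor-free center assigner: every ground truth
becomes a positive at the feature cell containing its center, at each
pyramid level (first ground truth wins a contested cell).  The box term is
the scale-based dynamic loss evaluated in feature-cell coordinates with the
level's resolution-of-cells factor, so the small-target reweighting engages
exactly as it would in full training; classification and distribution-focal
terms follow the base-detector convention, with loss gains box 7.5 /
cls 0.5 / dfl 1.5.

Full-schedule training (batch 16, 500 epochs, SGD lr 0.01, weight decay
0.001) is out of desk scope; those values are kept as defaults in
:class:`TrainConfig` for reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, concat
from .nn.module import SGD
from .sdl_loss import ScaleContext, sdl_loss_tensor
from .datasets import DetectionSample

__all__ = ["TrainConfig", "assign_targets", "detection_loss", "train_smoke",
           "box_loss_decreased"]


@dataclass
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.001
    batch_size: int = 16
    epochs: int = 500
    box_gain: float = 7.5
    cls_gain: float = 0.5
    dfl_gain: float = 1.5
    delta: float = 1.0
    sdl_policy: str = "asymmetric"
    use_sdl: bool = True     # False -> plain CIoU box loss


def batch_images(samples: list[DetectionSample]) -> np.ndarray:
    """Stack samples into a normalized (B, 3, H, W) float array."""
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    return imgs.transpose(0, 3, 1, 2)


def assign_targets(samples, img_shape, strides=(8, 16, 32)):
    """Center-cell assignment at every level.

    Returns per level a dict with positive indices (b, cell), ltrb targets
    in cells, gt boxes cxcywh in cells, and class ids.
    """
    H, W = img_shape
    out = []
    for s in strides:
        hc, wc = H // s, W // s
        taken = {}
        for b, sample in enumerate(samples):
            for cid, cxn, cyn, wn, hn in sample.labels:
                cx, cy = cxn * W / s, cyn * H / s      # cell units
                bw, bh = max(wn * W / s, 1e-3), max(hn * H / s, 1e-3)
                ix, iy = min(int(cx), wc - 1), min(int(cy), hc - 1)
                key = (b, iy * wc + ix)
                if key in taken:
                    continue
                ax, ay = ix + 0.5, iy + 0.5
                ltrb = (ax - (cx - bw / 2), ay - (cy - bh / 2),
                        (cx + bw / 2) - ax, (cy + bh / 2) - ay)
                taken[key] = (cid, (cx, cy, bw, bh), ltrb)
        idx_b = np.array([k[0] for k in taken], dtype=int)
        idx_cell = np.array([k[1] for k in taken], dtype=int)
        out.append({
            "stride": s, "hc": hc, "wc": wc,
            "idx_b": idx_b, "idx_cell": idx_cell,
            "cls": np.array([v[0] for v in taken.values()], dtype=int),
            "gt_cells": np.array([v[1] for v in taken.values()], dtype=float).reshape(-1, 4),
            "ltrb": np.array([v[2] for v in taken.values()], dtype=float).reshape(-1, 4),
        })
    return out


def _bce_with_logits(z: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits."""
    return (z.clamp(lo=0.0) - z * y + ((-(z.abs())).exp() + 1.0).log()).mean()


def _dfl_term(logits: Tensor, targets: np.ndarray, reg_max: int) -> Tensor:
    """Distribution-focal loss: CE against the two bins flanking each
    continuous ltrb target.  logits: (P, 4, reg_max); targets: (P, 4)."""
    t = np.clip(targets, 0.0, reg_max - 1 - 1e-3)
    lo = np.floor(t).astype(int)
    hi = lo + 1
    wl = hi - t
    wh = t - lo
    logp = logits.softmax(axis=2).clamp(lo=1e-9).log()     # (P, 4, reg_max)
    pi, si = np.meshgrid(np.arange(t.shape[0]), np.arange(4), indexing="ij")
    ll = logp[pi, si, lo]
    lh = logp[pi, si, np.minimum(hi, reg_max - 1)]
    return -(ll * wl + lh * wh).mean()


def detection_loss(outputs, samples, img_shape, detect, cfg: TrainConfig):
    """Composite loss over raw per-level head outputs.

    Returns (total Tensor, components dict of floats).
    """
    H, W = img_shape
    reg_max = detect.reg_max
    nc = detect.nc
    targets = assign_targets(samples, img_shape, detect.strides)

    cls_losses, box_losses, dfl_losses = [], [], []
    n_pos_total = 0
    for out, tgt in zip(outputs, targets):
        B, no, hc, wc = out.shape
        flat = out.reshape(B, no, hc * wc).transpose(0, 2, 1)   # (B, A, no)
        cls_logits = flat[:, :, 4 * reg_max:]
        y = np.zeros((B, hc * wc, nc), dtype=np.float32)
        if tgt["idx_b"].size:
            y[tgt["idx_b"], tgt["idx_cell"], tgt["cls"]] = 1.0
        cls_losses.append(_bce_with_logits(cls_logits, y))

        P = tgt["idx_b"].size
        if P == 0:
            continue
        n_pos_total += P
        pos = flat[tgt["idx_b"], tgt["idx_cell"]]               # (P, no)
        box_logits = pos[:, : 4 * reg_max].reshape(P, 4, reg_max)
        dfl_losses.append(_dfl_term(box_logits, tgt["ltrb"], reg_max))

        # decode: expectation over bins -> ltrb (cells) -> cxcywh (cells)
        probs = box_logits.softmax(axis=2)
        ramp = np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max)
        ltrb = (probs * ramp).sum(axis=2)                       # (P, 4)
        ax = (tgt["idx_cell"] % tgt["wc"]) + 0.5
        ay = (tgt["idx_cell"] // tgt["wc"]) + 0.5
        l, t_, r, b_ = ltrb[:, 0], ltrb[:, 1], ltrb[:, 2], ltrb[:, 3]
        cx = ((r - l) * 0.5) + ax
        cy = ((b_ - t_) * 0.5) + ay
        bw = (l + r).clamp(lo=1e-3)
        bh = (t_ + b_).clamp(lo=1e-3)
        pred = concat([t.reshape(P, 1) for t in (cx, cy, bw, bh)], axis=1)
        ctx = ScaleContext(wo=W, ho=H, wc=tgt["wc"], hc=tgt["hc"],
                           delta=cfg.delta, policy=cfg.sdl_policy,
                           gt_frame="feature")
        if not cfg.use_sdl:
            ctx = ScaleContext(wo=W, ho=H, wc=tgt["wc"], hc=tgt["hc"],
                               delta=1.0, policy="uniform", gt_frame="feature",
                               bgt_max=1e-9)  # every target "large" -> CIoU
        box_losses.append(sdl_loss_tensor(pred, tgt["gt_cells"], ctx))

    cls_loss = sum(cls_losses[1:], cls_losses[0]) / len(cls_losses)
    if box_losses:
        box_loss = sum(box_losses[1:], box_losses[0]) / len(box_losses)
        dfl_loss = sum(dfl_losses[1:], dfl_losses[0]) / len(dfl_losses)
    else:
        box_loss = Tensor(np.zeros(()))
        dfl_loss = Tensor(np.zeros(()))
    total = cfg.box_gain * box_loss + cfg.cls_gain * cls_loss + cfg.dfl_gain * dfl_loss
    comps = {"box": float(box_loss.data), "cls": float(cls_loss.data),
             "dfl": float(dfl_loss.data), "total": float(total.data),
             "n_pos": n_pos_total}
    return total, comps


class NonFiniteLoss(RuntimeError):
    pass


def train_smoke(model, dataset: list[DetectionSample], steps: int = 200,
                cfg: TrainConfig | None = None, batch_size: int = 2,
                lr: float = 0.01, seed: int = 0, verbose: bool = False):
    """Seeded short training run; returns the per-step loss trace.

    Aborts with diagnostics on a non-finite loss.  ``lr`` overrides the
    config default for desk-scale stability.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("empty dataset")
    H, W = dataset[0].image.shape[:2]
    opt = SGD(model.parameters(), lr=lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(seed)
    model.train()
    trace = []
    for step in range(steps):
        idx = rng.integers(0, len(dataset), size=batch_size)
        samples = [dataset[i] for i in idx]
        x = Tensor(batch_images(samples))
        outputs = model(x)
        total, comps = detection_loss(outputs, samples, (H, W), model.detect, cfg)
        if not np.isfinite(comps["total"]):
            raise NonFiniteLoss(f"non-finite loss at step {step}: {comps}")
        opt.zero_grad()
        total.backward()
        opt.step()
        comps["step"] = step
        trace.append(comps)
        if verbose and step % 20 == 0:
            print(f"step {step:4d}  box {comps['box']:.4f}  "
                  f"cls {comps['cls']:.4f}  dfl {comps['dfl']:.4f}")
    return trace


def box_loss_decreased(trace, key: str = "box") -> bool:
    """True when the last-quartile mean of a loss component is below the
    first-quartile mean."""
    vals = np.array([t[key] for t in trace], dtype=float)
    q = max(len(vals) // 4, 1)
    return float(vals[-q:].mean()) < float(vals[:q].mean())
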