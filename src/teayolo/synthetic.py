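"""Seeded synthetic tea-scene generator.

Emulates the statistical structure of a UAV tea-canopy detection dataset —
three classes (tender bud / one bud one leaf / one bud two leaves), a target
size distribution skewed toward small areas (configurable fraction below the
81 px^2 small-target bound), partial occlusion and illumination variation —
without any photo-realism.  Classes are encoded by shape: a bud is a small
bright ellipse cluster; the leaf classes add one or two elongated lobes, so
a small model can separate them within a smoke run.

All randomness flows from one seed through ``numpy`` generators, so a
dataset, or any single scene, is exactly reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import (DetectionSample, save_sample, write_dataset_config,
                       read_labels)

__all__ = ["SceneConfig", "generate_scene", "generate_dataset", "CLASS_NAMES"]

CLASS_NAMES = ("tender_bud", "one_bud_one_leaf", "one_bud_two_leaves")


@dataclass
class SceneConfig:
    """Knobs of one synthetic scene (defaults emulate the field conditions).

    ``small_fraction`` is the probability that a target's box area falls
    below ``small_area_bound`` px^2; the remaining targets draw a log-
    uniform area up to ``max_area``.  ``class_mixture`` must sum to 1.
    """
    image_size: tuple[int, int] = (160, 160)
    n_objects: tuple[int, int] = (3, 8)         # uniform inclusive range
    class_mixture: tuple[float, ...] = (0.27, 0.37, 0.36)
    small_fraction: float = 0.55
    small_area_bound: float = 81.0
    max_area: float = 1600.0
    occlusion_prob: float = 0.25
    clutter: float = 0.5                         # background texture amplitude
    illumination_jitter: float = 0.25
    blur_sigma_range: tuple[float, float] = (0.0, 0.8)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mixture) - 1.0) > 1e-6:
            raise ValueError("class mixture must sum to 1")
        if not 0 <= self.small_fraction <= 1 or not 0 <= self.occlusion_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


def _background(rng, h, w, clutter):
    """Low-frequency green-brown canopy-like texture."""
    base = np.empty((h, w, 3))
    base[..., 0] = 55
    base[..., 1] = 95
    base[..., 2] = 45
    for _ in range(6):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        sig = rng.uniform(0.15, 0.4) * max(h, w)
        amp = rng.uniform(-30, 30) * clutter
        yy, xx = np.mgrid[0:h, 0:w]
        blob = amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2)))
        base[..., 1] += blob
        base[..., 0] += 0.4 * blob
    base += rng.normal(0, 8 * clutter, size=(h, w, 3))
    return base


def _ellipse_mask(h, w, cy, cx, ry, rx, angle):
    yy, xx = np.mgrid[0:h, 0:w]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / max(rx, 0.5)) ** 2 + (v / max(ry, 0.5)) ** 2 <= 1.0


def _draw_target(img, rng, cid, cx, cy, bw, bh):
    """Paint one class-coded composite shape inside box (cx, cy, bw, bh)."""
    h, w = img.shape[:2]
    # bud: bright yellow-green ellipse cluster in the box center
    bud_rx, bud_ry = max(bw * 0.22, 0.6), max(bh * 0.30, 0.6)
    color_bud = np.array([170, 210, 90]) + rng.normal(0, 8, 3)
    for k in range(2):
        off = rng.normal(0, 0.06, 2) * [bw, bh]
        m = _ellipse_mask(h, w, cy + off[1] - (k - 0.5) * bud_ry * 0.6,
                          cx + off[0], bud_ry * 0.8, bud_rx, rng.uniform(-0.4, 0.4))
        img[m] = color_bud * rng.uniform(0.92, 1.08)
    # leaf lobes: elongated darker-green ellipses flanking the bud
    n_lobes = cid  # 0, 1 or 2
    color_leaf = np.array([60, 150, 60]) + rng.normal(0, 8, 3)
    for k in range(n_lobes):
        side = -1 if k == 0 else 1
        ang = side * rng.uniform(0.5, 1.1)
        m = _ellipse_mask(h, w, cy + bh * 0.18,
                          cx + side * bw * 0.26,
                          bh * 0.42, bw * 0.18, ang)
        img[m] = color_leaf * rng.uniform(0.9, 1.1)


def _sample_box_area(rng, cfg: SceneConfig) -> float:
    if rng.random() < cfg.small_fraction:
        return rng.uniform(9.0, cfg.small_area_bound * 0.98)
    lo, hi = np.log(cfg.small_area_bound), np.log(cfg.max_area)
    return float(np.exp(rng.uniform(lo, hi)))


def generate_scene(cfg: SceneConfig, seed: int | None = None) -> DetectionSample:
    """One textured scene with exact labels; deterministic under the seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    h, w = cfg.image_size
    img = _background(rng, h, w, cfg.clutter)

    n = int(rng.integers(cfg.n_objects[0], cfg.n_objects[1] + 1))
    labels = []
    placed = []
    for _ in range(n):
        cid = int(rng.choice(len(cfg.class_mixture), p=cfg.class_mixture))
        area = _sample_box_area(rng, cfg)
        aspect = rng.uniform(0.6, 1.6)
        bw = float(np.clip(np.sqrt(area * aspect), 3, w * 0.45))
        bh = float(np.clip(area / bw, 3, h * 0.45))
        if placed and rng.random() < cfg.occlusion_prob:
            # overlap a previous target
            pcx, pcy, pbw, pbh = placed[-1]
            cx = float(np.clip(pcx + rng.uniform(-0.6, 0.6) * pbw, bw / 2, w - bw / 2))
            cy = float(np.clip(pcy + rng.uniform(-0.6, 0.6) * pbh, bh / 2, h - bh / 2))
        else:
            cx = rng.uniform(bw / 2, w - bw / 2)
            cy = rng.uniform(bh / 2, h - bh / 2)
        _draw_target(img, rng, cid, cx, cy, bw, bh)
        placed.append((cx, cy, bw, bh))
        labels.append((cid, cx / w, cy / h, bw / w, bh / h))

    # illumination variation + mild blur
    img *= rng.uniform(1 - cfg.illumination_jitter, 1 + cfg.illumination_jitter)
    sigma = rng.uniform(*cfg.blur_sigma_range)
    if sigma > 0.05:
        from scipy import ndimage
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], sigma)
    img = np.clip(img, 0, 255).round().astype(np.uint8)
    return DetectionSample(image=img, labels=labels)


def generate_dataset(cfg: SceneConfig, n_images: int, root,
                     split_ratio: float = 0.8, class_names=CLASS_NAMES):
    """Write images/ + labels/ + dataset.yaml and a label-count summary.

    The first ``round(n * split_ratio)`` scenes go to train, the rest to
    val (scenes are i.i.d., so the order split is itself random).
    Returns a summary dict with per-class counts per split.
    """
    if n_images < 1:
        raise ValueError("need at least one image")
    root = Path(root)
    n_train = int(round(n_images * split_ratio))
    counts = {s: [0] * len(class_names) for s in ("train", "val")}
    master = np.random.default_rng(cfg.seed)
    for i in range(n_images):
        split = "train" if i < n_train else "val"
        scene_seed = int(master.integers(0, 2 ** 31 - 1))
        sample = generate_scene(cfg, seed=scene_seed)
        save_sample(sample,
                    root / "images" / split / f"scene_{i:05d}.png",
                    root / "labels" / split / f"scene_{i:05d}.txt")
        for lab in sample.labels:
            counts[split][lab[0]] += 1
    write_dataset_config(root, class_names)
    summary = {"n_train": n_train, "n_val": n_images - n_train,
               "class_names": list(class_names), "counts": counts}
    with open(root / "label_summary.csv", "w", newline="") as f:
        wtr = csv.writer(f)
        wtr.writerow(["class", "train_labels", "val_labels", "total"])
        for i, name in enumerate(class_names):
            wtr.writerow([name, counts["train"][i], counts["val"][i],
                          counts["train"][i] + counts["val"][i]])
    return summary
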