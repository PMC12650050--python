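"""Dataset plumbing: normalized-label I/O, config files, five-fold splits.

Labels follow the one-file-per-image text convention: each line holds
``class_id cx cy w h`` with box center/size normalized to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "DetectionSample", "read_labels", "write_labels", "load_sample",
    "save_sample", "write_dataset_config", "load_dataset", "five_fold_split",
    "kfold_pairs",
]


@dataclass
class DetectionSample:
    """Image (H, W, 3 uint8) plus normalized (class_id, cx, cy, w, h) labels."""
    image: np.ndarray
    labels: list[tuple[int, float, float, float, float]] = field(default_factory=list)

    @property
    def height(self):
        return self.image.shape[0]

    @property
    def width(self):
        return self.image.shape[1]

    def boxes_pixels(self) -> np.ndarray:
        """Labels as (N, 5) array [class, cx, cy, w, h] in pixel units."""
        if not self.labels:
            return np.zeros((0, 5))
        arr = np.array(self.labels, dtype=float)
        arr[:, [1, 3]] *= self.width
        arr[:, [2, 4]] *= self.height
        return arr


def read_labels(path) -> list[tuple[int, float, float, float, float]]:
    labels = []
    text = Path(path).read_text() if Path(path).exists() else ""
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        cid = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:5])
        labels.append((cid, cx, cy, w, h))
    return labels


def write_labels(path, labels) -> None:
    lines = [f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
             for c, cx, cy, w, h in labels]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def load_sample(image_path, label_path=None) -> DetectionSample:
    image_path = Path(image_path)
    if label_path is None:
        label_path = image_path.parent.parent / "labels" / (image_path.stem + ".txt")
    img = np.asarray(Image.open(image_path).convert("RGB"))
    return DetectionSample(image=img, labels=read_labels(label_path))


def save_sample(sample: DetectionSample, image_path, label_path=None) -> None:
    image_path = Path(image_path)
    image_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(sample.image).save(image_path)
    if label_path is None:
        label_path = image_path.parent.parent / "labels" / (image_path.stem + ".txt")
    Path(label_path).parent.mkdir(parents=True, exist_ok=True)
    write_labels(label_path, sample.labels)


def write_dataset_config(root, names, train="images/train", val="images/val") -> Path:
    root = Path(root)
    cfg = {"path": str(root), "train": train, "val": val,
           "names": {i: n for i, n in enumerate(names)}, "nc": len(names)}
    out = root / "dataset.yaml"
    out.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return out


def load_dataset(root, split="train") -> list[DetectionSample]:
    root = Path(root)
    img_dir = root / "images" / split
    lbl_dir = root / "labels" / split
    samples = []
    for p in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg")):
        samples.append(load_sample(p, lbl_dir / (p.stem + ".txt")))
    return samples


def five_fold_split(items, seed: int = 0) -> list[list]:
    """Random partition into five disjoint folds of near-equal size.

    Fold sizes differ by at most one; the union is the input.  Deterministic
    for a given seed.
    """
    items = list(items)
    n = len(items)
    if n < 5:
        raise ValueError(f"need at least 5 items to build 5 folds, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    bounds = np.linspace(0, n, 6).round().astype(int)
    return [[items[i] for i in order[bounds[k]:bounds[k + 1]]] for k in range(5)]


def kfold_pairs(items, seed: int = 0):
    """Rotate the five folds into (train, validation) pairs."""
    folds = five_fold_split(items, seed)
    pairs = []
    for k in range(5):
        val = folds[k]
        train = [x for j, f in enumerate(folds) if j != k for x in f]
        pairs.append((train, val))
    return pairs
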