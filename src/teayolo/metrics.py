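"""Detection evaluation: greedy IoU matching, P/R/F1, AP, mAP@0.5,
confusion matrix, and non-maximum suppression.

Definitions: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean (zero denominators give 0).  AP is the area under the precision-recall
curve of one class; mAP is the arithmetic mean over classes.  Matching is
greedy in descending confidence: a prediction claims the highest-IoU unmatched
ground truth of its class with IoU >= threshold; every ground truth is
claimed at most once.  Defaults: IoU 0.5, confidence 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import five_fold_split, kfold_pairs  # re-exported

__all__ = [
    "box_iou_xyxy", "nms", "MatchResult", "match_detections", "prf",
    "average_precision", "mean_average_precision", "confusion_matrix",
    "EvalReport", "evaluate", "five_fold_split", "kfold_pairs",
    "plot_confusion_matrix",
]


def box_iou_xyxy(a, b) -> np.ndarray:
    """Pairwise IoU between (N, 4) and (M, 4) xyxy boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(br - tl, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)


def nms(boxes, scores, iou_threshold: float = 0.45) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices."""
    boxes = np.asarray(boxes, dtype=float)
    order = np.argsort(np.asarray(scores))[::-1]
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        ious = box_iou_xyxy(boxes[i][None], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_threshold]
    return np.array(keep, dtype=int)


@dataclass
class MatchResult:
    tp: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)

    def totals(self):
        classes = set(self.tp) | set(self.fp) | set(self.fn)
        return (sum(self.tp.get(c, 0) for c in classes),
                sum(self.fp.get(c, 0) for c in classes),
                sum(self.fn.get(c, 0) for c in classes))


def _greedy_match(pred_boxes, pred_scores, gt_boxes, iou_threshold):
    """Greedy one-to-one matching by descending confidence.

    Returns for each prediction the matched gt index or -1.
    """
    order = np.argsort(-np.asarray(pred_scores), kind="stable")
    assigned = np.full(len(pred_boxes), -1, dtype=int)
    taken = np.zeros(len(gt_boxes), dtype=bool)
    if len(gt_boxes) == 0 or len(pred_boxes) == 0:
        return assigned
    ious = box_iou_xyxy(pred_boxes, gt_boxes)
    for i in order:
        cand = np.where(~taken & (ious[i] >= iou_threshold))[0]
        if cand.size:
            j = cand[np.argmax(ious[i][cand])]
            assigned[i] = j
            taken[j] = True
    return assigned


def match_detections(preds, gts, iou_threshold: float = 0.5,
                     confidence_threshold: float = 0.25) -> MatchResult:
    """Per-class TP/FP/FN for one image.

    preds: iterable of (class_id, confidence, x1, y1, x2, y2);
    gts: iterable of (class_id, x1, y1, x2, y2) in the same pixel frame.
    """
    preds = [p for p in preds if p[1] >= confidence_threshold]
    res = MatchResult()
    classes = sorted({int(p[0]) for p in preds} | {int(g[0]) for g in gts})
    for c in classes:
        pc = [p for p in preds if int(p[0]) == c]
        gc = [g for g in gts if int(g[0]) == c]
        pb = np.array([p[2:6] for p in pc], dtype=float).reshape(-1, 4)
        ps = np.array([p[1] for p in pc], dtype=float)
        gb = np.array([g[1:5] for g in gc], dtype=float).reshape(-1, 4)
        assigned = _greedy_match(pb, ps, gb, iou_threshold)
        tp = int((assigned >= 0).sum())
        res.tp[c] = tp
        res.fp[c] = len(pc) - tp
        res.fn[c] = len(gc) - tp
    return res


def prf(match: MatchResult) -> tuple[float, float, float]:
    """Micro-averaged (precision, recall, F1); zero denominators give 0."""
    tp, fp, fn = match.totals()
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def average_precision(detections, n_gt: int, iou_threshold: float = 0.5,
                      gts=None, interpolation: str = "all_points") -> float:
    """AP of one class from ranked detections.

    Two call styles: either ``detections`` is a list of (confidence,
    is_tp) pairs with ``n_gt`` ground truths, or ``gts``/pixel-box inputs
    are pre-matched by the caller.  ``interpolation`` is "all_points"
    (precision-envelope area) or "eleven_point".
    """
    if n_gt == 0:
        return 0.0
    det = sorted(detections, key=lambda d: -d[0])
    tps = np.array([bool(d[1]) for d in det], dtype=float)
    if tps.size == 0:
        return 0.0
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(1.0 - tps)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    if interpolation == "eleven_point":
        ap = 0.0
        for t in np.linspace(0, 1, 11):
            mask = recall >= t
            ap += (precision[mask].max() if mask.any() else 0.0) / 11
        return float(ap)
    # all-points: integrate the precision envelope over recall
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    for i in range(mpre.size - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def _rank_detections(image_preds, image_gts, iou_threshold):
    """Flatten per-image predictions into per-class ranked (conf, is_tp)."""
    per_class: dict[int, list] = {}
    n_gt: dict[int, int] = {}
    for preds, gts in zip(image_preds, image_gts):
        for g in gts:
            n_gt[int(g[0])] = n_gt.get(int(g[0]), 0) + 1
        classes = {int(p[0]) for p in preds}
        for c in classes:
            pc = [p for p in preds if int(p[0]) == c]
            gc = [g for g in gts if int(g[0]) == c]
            pb = np.array([p[2:6] for p in pc], dtype=float).reshape(-1, 4)
            ps = np.array([p[1] for p in pc], dtype=float)
            gb = np.array([g[1:5] for g in gc], dtype=float).reshape(-1, 4)
            assigned = _greedy_match(pb, ps, gb, iou_threshold)
            rec = per_class.setdefault(c, [])
            for conf, a in zip(ps, assigned):
                rec.append((float(conf), a >= 0))
    return per_class, n_gt


def mean_average_precision(image_preds, image_gts, iou_threshold: float = 0.5,
                           interpolation: str = "all_points"):
    """(per-class AP dict, mAP) over a set of images."""
    per_class, n_gt = _rank_detections(image_preds, image_gts, iou_threshold)
    classes = sorted(n_gt)
    aps = {c: average_precision(per_class.get(c, []), n_gt[c], iou_threshold,
                                interpolation=interpolation)
           for c in classes}
    m = float(np.mean([aps[c] for c in classes])) if classes else 0.0
    return aps, m


def confusion_matrix(image_preds, image_gts, num_classes: int,
                     iou_threshold: float = 0.5,
                     confidence_threshold: float = 0.25,
                     normalize: bool = False) -> np.ndarray:
    """(num_classes+1)^2 matrix; last row/column is background.

    Entry [i, j]: ground truths of class i predicted as class j; row i,
    background column: missed ground truths; background row, column j:
    false detections of class j.  Matching here ignores class so that
    cross-class confusions land off-diagonal.
    """
    m = np.zeros((num_classes + 1, num_classes + 1), dtype=float)
    bg = num_classes
    for preds, gts in zip(image_preds, image_gts):
        preds = [p for p in preds if p[1] >= confidence_threshold]
        pb = np.array([p[2:6] for p in preds], dtype=float).reshape(-1, 4)
        ps = np.array([p[1] for p in preds], dtype=float)
        gb = np.array([g[1:5] for g in gts], dtype=float).reshape(-1, 4)
        assigned = _greedy_match(pb, ps, gb, iou_threshold)
        matched_gt = set()
        for i, p in enumerate(preds):
            j = assigned[i]
            if j >= 0:
                m[int(gts[j][0]), int(p[0])] += 1
                matched_gt.add(j)
            else:
                m[bg, int(p[0])] += 1
        for j, g in enumerate(gts):
            if j not in matched_gt:
                m[int(g[0]), bg] += 1
    if normalize:
        sums = m.sum(axis=1, keepdims=True)
        m = np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)
    return m


@dataclass
class EvalReport:
    per_class_ap: dict
    map50: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    iou_threshold: float
    confidence_threshold: float

    def to_dict(self):
        return {
            "per_class_ap": {int(k): float(v) for k, v in self.per_class_ap.items()},
            "mAP@0.5": float(self.map50),
            "precision": float(self.precision),
            "recall": float(self.recall),
            "f1": float(self.f1),
            "confusion": self.confusion.tolist(),
            "iou_threshold": self.iou_threshold,
            "confidence_threshold": self.confidence_threshold,
        }


def evaluate(image_preds, image_gts, num_classes: int,
             iou_threshold: float = 0.5,
             confidence_threshold: float = 0.25) -> EvalReport:
    """Full evaluation over a set of images.

    P/R/F1 are computed at the operating confidence threshold; AP/mAP use
    every detection regardless of confidence (area under the PR curve).
    """
    aps, m = mean_average_precision(image_preds, image_gts, iou_threshold)
    agg = MatchResult()
    for preds, gts in zip(image_preds, image_gts):
        res = match_detections(preds, gts, iou_threshold, confidence_threshold)
        for c in set(res.tp) | set(res.fp) | set(res.fn):
            agg.tp[c] = agg.tp.get(c, 0) + res.tp.get(c, 0)
            agg.fp[c] = agg.fp.get(c, 0) + res.fp.get(c, 0)
            agg.fn[c] = agg.fn.get(c, 0) + res.fn.get(c, 0)
    p, r, f1 = prf(agg)
    cm = confusion_matrix(image_preds, image_gts, num_classes,
                          iou_threshold, confidence_threshold)
    return EvalReport(aps, m, p, r, f1, cm, iou_threshold, confidence_threshold)


def plot_confusion_matrix(cm: np.ndarray, class_names, path, normalize=True):
    """Render a (normalized) confusion matrix to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = cm.astype(float)
    if normalize:
        sums = m.sum(axis=1, keepdims=True)
        m = np.divide(m, sums, out=np.zeros_like(m), where=sums > 0)
    names = list(class_names) + ["background"]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(m, cmap="Blues", vmin=0, vmax=1 if normalize else None)
    ax.set_xticks(range(len(names)), names, rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            if m[i, j] > 0:
                ax.text(j, i, f"{m[i, j]:.2f}" if normalize else f"{int(m[i, j])}",
                        ha="center", va="center", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
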