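"""Evaluation metrics: matcher vs exhaustive oracle, P/R/F1 arithmetic,
AP vs hand-integrated PR area, confusion matrix, five-fold splitting."""

import itertools

import numpy as np
import pytest

from teayolo.metrics import (match_detections, prf, average_precision,
                             mean_average_precision, confusion_matrix,
                             box_iou_xyxy, nms, five_fold_split, kfold_pairs)


def exhaustive_max_matching(pred_boxes, gt_boxes, iou_threshold):
    """Oracle: maximum number of one-to-one matches with IoU >= threshold,
    by brute force over assignments (feasible for <= 6 boxes)."""
    if not len(pred_boxes) or not len(gt_boxes):
        return 0
    ious = box_iou_xyxy(pred_boxes, gt_boxes)
    n, m = ious.shape
    best = 0
    for perm in itertools.permutations(range(m), min(n, m)):
        rows = range(min(n, m))
        count = sum(1 for r, c in zip(rows, perm) if ious[r, c] >= iou_threshold)
        # try all subsets of predictions when n > m handled by permuting preds too
        best = max(best, count)
    if n > m:
        for rows in itertools.permutations(range(n), m):
            count = sum(1 for r, c in zip(rows, range(m)) if ious[r, c] >= iou_threshold)
            best = max(best, count)
    return best


def random_boxes(rng, n, lo=0, hi=80, smin=4, smax=20):
    out = []
    for _ in range(n):
        x, y = rng.uniform(lo, hi, 2)
        w, h = rng.uniform(smin, smax, 2)
        out.append((x, y, x + w, y + h))
    return out


class TestMatcher:
    def test_perfect_predictions(self):
        gts = [(0, 0, 0, 10, 10), (1, 20, 20, 30, 30)]
        preds = [(0, 0.9, 0, 0, 10, 10), (1, 0.8, 20, 20, 30, 30)]
        res = match_detections(preds, gts)
        assert res.totals() == (2, 0, 0)

    def test_duplicates_one_tp_rest_fp(self):
        gts = [(0, 0, 0, 10, 10)]
        preds = [(0, c, 0, 0, 10, 10) for c in (0.9, 0.8, 0.7)]
        res = match_detections(preds, gts)
        assert res.tp[0] == 1 and res.fp[0] == 2 and res.fn[0] == 0

    def test_wrong_class_never_matches(self):
        gts = [(0, 0, 0, 10, 10)]
        preds = [(1, 0.9, 0, 0, 10, 10)]
        res = match_detections(preds, gts)
        assert res.tp.get(1, 0) == 0 and res.fp[1] == 1 and res.fn[0] == 1

    def test_below_confidence_ignored(self):
        gts = [(0, 0, 0, 10, 10)]
        preds = [(0, 0.1, 0, 0, 10, 10)]
        res = match_detections(preds, gts, confidence_threshold=0.25)
        assert res.totals() == (0, 0, 1)

    @pytest.mark.parametrize("trial", range(25))
    def test_greedy_tp_count_equals_exhaustive_oracle(self, trial):
        """On random single-class scenes with <= 6 boxes the greedy
        confidence-ordered matcher finds a maximum matching."""
        rng = np.random.default_rng(1000 + trial)
        n_p, n_g = rng.integers(1, 6, 2)
        pb = random_boxes(rng, n_p)
        gb = random_boxes(rng, n_g)
        preds = [(0, rng.uniform(0.3, 1.0), *b) for b in pb]
        gts = [(0, *b) for b in gb]
        res = match_detections(preds, gts, iou_threshold=0.5)
        oracle = exhaustive_max_matching(np.array(pb), np.array(gb), 0.5)
        assert res.tp[0] == oracle


class TestPRF:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (8, 2, 2, (0.8, 0.8, 0.8)),
        (0, 0, 5, (0.0, 0.0, 0.0)),
        (6, 2, 4, (0.75, 0.6, 2 * 0.75 * 0.6 / 1.35)),
    ])
    def test_arithmetic(self, tp, fp, fn, expected):
        from teayolo.metrics import MatchResult
        res = MatchResult(tp={0: tp}, fp={0: fp}, fn={0: fn})
        p, r, f1 = prf(res)
        assert (p, r, f1) == pytest.approx(expected)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        det = [(0.9, True), (0.8, True), (0.7, True)]
        assert average_precision(det, 3) == pytest.approx(1.0)

    def test_no_correct_detection(self):
        det = [(0.9, False), (0.8, False)]
        assert average_precision(det, 3) == 0.0

    def test_toy_ranking_matches_hand_integration(self):
        # ranking hit, miss, hit, hit, miss over 3 ground truths:
        # raw precision at the recall steps is (1, 2/3, 3/4); the
        # all-points envelope lifts the middle step to max(2/3, 3/4) = 3/4
        det = [(0.9, True), (0.8, False), (0.7, True), (0.6, True), (0.5, False)]
        expected = (1 / 3) * 1.0 + (1 / 3) * (3 / 4) + (1 / 3) * (3 / 4)
        assert average_precision(det, 3) == pytest.approx(expected)

    def test_invariant_to_monotone_confidence_rescale(self, rng):
        det = [(float(c), bool(h)) for c, h in
               zip(rng.uniform(0, 1, 20), rng.random(20) > 0.5)]
        ap1 = average_precision(det, 12)
        det2 = [(0.1 + 0.5 * c ** 3, h) for c, h in det]
        assert average_precision(det2, 12) == pytest.approx(ap1)

    def test_map_is_mean_of_class_aps(self):
        gts = [[(0, 0, 0, 10, 10), (1, 30, 30, 40, 40)]]
        preds = [[(0, 0.9, 0, 0, 10, 10), (1, 0.8, 31, 30, 41, 40)]]
        aps, m = mean_average_precision(preds, gts)
        assert m == pytest.approx(np.mean(list(aps.values())))


class TestConfusionMatrix:
    def test_perfect_detector_identity_block(self):
        gts = [[(0, 0, 0, 10, 10), (1, 30, 30, 40, 40)]]
        preds = [[(0, 0.9, 0, 0, 10, 10), (1, 0.9, 30, 30, 40, 40)]]
        cm = confusion_matrix(preds, gts, num_classes=3)
        np.testing.assert_allclose(cm[:2, :2], np.eye(2))
        assert cm[:, 3].sum() == 0 and cm[3, :].sum() == 0

    def test_missed_gt_goes_to_background_column(self):
        gts = [[(2, 0, 0, 10, 10)]]
        cm = confusion_matrix([[]], gts, num_classes=3)
        assert cm[2, 3] == 1

    def test_cross_class_confusion_lands_off_diagonal(self):
        gts = [[(0, 0, 0, 10, 10)]]
        preds = [[(1, 0.9, 1, 0, 11, 10)]]   # overlaps gt but wrong class
        cm = confusion_matrix(preds, gts, num_classes=3)
        assert cm[0, 1] == 1
        assert cm[0, 3] == 0   # not counted as missed: it was localized

    def test_row_normalization(self):
        gts = [[(0, 0, 0, 10, 10), (0, 30, 30, 40, 40)]]
        preds = [[(0, 0.9, 0, 0, 10, 10)]]
        cm = confusion_matrix(preds, gts, num_classes=2, normalize=True)
        assert cm[0].sum() == pytest.approx(1.0)


class TestNms:
    def test_keeps_highest_of_overlapping_pair(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [50, 50, 60, 60]])
        keep = nms(boxes, np.array([0.8, 0.9, 0.5]), iou_threshold=0.45)
        assert set(keep) == {1, 2}


class TestFiveFold:
    def test_ten_items(self):
        folds = five_fold_split(range(10), seed=0)
        assert [len(f) for f in folds] == [2] * 5

    def test_2147_items(self):
        folds = five_fold_split(range(2147), seed=3)
        sizes = sorted(len(f) for f in folds)
        assert sum(sizes) == 2147
        assert max(sizes) - min(sizes) <= 1
        assert sizes == [429, 429, 429, 430, 430]
        all_items = sorted(x for f in folds for x in f)
        assert all_items == list(range(2147))

    def test_deterministic_under_seed(self):
        a = five_fold_split(range(50), seed=7)
        b = five_fold_split(range(50), seed=7)
        assert a == b
        c = five_fold_split(range(50), seed=8)
        assert a != c

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            five_fold_split(range(4), seed=0)

    def test_rotation_pairs(self):
        pairs = kfold_pairs(range(15), seed=0)
        assert len(pairs) == 5
        for train, val in pairs:
            assert len(train) == 12 and len(val) == 3
            assert sorted(train + val) == list(range(15))
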