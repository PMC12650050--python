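"""Scale-based dynamic box loss: CIoU decomposition, dynamic coefficients,
degradation to CIoU on large targets, gradients."""

import math

import numpy as np
import pytest

from teayolo.nn.autograd import Tensor
from teayolo.sdl_loss import (Box, ScaleContext, iou, ciou_terms, ciou_loss,
                              scale_factor, dynamic_beta, sdl_total,
                              sdl_loss_tensor)

from conftest import finite_difference_grad


def reference_ciou(pred, gt):
    """Independent CIoU implementation (straight from the textbook
    formulas, no shared code with the package path)."""
    px1, py1 = pred.cx - pred.w / 2, pred.cy - pred.h / 2
    px2, py2 = pred.cx + pred.w / 2, pred.cy + pred.h / 2
    gx1, gy1 = gt.cx - gt.w / 2, gt.cy - gt.h / 2
    gx2, gy2 = gt.cx + gt.w / 2, gt.cy + gt.h / 2
    iw = max(0.0, min(px2, gx2) - max(px1, gx1))
    ih = max(0.0, min(py2, gy2) - max(py1, gy1))
    inter = iw * ih
    union = pred.w * pred.h + gt.w * gt.h - inter
    i = inter / union
    v = 4 / math.pi ** 2 * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    alpha = v / (1 - i + v) if v > 0 else 0.0
    cw = max(px2, gx2) - min(px1, gx1)
    ch = max(py2, gy2) - min(py1, gy1)
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    return 1 - i + alpha * v + rho2 / (cw ** 2 + ch ** 2)


CTX_IMG = ScaleContext(wo=640, ho=640, wc=80, hc=80, gt_frame="image")


class TestIoU:
    def test_identical_boxes(self):
        b = Box(3, 4, 2, 5)
        assert iou(b, b) == pytest.approx(1.0)

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 2, 2), Box(10, 10, 2, 2)) == 0.0

    def test_hand_counted_overlap(self):
        # 2x2 boxes at centers (1,1) and (2,1): overlap 2, union 6
        assert iou(Box(1, 1, 2, 2), Box(2, 1, 2, 2)) == pytest.approx(1 / 3)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(0, 0, 0, 2)


class TestCiouTerms:
    def test_perfect_match_is_zero(self):
        b = Box(5, 5, 3, 2)
        l_bs, l_bl = ciou_terms(b, b)
        assert l_bs == pytest.approx(0.0, abs=1e-12)
        assert l_bl == pytest.approx(0.0, abs=1e-12)

    def test_concentric_different_aspect(self):
        l_bs, l_bl = ciou_terms(Box(5, 5, 4, 2), Box(5, 5, 2, 4))
        assert l_bl == 0.0
        assert l_bs > 0.0

    def test_matches_independent_reference(self):
        pred, gt = Box(5, 5, 4, 2), Box(6, 5, 4, 4)
        l_bs, l_bl = ciou_terms(pred, gt)
        assert l_bs + l_bl == pytest.approx(reference_ciou(pred, gt), abs=1e-9)

    def test_l_bl_bounded_by_one(self, rng):
        for _ in range(200):
            p = Box(*rng.uniform(1, 50, 2), *rng.uniform(0.5, 30, 2))
            g = Box(*rng.uniform(1, 50, 2), *rng.uniform(0.5, 30, 2))
            _, l_bl = ciou_terms(p, g)
            assert 0.0 <= l_bl <= 1.0


class TestScaleFactor:
    @pytest.mark.parametrize("ctx,expected", [
        (ScaleContext(640, 640, 80, 80), 64.0),
        (ScaleContext(32, 32, 32, 32), 1.0),
        (ScaleContext(1280, 960, 40, 30), 1024.0),
    ])
    def test_ratio(self, ctx, expected):
        assert scale_factor(ctx) == pytest.approx(expected)


class TestDynamicBeta:
    def test_large_target_degenerates(self):
        assert dynamic_beta(100.0, CTX_IMG) == (1.0, 1.0)

    def test_small_target_scalar_example(self):
        # delta=1, ROC=64, feature-scale area 0.02 -> image area 1.28
        ctx = ScaleContext(640, 640, 80, 80, delta=1.0, gt_frame="feature")
        beta_bs, beta_bl = dynamic_beta(0.02, ctx)
        assert beta_bs == pytest.approx(1.28 / 81, abs=1e-5)    # ~0.01580
        assert beta_bl == pytest.approx(2 - 1.28 / 81, abs=1e-5)  # ~1.98420

    def test_clamp_at_delta(self):
        ctx = ScaleContext(640, 640, 80, 80, delta=0.5, gt_frame="image")
        beta_bs, _ = dynamic_beta(81.0, ctx)
        assert beta_bs == pytest.approx(0.5)

    def test_uniform_policy(self):
        ctx = ScaleContext(640, 640, 80, 80, delta=1.0, policy="uniform",
                           gt_frame="image")
        b1, b2 = dynamic_beta(40.5, ctx)
        assert b1 == b2 == pytest.approx(0.5)

    def test_monotone_in_area_below_clamp(self):
        areas = np.linspace(0, 81, 50)
        betas = [dynamic_beta(a, CTX_IMG)[0] for a in areas]
        assert np.all(np.diff(betas) >= 0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            dynamic_beta(-1.0, CTX_IMG)


class TestSdlTotal:
    def test_degrades_to_ciou_for_large_targets(self, rng):
        for _ in range(1000):
            gw, gh = rng.uniform(10, 60, 2)  # area >= 100 px^2
            gt = Box(rng.uniform(50, 500), rng.uniform(50, 500), gw, gh)
            pred = Box(gt.cx + rng.normal(0, 5), gt.cy + rng.normal(0, 5),
                       gw * rng.uniform(0.5, 2), gh * rng.uniform(0.5, 2))
            res = sdl_total(pred, gt, CTX_IMG)
            assert res.total == pytest.approx(reference_ciou(pred, gt), abs=1e-6)

    def test_zero_loss_at_perfect_match_any_scale(self):
        for area_box in (Box(5, 5, 3, 3), Box(100, 100, 40, 40)):
            assert sdl_total(area_box, area_box, CTX_IMG).total == pytest.approx(0.0, abs=1e-12)

    def test_uniform_policy_scales_ciou(self, rng):
        ctx = ScaleContext(640, 640, 80, 80, policy="uniform", gt_frame="image")
        gt = Box(20, 20, 5, 5)   # 25 px^2, small
        pred = Box(22, 19, 6, 4)
        res = sdl_total(pred, gt, ctx)
        beta = 25 / 81
        assert res.total == pytest.approx(beta * reference_ciou(pred, gt), abs=1e-9)

    def test_asymmetric_betas_sum_to_two(self, rng):
        gt = Box(30, 30, 4, 4)
        res = sdl_total(Box(31, 30, 5, 5), gt, CTX_IMG)
        assert res.beta_bs + res.beta_bl == pytest.approx(2.0)

    def test_total_nonnegative_random_pairs(self, rng):
        for _ in range(300):
            p = Box(*rng.uniform(5, 100, 2), *rng.uniform(1, 30, 2))
            g = Box(*rng.uniform(5, 100, 2), *rng.uniform(1, 30, 2))
            assert sdl_total(p, g, CTX_IMG).total >= 0


class TestTensorPath:
    def test_matches_scalar_path(self, rng):
        ctx = ScaleContext(640, 640, 80, 80, gt_frame="image")
        preds = rng.uniform(5, 60, size=(6, 4))
        gts = preds + rng.normal(0, 2, size=(6, 4))
        gts[:, 2:] = np.abs(gts[:, 2:]) + 1
        loss = sdl_loss_tensor(Tensor(preds), gts, ctx)
        expected = np.mean([sdl_total(Box(*p), Box(*g), ctx).total
                            for p, g in zip(preds, gts)])
        assert float(loss.data) == pytest.approx(expected, rel=1e-5)

    def test_gradient_matches_finite_difference(self, rng):
        ctx = ScaleContext(640, 640, 80, 80, gt_frame="image")
        gts = np.array([[20.0, 20.0, 5.0, 5.0], [100.0, 80.0, 30.0, 20.0]])
        preds = gts + np.array([[1.0, -2.0, 1.0, 0.5], [-3.0, 4.0, -5.0, 2.0]])
        t = Tensor(preds, requires_grad=True)
        sdl_loss_tensor(t, gts, ctx).backward()

        num = finite_difference_grad(
            lambda a: float(sdl_loss_tensor(Tensor(a), gts, ctx).data), preds, eps=1e-4)
        np.testing.assert_allclose(t.grad, num, rtol=2e-3, atol=1e-5)
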