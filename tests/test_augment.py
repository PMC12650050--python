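"""Augmentation suite: identity cases, determinism, label-awareness."""

import numpy as np
import pytest

from teayolo.augment import (hsv_jitter, mean_blur, gaussian_blur, median_blur,
                             brightness, scale_xy, random_scale_xy, Augmenter)
from teayolo.datasets import DetectionSample


@pytest.fixture
def sample(rng):
    img = rng.integers(0, 256, size=(40, 60, 3), dtype=np.uint8)
    labels = [(0, 0.3, 0.4, 0.2, 0.2), (2, 0.7, 0.6, 0.1, 0.3)]
    return DetectionSample(image=img, labels=labels)


class TestPhotometric:
    def test_hsv_zero_gains_identity(self, sample):
        out = hsv_jitter(sample, 0, 0, 0, seed=1)
        np.testing.assert_array_equal(out.image, sample.image)
        assert out.labels == sample.labels

    def test_hsv_value_only_keeps_gray_hueless(self):
        gray = np.full((8, 8, 3), 120, dtype=np.uint8)
        s = DetectionSample(image=gray, labels=[])
        out = hsv_jitter(s, 0, 0, 0.3, seed=5)
        # gray stays gray: all channels equal
        assert np.all(out.image[..., 0] == out.image[..., 1])
        assert np.all(out.image[..., 1] == out.image[..., 2])

    def test_hsv_deterministic_under_seed(self, sample):
        a = hsv_jitter(sample, 0.02, 0.5, 0.3, seed=9)
        b = hsv_jitter(sample, 0.02, 0.5, 0.3, seed=9)
        np.testing.assert_array_equal(a.image, b.image)

    def test_hsv_negative_gain_rejected(self, sample):
        with pytest.raises(ValueError):
            hsv_jitter(sample, -0.1, 0, 0)

    @pytest.mark.parametrize("blur", [mean_blur, gaussian_blur, median_blur])
    def test_kernel_one_is_identity(self, sample, blur):
        out = blur(sample, 1)
        np.testing.assert_array_equal(out.image, sample.image)

    @pytest.mark.parametrize("blur", [mean_blur, gaussian_blur, median_blur])
    def test_even_kernel_rejected(self, sample, blur):
        with pytest.raises(ValueError):
            blur(sample, 4)

    @pytest.mark.parametrize("blur", [mean_blur, gaussian_blur, median_blur])
    def test_labels_never_touched(self, sample, blur):
        assert blur(sample, 3).labels == sample.labels

    def test_median_removes_impulse(self):
        img = np.full((9, 9, 3), 100, dtype=np.uint8)
        img[4, 4] = 255
        out = median_blur(DetectionSample(image=img, labels=[]), 3)
        # oracle: the 3x3 neighborhood median of the impulse pixel is 100
        assert np.all(out.image == 100)

    def test_mean_blur_constant_invariance(self):
        img = np.full((10, 10, 3), 77, dtype=np.uint8)
        out = mean_blur(DetectionSample(image=img, labels=[]), 5)
        np.testing.assert_array_equal(out.image, img)

    @pytest.mark.parametrize("value,factor,expected", [(200, 2.0, 255),
                                                       (100, 0.5, 50),
                                                       (123, 1.0, 123)])
    def test_brightness_arithmetic(self, value, factor, expected):
        img = np.full((4, 4, 3), value, dtype=np.uint8)
        out = brightness(DetectionSample(image=img, labels=[]), factor)
        assert np.all(out.image == expected)

    def test_brightness_nonpositive_rejected(self, sample):
        with pytest.raises(ValueError):
            brightness(sample, 0.0)


class TestGeometric:
    def test_unit_scale_is_identity_on_labels(self, sample):
        out = scale_xy(sample, 1.0, 1.0)
        assert out.labels == sample.labels

    def test_box_coordinates_follow_affine_oracle(self, sample):
        """Corner-transform oracle: scale the four corners, re-normalize."""
        sx, sy = 1.5, 0.8
        out = scale_xy(sample, sx, sy)
        H, W = sample.image.shape[:2]
        expected = []
        for cid, cx, cy, w, h in sample.labels:
            x1, x2 = (cx - w / 2) * W * sx, (cx + w / 2) * W * sx
            y1, y2 = (cy - h / 2) * H * sy, (cy + h / 2) * H * sy
            x1, x2 = np.clip([x1, x2], 0, W)
            y1, y2 = np.clip([y1, y2], 0, H)
            if (x2 - x1) * (y2 - y1) > 0:
                expected.append((cid, (x1 + x2) / 2 / W, (y1 + y2) / 2 / H,
                                 (x2 - x1) / W, (y2 - y1) / H))
        assert len(out.labels) == len(expected)
        for got, exp in zip(out.labels, expected):
            assert got[0] == exp[0]
            np.testing.assert_allclose(got[1:], exp[1:], atol=1e-9)

    def test_mild_scaling_preserves_inner_boxes(self, sample):
        out = scale_xy(sample, 0.95, 0.95)
        assert len(out.labels) == len(sample.labels)

    def test_surviving_boxes_inside_unit_square(self, sample):
        out = random_scale_xy(sample, (0.5, 2.0), (0.5, 2.0), seed=3)
        for _, cx, cy, w, h in out.labels:
            assert 0 <= cx - w / 2 + 1e-9 and cx + w / 2 <= 1 + 1e-9
            assert 0 <= cy - h / 2 + 1e-9 and cy + h / 2 <= 1 + 1e-9

    def test_mostly_cropped_box_dropped(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        # box near the right edge; doubling x pushes ~all of it off-canvas
        s = DetectionSample(image=img, labels=[(0, 0.95, 0.5, 0.1, 0.2)])
        out = scale_xy(s, 2.0, 1.0, min_visible=0.5)
        assert out.labels == []

    def test_nonpositive_scale_rejected(self, sample):
        with pytest.raises(ValueError):
            scale_xy(sample, 0.0, 1.0)


class TestPipeline:
    def test_deterministic_and_composable(self, sample):
        a, ma = Augmenter(seed=11)(sample)
        b, mb = Augmenter(seed=11)(sample)
        np.testing.assert_array_equal(a.image, b.image)
        assert a.labels == b.labels and ma == mb

    def test_manifest_records_applied_parameters(self, sample):
        _, manifest = Augmenter(seed=2)(sample)
        assert "brightness" in manifest and "scale" in manifest
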