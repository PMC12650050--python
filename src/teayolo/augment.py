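"""Label-aware augmentation suite.

Photometric ops (HSV jitter, blurs, brightness) never touch labels;
geometric ops (anisotropic scaling) transform the normalized boxes through
the same affine map and drop boxes whose visible area falls below a
configurable fraction.  Every op is deterministic under an explicit seed
and composable in any order.
"""

from __future__ import annotations

from dataclasses import replace as _dc_replace

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage.transform import resize as sk_resize

from .datasets import DetectionSample

__all__ = [
    "hsv_jitter", "mean_blur", "gaussian_blur", "median_blur",
    "brightness", "random_scale_xy", "scale_xy", "Augmenter",
]


def _copy(sample: DetectionSample, image=None, labels=None) -> DetectionSample:
    return DetectionSample(
        image=sample.image.copy() if image is None else image,
        labels=list(sample.labels) if labels is None else labels,
    )


def hsv_jitter(sample: DetectionSample, h_gain: float = 0.015,
               s_gain: float = 0.7, v_gain: float = 0.4,
               seed: int | None = None) -> DetectionSample:
    """Random perturbation of hue/saturation/value channels.

    Each channel is scaled by a factor drawn uniformly from [1-gain, 1+gain]
    (hue is shifted by a uniform draw in [-gain, +gain], wrapping around).
    Gains of 0 are the identity.
    """
    if min(h_gain, s_gain, v_gain) < 0:
        raise ValueError("gains must be non-negative")
    if h_gain == s_gain == v_gain == 0:
        return _copy(sample)
    rng = np.random.default_rng(seed)
    dh = rng.uniform(-h_gain, h_gain)
    fs = rng.uniform(1 - s_gain, 1 + s_gain)
    fv = rng.uniform(1 - v_gain, 1 + v_gain)
    hsv = skcolor.rgb2hsv(sample.image.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * fs, 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * fv, 0, 1)
    out = np.clip(skcolor.hsv2rgb(hsv) * 255.0, 0, 255).round().astype(np.uint8)
    return _copy(sample, image=out)


def _check_kernel(k: int):
    if k < 1 or k % 2 == 0:
        raise ValueError(f"kernel must be odd and >= 1, got {k}")


def mean_blur(sample: DetectionSample, kernel: int = 3) -> DetectionSample:
    """Box filter: every pixel replaced by the mean of its k x k neighborhood."""
    _check_kernel(kernel)
    if kernel == 1:
        return _copy(sample)
    out = np.empty_like(sample.image)
    for c in range(sample.image.shape[2]):
        f = ndimage.uniform_filter(sample.image[..., c].astype(np.float64),
                                   size=kernel, mode="reflect")
        out[..., c] = np.clip(f, 0, 255).round().astype(np.uint8)
    return _copy(sample, image=out)


def gaussian_blur(sample: DetectionSample, kernel: int = 3,
                  sigma: float | None = None) -> DetectionSample:
    """Gaussian smoothing; sigma defaults to the usual 0.3*((k-1)/2 - 1)+0.8."""
    _check_kernel(kernel)
    if kernel == 1:
        return _copy(sample)
    if sigma is None:
        sigma = 0.3 * ((kernel - 1) * 0.5 - 1) + 0.8
    out = np.empty_like(sample.image)
    for c in range(sample.image.shape[2]):
        f = ndimage.gaussian_filter(sample.image[..., c].astype(np.float64),
                                    sigma=sigma, truncate=(kernel // 2) / max(sigma, 1e-9),
                                    mode="reflect")
        out[..., c] = np.clip(f, 0, 255).round().astype(np.uint8)
    return _copy(sample, image=out)


def median_blur(sample: DetectionSample, kernel: int = 3) -> DetectionSample:
    """Median filter: removes salt-and-pepper impulses, preserves edges."""
    _check_kernel(kernel)
    if kernel == 1:
        return _copy(sample)
    out = np.empty_like(sample.image)
    for c in range(sample.image.shape[2]):
        out[..., c] = ndimage.median_filter(sample.image[..., c],
                                            size=kernel, mode="reflect")
    return _copy(sample, image=out)


def brightness(sample: DetectionSample, factor: float) -> DetectionSample:
    """Scale overall brightness by ``factor`` and clip to 8-bit range."""
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    out = np.clip(sample.image.astype(np.float64) * factor, 0, 255)
    return _copy(sample, image=out.round().astype(np.uint8))


def scale_xy(sample: DetectionSample, sx: float, sy: float,
             min_visible: float = 0.1) -> DetectionSample:
    """Anisotropic rescale on a fixed canvas.

    The image is resampled by (sx, sy) and composited back onto a canvas of
    the original size anchored at the top-left corner (cropping on
    upscales, zero padding on downscales).  Boxes go through the same
    affine map, are clipped to the image, and are dropped when the visible
    fraction of their area falls below ``min_visible``.
    """
    if sx <= 0 or sy <= 0:
        raise ValueError("scale factors must be positive")
    H, W = sample.image.shape[:2]
    if sx == 1.0 and sy == 1.0:
        return _copy(sample)
    new_h = max(1, int(round(H * sy)))
    new_w = max(1, int(round(W * sx)))
    resized = sk_resize(sample.image, (new_h, new_w), order=1,
                        preserve_range=True, anti_aliasing=sx < 1 or sy < 1)
    canvas = np.zeros_like(sample.image)
    ch, cw = min(H, new_h), min(W, new_w)
    canvas[:ch, :cw] = np.clip(resized[:ch, :cw], 0, 255).round().astype(np.uint8)

    labels = []
    for cid, cx, cy, w, h in sample.labels:
        # to pixels, through the affine, back to normalized
        x1 = (cx - w / 2) * W * sx
        x2 = (cx + w / 2) * W * sx
        y1 = (cy - h / 2) * H * sy
        y2 = (cy + h / 2) * H * sy
        full_area = max(x2 - x1, 0) * max(y2 - y1, 0)
        cx1, cx2 = np.clip([x1, x2], 0, W)
        cy1, cy2 = np.clip([y1, y2], 0, H)
        vis_area = max(cx2 - cx1, 0) * max(cy2 - cy1, 0)
        if full_area <= 0 or vis_area / full_area < min_visible or vis_area == 0:
            continue
        labels.append((cid, (cx1 + cx2) / 2 / W, (cy1 + cy2) / 2 / H,
                       (cx2 - cx1) / W, (cy2 - cy1) / H))
    return _copy(sample, image=canvas, labels=labels)


def random_scale_xy(sample: DetectionSample, sx_range=(0.7, 1.3),
                    sy_range=(0.7, 1.3), seed: int | None = None,
                    min_visible: float = 0.1) -> DetectionSample:
    rng = np.random.default_rng(seed)
    sx = rng.uniform(*sx_range)
    sy = rng.uniform(*sy_range)
    return scale_xy(sample, sx, sy, min_visible=min_visible)


class Augmenter:
    """Seeded random pipeline over the full suite, with a manifest of the
    parameters actually applied (for offline dataset expansion)."""

    def __init__(self, h_gain=0.015, s_gain=0.7, v_gain=0.4,
                 blur_prob=0.3, blur_kernels=(3, 5),
                 brightness_range=(0.6, 1.4),
                 sx_range=(0.7, 1.3), sy_range=(0.7, 1.3),
                 min_visible=0.1, seed: int = 0):
        self.params = dict(h_gain=h_gain, s_gain=s_gain, v_gain=v_gain,
                           blur_prob=blur_prob, blur_kernels=tuple(blur_kernels),
                           brightness_range=tuple(brightness_range),
                           sx_range=tuple(sx_range), sy_range=tuple(sy_range),
                           min_visible=min_visible)
        self.rng = np.random.default_rng(seed)

    def __call__(self, sample: DetectionSample):
        p = self.params
        manifest = {}
        seed = int(self.rng.integers(0, 2 ** 31 - 1))
        sample = hsv_jitter(sample, p["h_gain"], p["s_gain"], p["v_gain"], seed=seed)
        manifest["hsv_seed"] = seed
        if self.rng.random() < p["blur_prob"]:
            kind = self.rng.choice(["mean", "gaussian", "median"])
            k = int(self.rng.choice(p["blur_kernels"]))
            sample = {"mean": mean_blur, "gaussian": gaussian_blur,
                      "median": median_blur}[kind](sample, k)
            manifest["blur"] = {"kind": str(kind), "kernel": k}
        factor = float(self.rng.uniform(*p["brightness_range"]))
        sample = brightness(sample, factor)
        manifest["brightness"] = factor
        sx = float(self.rng.uniform(*p["sx_range"]))
        sy = float(self.rng.uniform(*p["sy_range"]))
        sample = scale_xy(sample, sx, sy, min_visible=p["min_visible"])
        manifest["scale"] = {"sx": sx, "sy": sy}
        return sample, manifest
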