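# teayolo

Detection components for counting fresh tea shoots (tender bud / one bud
one leaf / one bud two leaves) in low-altitude UAV imagery of large-leaf
tea plantations, built around three mechanisms borrowed from primate
vision, plus the full DE-YOLOv13-S network assembly they plug into.

The package is aimed at crop-phenotyping researchers who want the
mechanisms themselves — inspectable, unit-tested, runnable on a laptop CPU
— rather than a GPU training pipeline. The whole stack (a small
reverse-mode autodiff engine, convolution/attention blocks, losses,
metrics, augmentation, a synthetic scene generator) is numpy-based and
self-contained.

## The three mechanisms

**DynamicConv — expert-kernel routing.** A layer stores M expert kernels
W₁…W_M (default M = 4). Per input sample, global average pooling gives a
channel descriptor v, an affine router plus softmax gives coefficients
α = softmax(Wv + b) on the simplex, and the layer convolves with the fused
kernel W′ = Σᵢ αᵢ Wᵢ. Capacity grows ~M-fold while per-forward FLOPs stay
those of one convolution. `DynamicConvC3k2`/`DynamicConvC3k` embed the
layer in CSP-style blocks.

**EMCA — efficient mixed-pooling channel attention.** The per-channel
descriptor is GAP(x) + GMP(x); a 1-D convolution of adaptive width
k = odd(log₂(C)/γ + b/γ) (γ = 2, b = 1, floor-to-odd) slides across
neighboring channels, a sigmoid yields gates in (0, 1), and the input is
rescaled channel-wise. Each head costs exactly k + 1 = 4 scalars for
widths 64–256.

**SDL — scale-based dynamic loss.** CIoU is split into a scale term
L_BS = 1 − IoU + αv and a localization term L_BL = ρ²(b_p, b_gt)/c². With
ROC = (w_o·h_o)/(w_c·h_c) mapping feature-cell areas to image pixels, a
ground truth below the 81 px² small-target bound gets
β_B = min(A/81 · δ, δ); the default policy weights the terms as
(β_B, 2 − β_B), strengthening localization and relaxing scale for small
targets, and both weights become exactly 1 above the bound so the loss
degenerates to CIoU.

## Worked example

```python
from teayolo.sdl_loss import Box, ScaleContext, sdl_total
ctx = ScaleContext(wo=640, ho=640, wc=80, hc=80, gt_frame="image")
small = sdl_total(Box(101, 99, 6, 5),    Box(100, 100, 5, 5),   ctx)
large = sdl_total(Box(202, 198, 42, 40), Box(200, 200, 40, 40), ctx)
```

prints (via the returned breakdown):

```
small iou=0.4865 l_bs=0.5135 l_bl=0.0256 beta_bs=0.3086 beta_bl=1.6914 total=0.2017
large iou=0.8242 l_bs=0.1758 l_bl=0.0022 beta_bs=1.0000 beta_bl=1.0000 total=0.1780
```

The 5×5 ground truth (25 px² < 81 px²) is in the small-target regime:
its scale term is down-weighted to β = 25/81 ≈ 0.309 and its localization
term amplified to 2 − β ≈ 1.691. The 40×40 ground truth is an ordinary
target: both weights are 1 and the total is exactly the CIoU loss.

Assembling and auditing the full network:

```bash
teayolo verify-params
```

prints the 36-row table of expected-vs-actual trainable-parameter counts
(e.g. row 5 `DynamicConv [128, 128, 3, 2]` → 590,596; row 35
`Detect [3, [64, 128, 256]]` → 431,257), the total 4,620,460, and the
gradient-carrying count 4,620,444 (the 16 fixed distribution-focal
projection weights are parameters but carry no gradient). It exits
nonzero on any mismatch.

Other entry points: `teayolo synth` (seeded synthetic tea scenes with YOLO
labels), `teayolo augment` (HSV jitter, mean/Gaussian/median blur,
brightness, anisotropic scaling with label tracking), `teayolo evaluate`
(P/R/F1, per-class AP, mAP@0.5, confusion matrix). A short end-to-end
training smoke (`teayolo.train.train_smoke`) runs the full assembly with
the SDL box loss on synthetic scenes on one CPU.

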