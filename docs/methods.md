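# Methods

## Scope and stack

`teayolo` implements three biomimetic detection mechanisms — expert-kernel
dynamic convolution, mixed-pooling channel attention, and a scale-based
dynamic box-regression loss — together with the DE-YOLOv13-S assembly,
its evaluation/augmentation/cross-validation machinery, and a synthetic
scene generator. Everything runs on a small in-repo reverse-mode autodiff
engine over numpy (`teayolo.nn`): tensors carry a tape of parent/gradient
closures; conv2d is im2col + einsum with a vectorized col2im adjoint.
The engine exists so the package has no deep-learning-framework
dependency; gradient correctness is pinned by finite-difference tests on
every primitive and on composite blocks.

Working precision is float32; tensors built from float64 stay float64
(the finite-difference tests rely on this).

## Conventions that the parameter table pins down

The published per-layer table is the normative desk-verifiable contract.
The following conventions reproduce every printed count exactly:

- **Conv block** = bias-free conv2d + per-channel batch norm (2·C scalars)
  + SiLU. Row 0: 3·16·9 + 32 = 464; grouped row 1: 16·32·9/2 + 64 = 2368.
- **DynamicConv layer**: M bias-free experts, one affine router
  C_in → M (with bias), batch norm, SiLU. Budget
  M·C_out·C_in·K²/g + (C_in·M + M) + 2·C_out. With M = 4:
  4·128·128·9 + 516 + 256 = 590,596 (row 5) and
  4·256·128·9 + 516 + 512 = 1,180,676 (row 7). The expert count is not
  published; M = 4 is the unique small integer reproducing both rows with
  this layout, and it stays exposed as a constructor knob. The "MLP"
  router must be a single affine layer for the same budget reason.
- **DynamicConv-C3k2 bottleneck** = one plain 3×3 Conv followed by one
  3×3 DynamicConv, hidden expansion 1.0, residual add. This is the unique
  mixed layout matching all six printed C3k2 rows (15,940 / 63,108 /
  175,368 / 48,264 / 150,792 / 600,584); two dynamic convolutions per
  bottleneck or two plain ones both miss every row.
- **EMCA head**: descriptor fusion is elementwise addition (parameter-
  free), the 1-D conv carries a bias, and the odd(·) in
  k = odd(log₂(C)/γ + b/γ) is **floor-to-odd** (largest odd ≤ t). The
  conventional nearest-odd rounding gives k = 5 at C = 256 (6 scalars),
  contradicting the printed 4 scalars per head at widths 64/128/256;
  floor-to-odd gives k = 3 at all three widths. Nearest-odd remains
  available behind `EmcaConfig(rounding="nearest")`.
- **Area attention (A2C2f/ABlock)**: qkv/proj are 1×1 conv blocks without
  activation; the positional encoding on the values is a **5×5 depthwise**
  conv (a 7×7, as in some related ports, would add 1,536 scalars per
  block and miss rows 6/8). Attention is restricted to `area` contiguous
  chunks of the flattened token sequence.
- **Hypergraph fusion (HyperACE)**: three pyramid levels are aligned to
  the middle stride (avg-pool / nearest-upsample) and merged by a
  1×1 conv over the concatenated 4·C channels. Two C3AH branches each run
  one round of adaptive hypergraph message passing: context-conditioned
  prototypes (a Linear 2D → M·D on the concatenated mean/max context plus
  a learned prototype base), per-node pre-head projection, head-averaged
  scaled dot-product scores softmax-normalized over nodes, then
  edge/node Linear+GELU projections with a residual. The main path is one
  DSC3k (two depthwise-separable bottlenecks, kernels 3 and 7); a DSConv
  is a norm-free depthwise conv followed by a pointwise conv block. Sum:
  273,536, matching row 9.
- **Detect head**: distribution-focal regression with 16 bins per side
  (branch: two 3×3 conv blocks + 1×1 conv, 4·16 outputs) and a depthwise-
  separable classification branch, head widths c2 = c3 = 64; the DFL
  projection is the fixed ramp 0…15, counted as 16 parameters without
  gradients. Total 431,257; this also reproduces the published
  parameters-vs-gradients gap of 16 (4,620,460 vs 4,620,444).

Forward semantics of the base-detector blocks beyond these counts (exact
hypergraph normalization, attention partitioning) are not pinned by any
desk-verifiable number; the implementations here are reasonable reference-
style choices, and the parameter audit is the contract.

## Scale-based dynamic loss

CIoU is decomposed as L_BS = 1 − IoU + αv (v the aspect-consistency term,
α = v/((1 − IoU) + v); the published text names these without formulas, so
the standard CIoU definitions are adopted) and L_BL = ρ²/c². The dynamic
coefficient uses the ground-truth area **at feature-map scale** multiplied
by ROC = (w_o·h_o)/(w_c·h_c); this is the only reading under which the ROC
factor is dimensionally meaningful, and it makes the 81 px² comparison an
image-scale statement (the 9×9-pixel small-target convention). Above the
bound both coefficients are overridden to exactly 1 (accepting a jump
from δ to 1 at the boundary when δ < 1). Because a single β formula must
serve two coefficients that the prose wants to move in opposite
directions, two policies are provided: `asymmetric` (default,
β_BS = β, β_BL = 2 − β, continuous with CIoU at δ = 1) and `uniform`
(both β, the literal single-coefficient reading). δ defaults to 1.0.
In the composite training objective the SDL replaces only the box term;
classification (BCE) and distribution-focal terms are untouched, with
gains 7.5/0.5/1.5.

In the batched differentiable path, α is not detached: the loss gradient
flows through the full closed-form expression, which finite-difference
tests verify exactly.

## Evaluation

Matching is greedy in descending confidence, one-to-one, same-class, IoU ≥
0.5, operating confidence 0.25 (both configurable). On scenes with ≤ 6
boxes per class the greedy matcher is verified against an exhaustive
maximum-assignment oracle. AP uses all-points interpolation (precision
envelope); an 11-point option exists because the published text does not
specify the interpolation. mAP is the arithmetic class mean. The confusion
matrix matches class-agnostically so cross-class confusions land
off-diagonal, with background row/column for false and missed detections.
NMS IoU defaults to 0.45. The five-fold splitter permutes items under a
seed and cuts at rounded fifths, so fold sizes differ by at most one.

## Synthetic scenes and the training smoke

The generator emulates the statistical structure of the UAV dataset the
mechanisms target: three shape-coded classes (bud = bright ellipse
cluster; the leaf classes add one or two elongated lobes), a target-area
mixture with a configurable fraction below 81 px² (default 0.55,
reflecting a small-target-heavy canopy), optional overlap placement
(occlusion ~0.25), low-frequency background clutter, illumination jitter
and mild blur. It does **not** emulate UAV optics, real phenology, or
photo-realistic texture — passing tests show the mechanisms and training
plumbing work, not that field accuracy transfers.

The smoke harness assigns every ground truth to the center cell of each
pyramid level (first ground truth wins a contested cell), which
guarantees gradient flow through all three head scales at desk scale.
Problem sizes for the end-to-end check are the package's choice of desk
scale: 200 SGD steps (lr 5e-3, momentum 0.9, weight decay 1e-3), batch 2,
160×160 scenes, 12-image easy dataset; the published full-schedule
hyperparameters (batch 16, 500 epochs, SGD lr 0.01, weight decay 0.001)
are recorded in `TrainConfig` but full training is out of scope. The
check asserts finite losses and a decreasing box-loss trend
(last-quartile mean below first-quartile mean).

## Numerical notes and limitations

- IoU is clamped into [0, 1]; self-loss is exactly 0 on representable
  boxes and ≤ 1e-9 under adversarial float coordinates.
- Batch-norm uses batch statistics in training mode (momentum 0.03 running
  stats for inference); at batch 2 this is noisy but adequate for smoke
  runs.
- Router weights initialize near zero so initial routing is near-uniform;
  expert kernels use fan-in-scaled uniform init. Softmax temperature is
  fixed at 1.
- Augmentation perturbation ranges (uniform within ±gain) and the
  minimum-visible-area drop threshold (0.1) follow common detection
  practice; blur border handling is reflect padding.
- The numpy engine is single-threaded apart from BLAS; it is meant for
  correctness and desk-scale runs, not throughput. No mosaic/mixup, no
  COCO-style mAP@[.5:.95], no FLOPs certification (counting conventions
  vary), no pretrained weights.
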