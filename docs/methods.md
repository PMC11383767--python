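# Methods

This note documents the models, the procedures and the design decisions of
the `resswin` package in enough detail to reproduce or audit them.

## Preprocessing

Resizing uses separable bicubic interpolation with the Keys kernel,

    W(x) = (a+2)|x|³ − (a+3)|x|² + 1     for |x| ≤ 1
    W(x) = a|x|³ − 5a|x|² + 8a|x| − 4a   for 1 < |x| < 2
    W(x) = 0                             otherwise,

sharpness a = −0.5 (exposed in `BicubicKernelParams`). Each output pixel is
the weighted average of its 4×4 source neighbourhood with weights
W(a−u)W(b−v). Sampling aligns pixel centres (`src = (dst + 0.5)·scale −
0.5`) and clamps source indices at borders; this convention was an open
choice and is pinned for reproducibility. The kernel satisfies W(0)=1,
W(1)=W(2)=0 and partition of unity Σₖ W(k−u) = 1 for any phase, which the
tests verify to 1e−9. Internally the resize is two dense matrix
contractions in float64; results are rounded and clamped to 8-bit.

The augmentation set is exactly six transforms: rotation by 90° (clockwise
by convention) and 180°, horizontal mirroring, brightness scaling by 0.9
and 1.5 (multiplicative on RGB with rounding and clamping — an HSV
alternative was rejected for determinism), and a Gaussian blur emulating
wind-blown dust. Blur defaults, which no source pins: σ = 1.0 px, 5-tap
kernel, reflect borders, taps normalised to sum 1. A "filter" reading
(blur) was chosen over additive noise; additive noise exists behind
`additive_gaussian_noise` and is not part of the default set.

## Dataset bookkeeping

Manifests are pandas DataFrames with columns `image_id, path, label,
split, source_id, transform`. The pipeline order is pinned: resize →
split → augment. Augmenting after splitting guarantees that every derived
record inherits its source's split, so no augmented view of a training
image can reach validation or test (a property test checks this over
random manifests).

Splitting is per class at ratios 7:2:1. The published partition of the
2705 field images (779/222/111, 493/140/70, 624/177/89) is not generated
by any single rounding rule — 890 → 624/177/89 contradicts both floor and
largest-remainder apportionment — so those counts ship as an explicit
fixture (`TABLE1_COUNTS`) and `SplitSpec.explicit_counts` applies them
verbatim. The default rule for other totals is largest remainder with
ties resolved toward the earlier split. Which images land where is a
seeded uniform shuffle within each class, deterministic given manifest
order and seed.

`keep_original` defaults to false because 2705 × 6 = 16,230 exactly: the
augmented dataset replaces, not extends, the originals in the augmented
manifest (the original files stay on disk). Validation and test splits are
augmented like the training split, matching the augmented-partition table;
evaluation itself never applies transforms.

## The autodiff core

`resswin.autodiff` is a reverse-mode tape over NumPy arrays with a small
primitive set (arithmetic with broadcasting, matmul, reshape/transpose/
slice/roll/concatenate, reductions, ReLU, erf-based GELU, stable
(log-)softmax, and a stride-1 same-padding conv2d implemented via
sliding-window views). Layer norm, batch norm and attention are composed
from primitives, so their gradients come for free. Gradients are retained
on intermediate tensors, which Grad-CAM uses directly. Every primitive and
the composed layers are gradient-checked against central finite
differences in float64 (tolerance 1e−6 to 1e−5). Model parameters are
float32; batch norm keeps float32 running statistics (momentum 0.1,
biased variance) used in eval mode.

## Backbone

The default configuration is the tiny variant with a 3-class head: 224²
input, 4×4 patches, embed dim 96, depths (2,2,6,2), heads (3,6,12,24),
window 7, shift 3, MLP ratio 4, qkv bias on, GELU, pre-norm blocks, no
dropout or stochastic depth. These hyperparameters are not printed in the
source material; they are pinned by the published parameter count
2752.09·10⁴, which only that configuration reproduces (our exact count is
27,521,661 = 2752.17·10⁴, 761 scalars ≈ 0.003% above the printed value;
the residue is unexplained there and tolerated here). Patch embedding is
implemented as reshape + linear (parameter-identical to a strided
convolution). Patch merging concatenates 2×2 neighbours, layer-normalises
4C channels and reduces to 2C without bias. The head is layer norm →
global average pool → linear 768→3.

The SW-MSA mask is built by banding the shifted grid into 3×3 = 9 regions
with slices (0, −M), (−M, −shift), (−shift, ·) per axis, partitioning the
region ids into windows and forbidding cross-region pairs with an additive
−1e9 logit. Window attention with this mask is verified against a naive
per-pair loop oracle, and against independent per-region attention, at
14×14 scale.

Initialisation: truncated normal (clip at ±2σ, σ = 0.02) for linear
weights and the relative-bias table, zeros for biases, He-normal for the
convolutional residual branches, all drawn from one `numpy.random.
Generator` in construction order — two models built from the same seed are
weight-identical. Training starts from random initialisation; whether the
original work used pretrained weights is not stated, and no external
checkpoints are loaded. Input normalisation uses the fixed per-channel
mean/std (0.485, 0.456, 0.406)/(0.229, 0.224, 0.225) recorded in
`SwinConfig`.

## The improved model

Two insertions around the backbone:

1. **Residual module 1** on the normalised image before patch embedding:
   two Conv(7×7, 3→3)+BN pairs with ReLU between, added to the identity.
2. **Per-stage skip fusion + residual module 2**: for each stage,
   `f = stage_input + stage_output` (element-wise, parameter-free, valid
   because the skip spans the stage's block sequence before patch
   merging), then a 3×3 residual module at the stage width, then merging.

The module form — two Conv+BN pairs, 2k²C² + 6C parameters — was the
pivotal reconstruction decision. The source equation `y = x +
Conv2d{F[F(x)]}` literally implies a third convolution, but the published
parameter increments (+900 at the input; +1410.91·10⁴ across stages) are
matched exactly, and uniquely among natural variants, by the two-pair
form with k = 7 at C = 3 (the only odd k with 18k² + 18 = 900) and k = 3
at C ∈ {96, 192, 384, 768} (Σ 18C² + 6C = 14,109,120). The outer Conv2d is
read as notational duplication. Likewise the four-stage placement of
module 2 is the only one consistent with the printed increment. ReLU sits
between the two pairs; it is parameter-free, so counts are unaffected.

`zero_init="last_bn"` (default) zeroes the second BN scale of every
residual branch, making each branch exactly zero at initialisation. With
`skip_stages=()` the improved model then reproduces the baseline's logits,
gradients and Grad-CAM maps exactly — the equivalence the tests check.
With skips enabled (the default) the parameter-free addition itself
changes the computed function even at identity initialisation; that is
inherent to the architecture (it is why the skip-only ablation row changes
accuracy at an unchanged parameter count), so the equivalence tests
disable skips and a companion test asserts the with-skip difference.

## Training and evaluation

Adam (β = 0.9/0.999, ε = 1e−8) at learning rate 0.001, cross-entropy, up
to 100 epochs — the published protocol. Batch size 32, no weight decay, no
LR schedule (unspecified there; package defaults, all in `TrainConfig`).
The model is checkpointed every epoch; the best checkpoint maximises
validation accuracy, with lower validation loss then earlier epoch as tie
breakers (the sources state both an accuracy and a loss criterion;
accuracy is primary here because it matches the reported test protocol).
Training is bitwise deterministic given seed, manifest order and
hardware. Evaluation runs in eval mode (running BN statistics), applies no
augmentation, and reports the confusion matrix plus one-vs-rest
precision, recall, specificity, F1 and overall accuracy (trace/total).

Specificity defaults to TN/(TN+FP), the standard true-negative rate, which
also matches the prose definition ("ability to judge negative samples");
the printed variant TN/(TN+FN) is available via
`specificity_denominator="fn"` for literal reproduction. Degenerate 0/0
metrics are defined as 0 and flagged with a `RuntimeWarning`.

Grad-CAM targets the last spatial feature map — for the improved model the
input to the final stage's residual module 2 (7×7×768 at full size),
tokens relaid to a channel-first grid; for the baseline the final stage's
token grid. Channel-averaged gradients weight the activations, the sum is
rectified, min-max normalised (an all-zero map is returned as zeros rather
than normalised) and bilinearly upsampled to the input size.

## Synthetic data generator

`synthgen` renders: a soil-textured background (low-pass filtered noise in
brown tones) with weed-fragment distractors scaled by `clutter_level`; a
star-convex leaf blade with harmonic boundary wobble, smooth shading and
drawn veins; and one class motif — aphid: rim ridging plus 2–4 clusters of
small white/black dots; mite: yellow-white stipples plus a reddening patch
whose area grows with `motif_intensity`; mirid: black feeding spots plus
ragged holes with necrotic rims through which the background shows.
Defaults follow the emulated field dataset where stated: per-class counts
(1112, 703, 890) and three classes. The rendering size default is 448 px
(downstream-resized to the network input); motif geometry parameters were
chosen once for visible class separation at intensity 1 and are all in
`SynthConfig`, with no claim of biological calibration.

Per-image randomness derives from `default_rng([seed, class_index,
index])`, so outputs are byte-identical per (seed, class, index) and
images can be regenerated individually. At `motif_intensity=0` the motif
layer is skipped entirely and identical random streams render identical
pixels for all three labels: the background and leaf carry no label
information, so chance-level held-out accuracy on motif-free data is the
no-leakage control.

What the generator does *not* emulate: photographic statistics of field
imagery (sensor noise beyond simple grain, lighting variation, occlusion
by other plants, realistic lesion morphology, scale variation). Passing tests
therefore demonstrate that the pipeline and model are wired correctly and
can learn class-conditional local structure — not that field-level
accuracies are reproduced, which would require the original data.

## Problem sizes and numerical choices

Forward/backward passes of the full 224² model cost seconds per image on
one CPU core in this NumPy implementation, so the suite uses a reduced
configuration (56² input, embed 32, depths (2,2), heads (2,4), window 7)
wherever passes are needed in volume: the learnability checks train on 60
synthetic images (20/class) for ≤30 epochs, and identity-at-init is
checked on 100 inputs at the reduced size plus a pair at full 224². The
dataset-arithmetic reproduction runs at full record counts
(2705 → 16,230) with 64-px pixels materialised. Parameter accounting
always uses the full-size models.

Tolerances: attention oracle agreement 1e−5 (float32 reassociation);
identity-at-init 1e−5 on logits (observed ≈ 2e−8 at full size); kernel
partition of unity 1e−9 (float64); published parameter counts 0.05%
relative (covering the 0.003% counting-convention residue). Ties in
checkpoint selection and split apportionment break deterministically as
described above. Degenerate inputs (empty images, even blur kernels,
non-divisible grids, mismatched masks or channels, out-of-range labels,
unknown augment ops) raise `ValueError` rather than being silently fixed.

## Known limitations

* No GPU path and no batched im2col reuse: full-size training is
  impractical; the implementation is aimed at correctness, auditability
  and desk-scale experiments.
* The field dataset is unavailable, so published field accuracies
  (94.6% → 97.4% and the per-class test metrics) are out of scope and are
  not claimed or approximated by the synthetic results.
* The reconstruction of the residual-module form and the four-stage skip
  placement is inference from the published parameter accounting, not an
  authorial statement; alternative kernel/placement configurations are
  available as config overrides but are untested against the published
  counts.
* Single-label classification only: no detection, severity grading, or
  multi-pest co-occurrence.
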