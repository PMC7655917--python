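# Methods

## Model

The cascade consists of a fusion sub-network and a segmentation
sub-network, trained jointly so that segmentation gradients reach the
fusion encoder.

**Fusion.** `E_θ` is a 3-stage U-Net (widths 32-64-128, bottleneck 256 at
full scale; configurable) taking the stacked 2-channel `(CT, MRI)` input
and emitting one fused channel through a sigmoid. `D_φ` mirrors it
(1 → 2 channels, sigmoid) and exists only to supply the reconstruction
loss during training. The published account of the fusion stage names the
U-Net shape but not its widths; the widths here are the smallest faithful
reading and are exposed in `FsNetConfig.fusion_widths`.

**Dual encoder.** Path A is the textbook U-Net encoder (two 3×3
convolutions + BN + ReLU per stage, 2×2 max-pool between stages). Path B
replaces each stage with four 2×2 convolutions, padding `0101`
(alternatives: `1010`, `3x3`, `5x5`). A 2×2 kernel with symmetric padding
p gives `out = in + 2p − 1`, so the alternating pattern telescopes
−1/+1/−1/+1 and the stage preserves size. The two deepest features are
merged by channel concatenation + 1×1 reduction before the shared
bottleneck; the merge rule is not written as an equation in the source
design, and concatenate-reduce was chosen for consistency with every
other fusion point in the architecture.

**CSAB.** Channel attention pools each feature to max- and avg-
descriptors, passes both through one shared bottleneck
(C → C/8 → C/8 → C, 1×1 convolutions, ReLU after every layer including
the last — a flag `csab_final_relu=False` disables the final ReLU, which
halves the usable pre-sigmoid range), concatenates (2C) and reduces to C
before the sigmoid. The bottleneck is shared between the two pooling
branches of one feature but **not** between the g- and x-side blocks.
Spatial attention projects `g^l` and `x^l` with 1×1 convolutions,
concatenates, reduces to one channel and applies a sigmoid; the block
output stage is the triple product `f = α₃ ⊗ x^l ⊗ g^l` (not the more
common `α·x` gating) followed by `F = w·Cat[f, x] + b`. Channel counts
must be divisible by 8.

**Skip variants.** With stage width C and the decoder feature up-sampled
inside the block (transposed convolution, kernel = stride = 2):

| variant | order | realisation |
|---|---|---|
| a | 1×1 → Cat → Cu | per-path 1×1 (C→C), concat (2C), CSAB at 2C |
| b | Cat → 1×1 → Cu | concat (2C), 1×1 mix (2C→2C), CSAB at 2C |
| c | Cu → Cat → 1×1 | CSAB per path at C, Cat[F₁,F₂,u] (3C), 1×1 → 2C |
| d | Cu → 1×1 → Cat | CSAB per path, per-path 1×1 of Cat[Fᵢ,u] (2C→C), concat |

Variant d implements the published skip-fusion equations verbatim; the
a–c orderings are reconstructions of the figure captions (the source
specifies them only as primitive orders), chosen so that **every** variant
hands the decoder 2C channels — the invariant that keeps the standard
U-Net decoder unchanged across variants. With the dual encoder off the
block degenerates to the plain `Cat[x, u]`; with attention off CSAB is the
identity on the skip feature. With all three ablation flags off the model
is parameter-for-parameter a plain U-Net (tested against an inventory
derived from the plan arithmetic alone).

**Channel plans.** `"(32)"` = 1-32-64-128-256-512-…-1 (default) and
`"(16)"` = half of it; arbitrary doubling tuples are accepted, which is
how the desk-scale runs use widths (8, 16, 32, 64, 128).

## Losses

`L_total = η(L_MSE + L_SSIM) + γ·L_BCE`, η = 0.02, γ = 1 (both
configurable; η = 1 reproduces the unbalanced regime in which the fusion
terms dominate). Normalisation of `L_MSE` is per element (batch ×
channels × pixels): the alternative literal reading of its normaliser as
an epoch count is not implementable as a per-batch loss. The SSIM term
compares the 1-channel fused image against **each** input modality and
averages, so both CT and MRI structure constrain the fusion; SSIM uses the
standard 11×11 Gaussian window (σ = 1.5), C₁ = (0.01)², C₂ = (0.03)² at
dynamic range 1, population covariance, mean over fully-valid windows (it
matches `skimage.metrics.structural_similarity(gaussian_weights=True,
use_sample_covariance=False)` to ≤ 1e-6). BCE predictions are clamped to
[1e-7, 1 − 1e-7].

## Metrics

ACC, PPV, JS, DC from pixel confusion counts. Zero-denominator
convention: empty-prediction vs empty-truth scores 1.0, empty vs
non-empty 0.0 (standard in segmentation evaluation; the quantities are
otherwise undefined). Dataset aggregation is macro (mean of per-slice
scores) by default with pooled micro counts available; probability maps
are binarized at 0.5, the BCE-consistent default.

## Phantom generator

Each slice family is keyed by `(seed, index)` through
`numpy.random.Generator` integer seed sequences, giving bit-identical
output across runs and platforms. A slice contains: an elliptical skull
ring (bright on CT, dark on MRI), brain interior with smooth per-modality
texture (Gaussian field, amplitude 0.02), and one tumor — a rotated
ellipse whose radius is modulated by two low-frequency harmonics
(amplitude 0.12 of the radius), star-shaped about its centre and therefore
a single connected component. The tumor is homogeneous and sits exactly
`tumor_contrast_mri` (default 0.45) above the tissue base on MRI and
`tumor_contrast_ct` (default 0.08) on CT, before additive Gaussian noise
(σ = 0.02). Slices are grouped into pseudo-patients of 33 consecutive
slices by default, mirroring the ~860-slices/26-patients ratio of the
clinical setting the generator emulates, so splits can be done per
patient.

What the phantoms do **not** model: CT physics (Hounsfield scales, beam
hardening), MR sequence contrast mechanisms, anatomy, inter-slice 3D
coherence, registration error. Passing tests on phantoms therefore
demonstrates that the architecture, losses, training loop and evaluation
are correct and learnable end to end — not that clinical-level accuracy
is reached.

## Training protocol

Reference settings: 150 epochs, batch 4, weight decay 5e-8, learning rate
×0.1 once after epoch 100, patient-level 60/20/20 split (largest-remainder
rounding over patients; slice-level splitting available behind a flag),
augmentation by a seeded random subset of {horizontal flip, rotation ±15°,
scale 0.9–1.1} applied identically to CT/MRI/mask with the mask
re-binarized. Initial learning rates are not part of the published
protocol; defaults are 1e-2 (SGD) and 1e-3 (Adam/AdaBound). AdaBound
clips each element-wise step into
`[final_lr(1 − 1/(γt+1)), final_lr(1 + 1/(γt))]` with final_lr = 0.1,
γ = 1e-3, converging from Adam-like to SGD-like behaviour. Model
selection uses best validation Dice.

## Problem sizes

The package runs on a numpy autodiff core (`fsnet.nn`): reverse-mode
differentiation over stride-1 convolution (im2col/tensordot),
non-overlapping transposed convolution, 2×2 max-pooling, batch
normalisation with running statistics, global pooling, concatenation and
the pointwise ops. Default tensors are float32; verification tests run
in float64. On this core the package's own standard experiment sizes
are: overfit sanity on 8 phantom slices at 32×32 with widths
(8,…,128) for 200 iterations; design grids on 24 slices, 6
pseudo-patients, 6 epochs (the optimizer×plan grid divides the preset
widths by 2, keeping the wide/narrow relation; the other grids use the
(8,…,128) plan). Full-scale settings — 256×256, the "(32)" plan, 150
epochs — remain available through the same configuration objects.

## Numerical choices and edge cases

- Max-pool gradient breaks ties toward the first maximum in the window.
- Batch-norm uses ε = 1e-5, momentum 0.1, biased batch variance in the
  normalisation and unbiased running variance, framework convention.
- Parameter initialisation is Kaiming-uniform (fan-in), zero biases, drawn
  from a process-level generator reset by `fsnet.nn.manual_seed`.
- Masks are stored as 0/255 PNG and binarized at half range on read;
  images rescale by the dtype maximum. NIfTI volumes normalise per volume
  (min-max by default, z-score optional; constant volumes map to zeros).
- A `(seed, epoch)`-keyed RNG stream per training epoch makes runs
  resumable: continuing from a checkpoint with the same seed consumes
  identical randomness from that epoch on.

## Known limitations

- 2D slices only; no volumetric context.
- The attention bottleneck width C/8 forbids stage widths below 8.
- Transposed-convolution up-sampling requires kernel = stride (no overlap);
  this matches the 2× decoder steps used here but is not a general op.
- Training at the full 256×256 scale is possible but slow on the numpy
  core; the design grids are meant to be run at reduced sizes.
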