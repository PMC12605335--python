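# Methods

This note documents the model, the training procedure, the synthetic data
used to exercise them, and the numerical and design choices a maintainer
would want to know about. Empirical statements here are limited to what
the test suite and `scripts/acceptance.py` themselves compute.

## Problem setting

Binary semantic segmentation of bleeding regions in nasal-endoscopy
frames (classes: background, anomaly), under scarce pixel-level
annotation. Training uses a small labeled pool and a larger unlabeled
pool from the same distribution; the design goal is a network light
enough for clinical deployment that still exploits the unlabeled images.

## Model

### Encoder

A five-stage hybrid CNN–Transformer backbone in the MobileViT style:

- a stride-2 convolutional stem and an inverted-residual stage supply the
  stride-2 level; a stack of inverted-residual (MobileNetV2) blocks
  supplies stride 4;
- the stride-8/16/32 stages each combine an inverted-residual
  downsampling block with a MobileViT block: local 3×3 convolution,
  1×1 projection to token width, unfold into non-overlapping 2×2 patches,
  transformer self-attention over patch positions (one sequence per
  in-patch offset), fold back, 1×1 projection, and fusion with the block
  input via concatenation + 3×3 convolution.

The `small` variant uses the reference channel plan
(stem 16; levels 32, 64, 96, 128, 160; token widths 144, 192, 240;
transformer depths 2, 4, 3; 4 heads; MLP ratio 2; expansion 4). Batch
normalisation + SiLU in convolutional paths, layer normalisation in
transformer paths. When a feature map's spatial size is not divisible by
the patch size (any input whose side is an odd multiple of 32), the block
resizes to the nearest patch multiple and back, as in the reference
design, rather than failing.

### Decoder

Skip connections are replaced by attention-gated multi-scale fusion:

- **Global feature.** All five pyramid levels are bilinearly resized to
  the stride-4 resolution, concatenated (480 channels) and projected by a
  1×1 convolution to 368 channels.
- **Channel attention (coordinate style).** Each encoder level is pooled
  along width and along height; the two descriptor stacks pass through a
  shared 1×1 reduction (ratio 16, minimum width 8), then per-axis 1×1
  expansions and sigmoids give row gates `s_h` and column gates `s_w` in
  (0, 1); the level is multiplied by both.
- **Stages.** Four stages at strides 16, 8, 4, 2 with widths
  320, 256, 256, 256 (deep→shallow). Each stage upsamples the previous
  decoder state ×2 (bilinear), adds the gated encoder level and the
  resized global feature — each behind a 1×1 aligning convolution +
  batch norm — and refines with two 3×3 conv-BN-SiLU blocks.
- **Head.** A 3×3 convolution to 96 channels at stride 2, a 1×1
  convolution to 2 classes, and a final bilinear ×2 to full resolution.

Bilinear resizing uses half-pixel centres (corner alignment off)
everywhere. Ablation switches expose the plain additive decoder
(`use_channel_attention=False`, `use_global_fusion=False`).

**Width choice.** The published profile of the assembled network is
11.491 M parameters and 146.165 GFLOPs at 512×512, but the decoder's
widths are not published. The defaults above were chosen so that the
implementation reproduces that profile (measured: 11.492 M /
145.86 G under the counting convention below); narrower "textbook"
decoder widths such as (256, 128, 96, 64) yield a ~6.3 M / ~20 G model
and cannot be what produced the printed numbers.

### Profile counting convention

`profile_model` counts multiply-accumulates during a real forward pass:
one MAC = one operation, convolutions / linear layers / matrix products
(including attention score and value products) only; elementwise
arithmetic, normalisation, pooling and interpolation are excluded. This
matches what mainstream profilers report as "GFLOPs". Parameters count
all trainable weights and are input-size independent.

## Losses and semi-supervised training

- **Supervised:** mean per-pixel cross-entropy on labeled images.
- **Triplet consistency:** for each unlabeled image, three views —
  original, weak `t(·)` (horizontal flip p=0.5, brightness ±0.1,
  contrast ×[0.9, 1.1]) and strong `T(·)` (weak + rotation up to ±20°,
  saturation ±0.2, hue ±0.05) — are passed through the shared network;
  the loss is the batch mean of
  `α‖p_o−p_w‖² + β‖p_o−p_s‖² + γ‖p_w−p_s‖²` on softmax maps. The squared
  distance is averaged over pixels and channels by default (resolution
  independent); the summed form is available.
- **Total:** `L = L_sup + λ(epoch)·L_triplet`, with λ following the
  standard `exp(-5(1-t)²)` sigmoid ramp to `lambda_u` over `ramp_epochs`
  (default: first 20 % of training), constant afterwards. α=β=γ=1 and
  λ→1.0 by default; none of the four is published.

**View alignment.** Pixelwise MSE between probability maps is only
meaningful in a common geometric frame. The training loop therefore undoes
each view's geometry before the loss — rotation inverted by a
differentiable bilinear warp, then the flip — so the consistency term
compares predictions for the *same* physical pixels (prediction
equivariance). On the synthetic task the unaligned variant (kept available
via `TrainConfig(align_views=False)`) collapses segmentation quality, as
it rewards spatially symmetric predictions; alignment is therefore the
default.

**Optimisation.** SGD with momentum 0.9; cosine learning-rate decay from
0.01 to a floor of 0.001 (the published endpoints; the shape is a
choice); batch size 8, half labeled / half unlabeled, the smaller pool
resampled with replacement. An *epoch* is one shuffled pass over the
labeled pool; the unlabeled pool is consumed by a reshuffling cyclic
iterator across epochs. The three views are separate forward passes, so
batch-norm layers normalise each view with its own batch statistics;
the *running* statistics, however, are only updated by passes on
unaugmented data — rotated, reflection-padded and hue-shifted view
batches would otherwise drift the evaluation-mode statistics away from
the clean-data distribution (measured as a 2–3 mIoU-point loss on the
tiny task). With `lambda_u=0` the
unlabeled passes are skipped entirely (they would contribute no
gradient); batch-norm running statistics then see labeled batches only.
The best test-mIoU checkpoint is retained when a test set is present,
otherwise the final state. All randomness (initialisation, shuffling,
view sampling) derives from the single configured seed; training is
bit-reproducible.

## Synthetic data generator

The generator emulates the structure of bleeding-endoscopy data — not its
photorealism: a textured pink-orange mucosa background with a mild
vignette; one dark-red lesion per frame from four shape families (1–3
point foci, one extensive region, a warped quadrilateral, a thin vessel
streak); optional near-saturated specular reflections and Gaussian blur
as distractors that are *never* foreground. Lesion masks are produced by
quantile-thresholding a smooth scalar field, so each mask's foreground
fraction lands exactly inside the configured range (default 1–10 % of
pixels; the tiny experiments use 2–15 % at 64 px). Default image size is
512 px, matching the published input resolution; categories are mixed
uniformly (their real composition is unpublished).

What passing tests on this data do and do not show: they validate the
training dynamics, the semi-supervised machinery, the metric
implementations and all contracts end-to-end; they do not establish
clinical performance — real endoscopy has pose/illumination variation,
motion artefacts, occlusion and annotation noise the generator does not
model.

## Experiment scales

Desk-scale experiments use the `tiny-test` configuration (stem 8;
levels 8–40; token widths 24–40; depth 1; decoder widths 24, 20, 16, 16;
global width 24; head 8; one fuse conv) at 64×64 — about 0.16 M
parameters — with 200 training images (40 labeled, i.e. label ratio 0.2,
160 unlabeled), a 50-image held-out test set, 25 epochs, seeds 0–2, and a
supervised-only (λ=0) control per seed. These sizes were chosen so the
whole battery runs on one CPU core in minutes while still exercising
every component; the published 200-epoch 512×512 recipe remains the
default configuration of the full model.

## Metrics

Dice, per-class IoU and mIoU, mean recall, two accuracy variants, HD95,
ECE, per-pixel entropy, foreground F1, and the model profile. Conventions
(all cross-checked against naive brute-force oracles to 1e-9 in the
tests):

- the printed accuracy formula `ΣTP/(Σ(TP+FP+FN))` counts every
  misclassified pixel once as FP and once as FN; it is reported as
  `accuracy_eq8` alongside standard `pixel_accuracy` (trace/total);
- a class absent from truth and prediction has IoU 1 (flagged); a class
  absent from truth is excluded from mean recall (flagged);
- Dice of two empty masks is 1; HD95 uses 4-neighbour boundaries, pools
  the directed distances from both masks, and takes the 95th percentile;
  both-empty → 0, exactly-one-empty → +inf (flagged);
- HD95 is in pixel units unless a physical spacing is supplied (none is
  published for the source data);
- ECE uses 15 equal-width confidence bins by default;
- over a test set: one global confusion matrix for mIoU / recall /
  accuracy / F1; Dice and HD95 averaged per image over images with
  non-empty truth, infinite HD95 values excluded from the mean and
  flagged; argmax ties resolve to background.

## Known limitations

- The dataset-expansion arithmetic (405 → 2025) applies the ×5 operator
  to a whole corpus, while the stated protocol augments only the
  training subset (324·5 + 81 = 1701 ≠ 2025); both behaviours are
  exposed (`augment --all` vs the default) and the inconsistency is
  inherent to the source description, not resolved here.
- λ, α, β, γ and the λ-schedule are unpublished; defaults follow common
  consistency-training practice and are configurable.
- The NumPy compute stack is single-threaded per operation and intended
  for CPU-scale experiments; the full 512×512, 200-epoch recipe is
  expressible but not practical without acceleration.
- Checkpoints store raw arrays keyed by module path; architectural
  refactors invalidate saved checkpoints.
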