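# Methods

## The segmentation framework

`mammoseg` implements a two-stage segmentation of fibroglandular tissue
(FGT) in bilateral 3-D breast MRI. Stage 1 produces a whole-breast mask —
either a ground-truth mask or a stage-1 network applied to the full
(pre-contrast T1 [, T2]) volume. Stage 2 splits the volume at the lateral
midline (half the column axis), crops each side to the per-side breast
bounding box dilated by a margin (default 8 voxels in-plane, 0 along
slices), z-score-normalizes each channel *within the crop*, stacks
(pre-contrast T1, post−pre subtraction [, T2]) along the channel axis and
segments FGT per side. Side predictions are pasted back into the full grid
(zeros outside the crop boxes) and, by default, intersected with the stage-1
breast mask so FGT ⊆ breast holds by construction.

Array convention throughout: axis 0 = rows (anterior→posterior), axis 1 =
columns (right→left), axis 2 = slices (the coarse, anisotropic axis).
Stride/kernel tuples are written in that order, so the in-plane-only
downsampling step is `(2,2,1)`. Crop boxes are 0-based half-open ranges.

Whether to normalize before or after cropping is genuinely open; we
normalize per side after cropping, since stage-2 inputs are the crops and
per-crop statistics adapt to breast size. A constant channel inside a crop
(e.g. a subtraction image without enhancement) is mapped to zeros rather
than failing.

## Networks

**Anisotropic Swin U-Net.** A shifted-window transformer encoder
(SwinUNETR-family) with four stages, default embedding widths
(24, 48, 96, 192), attention heads (2, 4, 8, 16) and two blocks per stage
(alternating plain and cyclically-shifted windows, standard region masking).
The first `aniso_stages = 2` resolution steps (patch embedding and the first
patch merging) downsample in-plane only (`(2,2,1)`), all later steps use
`(2,2,2)`; convolutions at resolutions where the slice axis is still at full
resolution use `(3,3,1)` kernels, `(3,3,3)` elsewhere. The decoder mirrors
the encoder with nearest-neighbour upsampling + convolution blocks and skip
connections; a full-resolution convolutional stem supplies the last skip.
Deep supervision: `1×1×1` convolution heads on the two finest decoder levels
below full resolution.

Head counts follow the doubling pattern of the widths. The attention window
is (7,7,4) by default — reduced along the slice axis to respect anisotropy —
and (4,4,2) in the `tiny` preset (widths 12/24/48/96) used for CPU-scale
work. Two deliberate simplifications relative to published Swin
implementations, chosen to keep the from-scratch implementation small and
auditable: no relative-position bias table, and token grids are zero-padded
to window multiples without masking the padded tokens out of attention.
Tests exercise contracts (shapes, anisotropy, gradient flow, trainability),
none of which depend on these details.

**Baseline U-Net.** Encoder/decoder conv blocks (two convolutions, instance
norm, leaky ReLU 0.01) with max-pooling strides
`(2,2,1), (2,2,1), (2,2,2), (2,2,2)` — cumulative downsampling 16× in-plane
and 4× along slices — `(3,3,1)` kernels in the two top levels, `(3,3,3)`
below, and the same deep-supervision heads. This reimplements the pooling
scheme and block style of the nnUNet family; it is not the nnUNet framework
(no fingerprinting/self-configuration).

Inputs whose spatial size does not divide the cumulative stride are
symmetrically zero-padded and the main logits cropped back, so arbitrary
crop boxes pass through. Auxiliary logits are reported on the padded grid
together with the padding and their downsampling factors; the multi-scale
loss pads the target identically.

Both networks run on `mammoseg.nn`, a reverse-mode autodiff engine on NumPy:
convolution via im2col + BLAS matmuls (the input gradient is the full
correlation with the flipped kernel, also via im2col), non-overlapping max
pooling, nearest-neighbour upsampling, fused softmax/log-softmax and an
exact erf-based GELU. Gradients were verified against central finite
differences for every primitive.

## Training

- Loss: soft Dice (foreground classes; smooth term 1e-5, squared-denominator
  variant off) plus voxel-mean cross-entropy, summed.
- Multi-scale supervision: the loss is also evaluated at the auxiliary
  resolutions against nearest-neighbour-downsampled masks (block-center
  voxel), with weights halving per level and normalized to sum 1.
- Optimizer: AdamW, learning rate 1e-4, decoupled weight decay 0.01
  (betas 0.9/0.999).
- Patches: a uniformly random 256×256×32 region inside the (zero-padded)
  side per sample; the tiny preset uses 64×64×16. Both breast sides of a
  case enter training as independent samples.
- Augmentation (training only): per-axis flips, small affine
  (in-plane rotation ±10°, scale 0.9–1.1), k-space ghosting, Gaussian noise,
  Gaussian blur, smooth multiplicative bias field and gamma — spatial
  transforms applied jointly to image and mask (mask nearest-neighbour),
  intensity transforms to images only; deterministic per seed.
- Cross-validation: k = 5 test folds partitioning the cohort; within each
  fold the remaining cases split 80/20 into train/validation
  (validation size `max(1, round(0.2 n))`), all deterministic per seed.
- Early stopping: training halts once the validation loss has not improved
  for 30 epochs (default) and the best-validation weights are restored.
  Divergence (non-finite loss) aborts with a diagnostic.

Batch size and epoch length are not canonical; defaults are batch 1 with 10
steps per epoch, both configurable. For overfit sanity checks (one phantom,
no augmentation) the package uses learning rate 2e-3 — a deliberately hotter
rate appropriate for single-sample overfitting — with an optional early exit
once a target training Dice is reached; production training keeps 1e-4.

## Inference

Sliding windows of the training patch size with 50% overlap; window start
positions step by `patch·(1−overlap)` and the last window is shifted to
end-align with the volume, so every voxel is covered; overlapping softmax
probabilities are averaged uniformly. Test-time augmentation averages
predictions over mirrored copies of the input — by default all 8 flip
combinations, which is deterministic and a superset of random flipping; a
seeded random subset ("random:k") is available. Cross-fold ensembling takes
a per-voxel majority vote over the models' hard argmax masks (probability
averaging available as an option); even ensemble sizes are rejected unless a
tie-break is specified.

## The phantom generator

The generator emulates the properties of a screening cohort that the
pipeline actually depends on, with known ground truth:

- bilateral breasts as two half-ellipsoids attached to a flat pectoral plane
  (fixed row, 70% of the row axis), with mildly randomized per-case
  geometry;
- FGT grown by posteriorly-biased random walks from retroareolar seeds,
  Gaussian-smoothed and thresholded by bisection so the realized FGT
  fraction of the breast volume hits the requested density (generation
  fails loudly if the realized density misses the target by more than 20%
  relative, rather than silently clipping);
- default grid 128×128×32 at 1.4×1.4×3.0 mm — the ~2:1 slice-to-in-plane
  anisotropy of axial screening protocols at desk scale; a default target
  density of 18% matching a typical cohort mean;
- piecewise-constant tissue intensities per sequence (fat bright and FGT
  dark on non-fat-suppressed T1, reversed contrast on T2); the post-contrast
  volume equals the pre-contrast volume with FGT voxels multiplied by the
  enhancement factor (default 1.5 → BPE 50%) *before* corruption, so the
  subtraction image is nonzero exactly on FGT in the noiseless case;
- confounders: an enhancing spherical lesion and a homogeneous high-signal
  implant hemisphere on the pectoral plane (inside the breast mask, excluded
  from the FGT mask);
- corruption: a multiplicative low-frequency bias field built from low-order
  cosine modes (spectrally exact by construction) plus additive Gaussian
  noise, so E[corrupted] = image × bias field.

Generation is a pure function of the config including its seed (bit-identical
repeats). The phantom does **not** model MR physics (no k-space simulation),
fat suppression, inter-sequence misalignment, realistic FGT texture, or
partial-volume effects. Passing tests therefore demonstrate that the
pipeline's mechanics — cropping, training dynamics, inference algebra,
quantification — are correct and self-consistent, not that clinical-grade
accuracy transfers to patient data.

The phantom targets density (a percentage) rather than absolute FGT volume;
absolute volumes scale with the configured grid and are reported in mm³/cm³
from the voxel count and spacing.

## Evaluation and statistics

- Dice: `2|A∩B|/(|A|+|B|)`; both-empty defined as 1.0 and one-empty as 0.0
  so degenerate folds remain well-defined.
- ASSD: surfaces are foreground voxels with a background 6-neighbour (the
  grid boundary counts as background); distances are exact Euclidean
  distances between border-voxel centers weighted by the physical spacing
  (computed with an exact Euclidean distance transform); the symmetric
  value pools both directed distance sets. Empty masks make the distance
  undefined — an error to be caught and excluded with a warning, never a
  silent zero. Voxel-center distances were chosen over sub-voxel surface
  meshes as the simplest reproducible convention.
- Density: `100 · V_FGT / V_breast`; a warning (not an error) if the FGT
  mask leaks outside the breast mask.
- BPE: relative change of the *mean* FGT signal between post- and
  pre-contrast, in percent. The alternative reading — the fraction of FGT
  voxels enhancing beyond a threshold — is available via
  `mode="enhanced_fraction"`. The first post-contrast acquisition is the
  intended operand when several exist.
- Pearson correlation via `scipy.stats.pearsonr` (degenerate variance
  rejected).
- Bootstrap: case-level percentile bootstrap (default 2000 resamples),
  deterministic per seed.
- Paired permutation test: two-sided sign-flip test on paired differences
  with the mean difference as statistic; exhaustive over all 2^n sign
  patterns when 2^n ≤ n_perm (exact), otherwise Monte Carlo with the
  observed permutation included (so p > 0 always); all-zero differences
  give p = 1.
- Density-stratified reporting: per-bin mean ± SD of Dice and ASSD over
  half-open density bins; empty bins are kept (NaN) and flagged with a
  warning.

## Problem sizes used by the tests and the acceptance script

Tests and the acceptance script run everything on 64×64×16 phantoms at
2.8×2.8×6.0 mm (the default anisotropy ratio at a smaller grid), the tiny
network presets, and short overfit-style training runs (≤200 steps); the
pipeline-recovery experiment uses one stage-2 model trained on 4 phantoms
and evaluated on 20 unseen phantoms spanning 5–60% density, with TTA off
for that sweep. The density-trend sweep uses 30 phantoms at 48×48×16 in
three density bins with a fixed one-step 6-neighbourhood erosion of the
truth as the imperfect predictor. These sizes are the package's chosen
desk-scale study conditions; all thresholds the checks assert (Dice ≥ 0.9
overfit, ρ ≥ 0.9 recovery, calibration bands) refer to them.

## Known limitations

- The autodiff engine is single-threaded NumPy: suitable for the tiny
  presets and desk-scale grids, not for full-resolution training.
- The phantom's simplicity means segmentation on it is far easier than on
  patient data; reported Dice values on phantoms say nothing quantitative
  about clinical performance.
- Stage 1 defaults to ground-truth breast masks (the usual setting when the
  research question is FGT segmentation quality); stage-1 training works
  through the same machinery but carries no accuracy claims here.
- Attention padding/masking simplifications above; no relative-position
  bias; no Gaussian-weighted window blending or uncertainty maps.
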