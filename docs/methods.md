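# Methods

## Problem and pipeline

Regional lung ventilation maps guide functional-lung-avoidance radiotherapy
planning: sparing well-ventilated lung reduces the risk of radiation-induced
lung injury. Nuclear-medicine ventilation imaging (e.g. inhaled
⁶⁸Ga-aerosol "Galligas" PET) is the reference standard but is costly and not
widely available. This package implements the machine-learning alternative:
a 2D U-Net maps a pair of breath-hold CT volumes (exhale and inhale phases)
directly to a ventilation image (a CTVI), with no deformable image
registration and no hand-chosen ventilation metric.

The pipeline is: isotropic resampling → optional rigid shift → lung
segmentation → union-lung masking → fixed-size crop → normalization →
slice-wise 2D network training against the ventilation label → slice-wise
prediction reassembled into a 3D map → evaluation with masked Spearman
correlation and equal-volume functional-lung Dice overlap.

Because no clinical dataset ships with the package, a synthetic thorax
phantom generates paired CTs plus a ventilation ground truth with known
structure, so the entire pipeline trains, predicts and evaluates at desk
scale, and recovery of the known field is a measurable end point.

## Preprocessing

* **Resampling.** Order-3 (cubic B-spline) interpolation to an isotropic
  grid, default 1 mm (`target_spacing_mm`). The output size per axis is
  `round(size * spacing / target)`. Boundary handling is edge replication: a
  constant far-field value would leak spline-prefilter ringing several
  voxels into the volume. Outputs are clamped to the input intensity range
  so interpolation overshoot never invents values.
* **Rigid alignment.** The clinical workflow aligned PET to the exhale CT
  by visual inspection, which is not reproducible; here the shift is an
  explicit configuration value (`shift_mm`, default zero — the phantom
  generates pre-aligned volumes). Linear interpolation; regions shifted in
  from outside are filled with −1000 HU for CT and 0 for activity.
* **Lung segmentation.** Threshold CT < −500 HU; remove the
  border-connected component (outside air) by flood fill; keep at most the
  two largest components with at least `min_component_vox` voxels;
  morphological closing (ball radius `closing_radius_vox`) to fill vessels
  and airway walls. The clinical procedure was patient-tuned; this fixed,
  parameterized pipeline is deterministic, with per-case config overrides.
* **Masking and cropping.** CT phases are masked with the union
  (exhale OR inhale) lung mask, fill −1000 HU (air — the physically neutral
  background, which then anchors the normalization minimum). Volumes are
  cropped/padded to 250×304×304 (configurable) centred on the union-mask
  centroid, the deterministic way to guarantee the crop encompasses the
  lung.
* **CT normalization.** Per-case min–max to [0, 1] over the whole cropped
  volume (not lung-only), so the −1000 HU background maps to 0 consistently
  across cases.
* **Activity standardization.** Radio-aerosol clumping produces rare
  single-voxel hot spots orders of magnitude above the lung signal; plain
  min–max would compress the signal into a sliver of the range. The rule:
  compute μ and σ (population form; at ~10⁶ lung voxels the sample/population
  distinction is negligible) over lung voxels, clip **all** voxels at
  μ + 4σ (`sigma_clip_k`), then min–max normalize globally. Clipping is
  applied to every voxel, not just lung voxels, matching the rule's plain
  reading; the label is otherwise left unmasked.

## Network and training

The 2D U-Net consumes one axial slice as three channels — exhale, inhale,
and their voxelwise average — and emits one channel through a sigmoid.
Hidden convolutions are 3×3, ReLU, He-initialized, 'same' padding;
downsampling is 2×2 max pooling (stride 2); upsampling is a 2×2
transposed convolution (stride 2) with skip concatenation; two convolutions
per level. The full-scale configuration uses encoder widths
(14, 28, 54, 108) with a 310-wide bottleneck, a near-doubling schedule
chosen so the trainable-parameter count is exactly **1,962,901** (0
non-trainable) — the parameter budget of the reference architecture. The
test-scale default is (8, 16, 32) with a 64-wide bottleneck (120,825
parameters), used with 64×64 slices.

All layers, backpropagation and the Adam optimizer are implemented in NumPy
(channels-last, one matrix product per kernel offset); gradients are
verified against finite differences in the test suite. Training is
CPU-only and deterministic given the seeds.

**Loss.** A continuous-label generalization of focal loss with label
y ∈ [0, 1] and prediction p:

```
L = −mean[ α·y·(1−p)^γ·ln p + (1−y)·p^γ·ln(1−p) ],  α = 1.5, γ = 5.0
```

α weights only the positive (y) term, so underpredicting ventilated voxels
costs more than overpredicting empty ones. This matters because most voxels
are background: a plain regression loss (MSE/MAE) is minimized by blank
images on such data. The loss is averaged over all pixels, background
included. Predictions are clipped to [1e−7, 1−1e−7] inside the loss.

**Procedure.** Eightfold cross-validation at the clinical scale: with 15
cases and 2 test slots per fold, exactly one case (the first in shuffled
order) is tested twice, so every fold trains on 13 and tests on 2. All
training-case slices form one stack; a seeded random 10% of slices is the
validation split (slice-level, which mildly flatters validation loss — kept
deliberately, matching the described procedure). Augmentation is applied
on the fly, per slice per epoch: rotation uniform in ±10°, integer in-plane
translation uniform in ±20 px (scaled to ±4 px at the 64×64 test scale),
identical transform for input and label, zero fill. Adam, learning rate
3×10⁻⁴, batch size 8 (unstated in the reference procedure; chosen to fit
CPU memory at both scales).

**Epochs.** The clinical-scale default is 15 epochs. At the test scale a
training fold holds only ~144 slices (~18 optimizer steps per epoch), two
orders of magnitude fewer steps per epoch than clinical stacks provide, so
the recovery experiment trains for 60 epochs — the point at which the
held-out metrics plateau on the learning curve.

## Inference and evaluation

Each axial slice is predicted independently (batched, z-order restored by
explicit index bookkeeping), then the 3D volume is min–max normalized
globally. No post-prediction smoothing is applied; slice-wise prediction
leaves characteristic jagged edges in coronal/sagittal views, which is a
property of the method, not a defect to filter away. The global rescale is
monotone, so rank-based metrics are invariant to it (tested).

* **Spearman correlation** over the exhale-lung-mask voxels only, average
  ranks for ties.
* **Equal-volume functional lung.** Masked voxels are ranked ascending
  (ties broken by the stable linear voxel index — deterministic and
  platform-independent) and cut into three equal-count regions: low (LFL),
  medium (MFL) and high functioning lung (HFL). Region sizes are N÷3 with
  the remainder going to the lowest regions first. Segmentations are
  computed independently for the CTVI and the reference within the same
  exhale mask, then DSC = 2TP/(2TP+FP+FN) per region plus their mean.
  Both regions empty → DSC 1.
* Cohort summaries report mean ± sample (n−1) standard deviation.

## Synthetic phantom

The phantom encodes the physics that makes ventilation learnable from a CT
pair: inhaled air lowers lung density, so `inhale HU = exhale HU −
β·v(x)` with β = 150 HU per unit ventilation — an exactly linear,
analytically known link (pre-noise, the CT difference recovers the field
with correlation 1).

* **Geometry.** An elliptical body (soft tissue, 0 HU) on an air background
  (−1000 HU), two ellipsoidal lungs at −800 HU with smooth ±30 HU texture,
  optional solid tumor (20 HU, unventilated) inside a lung. Default grid
  96×128×128 at 2 mm; the recovery experiment uses 40×64×64 at 4 mm.
  Cohorts jitter geometry (±10% scale, ±5 mm centres) per case with seeds
  derived from the master seed by SeedSequence spawning.
* **Ventilation field.** A sum of random Gaussian blobs inside the lung,
  weighted toward the anterior-central lung (matching where high
  ventilation concentrates in supine patients), then stretched so the
  best-ventilated quarter saturates at 1 and the bottom 5% tail at 0 —
  keeping the field's dynamic range wide rather than letting one peak
  compress it. Zero outside the lung.
* **CT noise.** Independent additive Gaussian noise, σ = 10 HU per phase.
  With these defaults the voxelwise correlation between (exhale − inhale)
  and the true field stays ≥ 0.95.
* **PET-like label.** Activity = 10 kBq/mL per unit ventilation, blurred by
  a 6 mm Gaussian PSF, multiplied by log-normal noise (σ_log = 0.15), plus
  3 single-voxel hot spots at 100× the 99th-percentile activity — the
  clumping artefact that makes the μ+4σ rule necessary: the spots are
  <0.01% of lung voxels but >50× the median activity, and min–max alone
  would push the lung signal below 0.1 of the range.

**What the phantom does not emulate:** real anatomy (airways, fissures,
vasculature, diaphragm), respiratory-motion artefacts, scanner-specific PET
reconstruction, attenuation correction, and inter-modality misalignment
(volumes are generated pre-aligned). Passing the recovery test shows the
pipeline can learn a ventilation-like signal with the stated noise/blur
structure; it does not certify clinical accuracy on patient data.

## Numerical choices and edge cases

* Constant volume under min–max normalization → all zeros; constant input
  over a mask makes Spearman undefined → explicit error, never a silent 0.
* Tertile split needs ≥3 masked voxels; empty lung masks raise
  degenerate-case errors naming the case.
* Max-pool ties resolve to the first element; all seeds derive from one
  master seed through a fixed offset table (SeedSequence entropy
  `[master, offset]`), so each stage replays in isolation.
* Volumes are float32 on disk and in training; metric computations promote
  to float64.
* Boolean masks are stored as uint8 {0,1}; only axis-aligned orientations
  are accepted at I/O (oblique volumes are rejected, not resampled).

## Known limitations

* The NumPy network trains at desk scale; the full 250×304×304 clinical
  scale would be slow on one CPU (the architecture and parameter count are
  still exact at full scale, and inference is feasible).
* The per-level widths of the full-scale U-Net are this package's choice,
  constrained to the canonical topology, the published layer conventions
  and the exact 1,962,901-parameter budget; other width schedules matching
  the same budget exist.
* Slice-level validation splits leak same-patient slices between train and
  validation loss tracking (not between train and test folds, which are
  split by case and audited from the run manifest).
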