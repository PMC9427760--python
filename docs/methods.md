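# Methods

## Problem and pipeline

`ctatrophy` estimates regional cortical-atrophy grades from skull-stripped
brain CT. Clinically, atrophy is graded on ordinal visual rating scales
(VRS): frontal (FA) and parietal (PA) atrophy on 0–3, and right/left medial
temporal atrophy (MTAR/MTAL) on 0–4. The pipeline replaces the rater with a
four-stage computation:

1. **Preprocessing** — window the CT to the brain-tissue range, normalize to
   [0, 1], histogram-equalize over in-brain voxels, drop brain-invisible
   axial slices, and (for the network) resize slices to the model's input
   resolution.
2. **Tissue segmentation** — label every voxel CSF, gray matter (GM), or
   white matter (WM), either with a 2D encoder–decoder network or with a
   deterministic intensity-threshold fallback.
3. **Feature extraction** — reduce the label volume to eight global-atrophy
   features (below).
4. **Grading** — per region, binarize the VRS (scores ≥ 2 positive) and fit
   a regularized logistic regression (RLR) on the eight features; report the
   cross-validated ROC/AUC, the Youden-optimal operating point, and
   normalized feature importances.

Upstream rigid registration and skull stripping are out of scope: the
pipeline consumes already-registered, already-masked volumes and merely
records the upstream protocol parameters in its config for provenance.

## The eight features

With `B` the brain mask (voxel count `|B|`), `V` the ventricle mask, and a
reference axial slice `r`:

- `GMR3D = |GM| / |B|`, `WMR3D = |WM| / |B|`, `GMWMR3D = GMR3D + WMR3D`
  (computed as the sum of the two ratios so the additivity identity holds
  exactly in floating point), `Ven3D = |V|` (raw voxel count);
- the 2D analogues `GMR2D`, `WMR2D`, `GMWMR2D` on slice `r`, with the
  brain-mask pixel count of that slice as denominator, and `Ven2D` the
  ventricle pixel count on the "butterfly" slice.

Slice conventions: slices are indexed 0-based with index 0 the most superior
slice. The reference slice is the visible slice just *prior to* the
ventricle scanning top-down, i.e. `s* − 1` where `s*` is the most superior
slice containing a ventricle voxel (clamped to 0 with a warning if the
ventricle reaches the top). The butterfly slice maximizes the ventricle
pixel count, ties broken toward the superior slice. If no ventricle is
resolvable at all, both counts are 0 and the mid-brain slice stands in for
`r`, with a warning.

**Ventricle rule.** Tissue segmentation yields only three classes, so the
ventricle must be separated from total CSF. We take 6-connected CSF
components that do not touch the brain-mask boundary (interior CSF; sulcal
CSF always reaches the surface), largest first, up to two components — the
two lateral lobes. This is the simplest rule consistent with ventricular
anatomy and is exactly verifiable on phantoms. The 2D denominators use the
brain-mask area rather than the full frame; this choice is configurable in
spirit (the denominator cancels in rank-based analyses) and flagged for
sensitivity analysis.

Ventricle counts stay raw counts (not ratios) by design; the grader
z-scores all features, which makes the mixed units immaterial and the
coefficient magnitudes comparable.

## Segmentation

**Trainable network.** A compact 2D U-Net: per contracting level two 3×3
convolutions + ReLU, 2×2 max-pooling; channels double per level from
`base_channels`; the expanding path mirrors it with nearest-neighbor
upsampling, a channel-halving convolution, skip concatenation, and two more
convolutions; a 1×1 head produces 4-class logits. The loss is per-pixel
multiclass cross-entropy (the natural choice for mutually exclusive tissue
classes), optimized with Adam. Early stopping monitors a validation split
(default 10%, split by subject when slice→subject groups are provided) and
restores the best-validation weights after `early_stop_patience` stale
epochs. The implementation is pure NumPy (im2col convolutions, float32),
single-process and deterministic for a fixed seed. Config defaults keep the
published clinical settings (learning rate 1e-6, batch 16), which suit
fine-tuning on a large cohort; desk-scale phantom experiments pass a larger
rate (1e-3 in our tests) because they train small nets from scratch for few
epochs.

Network size in this repository's experiments is depth 3 with 16 base
channels on 32×32 phantom slices — chosen so a 30-subject training run
completes in about a minute on a single CPU core while leaving the
architecture family intact. Accuracy at these sizes is not a claim about
clinical CT.

**Threshold fallback.** CT orders mean intensities CSF < WM < GM. The
fallback assigns each in-mask voxel the class of its half-open HU interval,
with boundaries midway between the configured tissue means. On zero-noise
phantoms the classes are separable by construction, so the fallback is
exact (per-class Dice 1.0); this gives every downstream stage a
deterministic, training-free oracle path. In the pipeline the fallback runs
on the raw HU volume (thresholds stay interpretable against the tissue
means); the windowed/equalized volumes feed the network path.

**Evaluation.** Dice similarity `DSC = 2|X∩Y|/(|X|+|Y|)` per tissue class,
one-vs-rest; the subject DSC is the unweighted mean over the three classes
(a class absent from both volumes is excluded and logged; the both-empty
single-mask case raises rather than silently returning 0 or 1). Fold
assignment for any k-fold experiment is by subject, never by slice, so
adjacent slices of one subject cannot straddle train/test.

## Grading

Features are z-scored with training statistics. Hyperparameters — penalty
(L1/L2), regularization strength `C` log-uniform on [1e-3, 1e3], solver
(liblinear/saga), 50 draws — are tuned by random search, each draw scored
by mean AUC over threefold subject-level cross-validation, and the best
setting refit. Reported metrics use out-of-fold predicted probabilities
pooled over three folds (a fresh fold split, seeded separately from the
tuning folds) into a single ROC curve; AUC equals the
positive-outranks-negative probability with ties counted one half. The
operating point maximizes Youden's `J = SENS + SPEC − 1`, ties broken
toward higher sensitivity (the screening convention). The cutoff is chosen
on the same pooled predictions that are reported, which is optimistically
biased but matches how such operating points are conventionally tabled;
the bias is documented rather than hidden. Feature importance is
`|coef_i| / Σ|coef_j|` on the standardized scale; if regularization shrinks
every coefficient to zero the importances are reported uniform with a
warning.

## The phantom generator

The phantom is a nested-ellipsoid brain in a `(slices, rows, cols)` grid
(default 24×48×48, voxel 0.5×0.5×3.3 mm to mirror thick-slice axial CT):
an outer sulcal-CSF shell (8% of the normalized radius), a GM rind
(default thickness 0.18 in radius units), a WM core, and two mirrored
ventricle lobes offset left/right of the midline — a mid-ventricular axial
slice shows the classic butterfly. Tissue means default CSF 8, WM 28, GM 38
HU (CT shows GM brighter than WM); intensities add Gaussian noise of
`noise_sd` HU inside the brain only.

Atrophy enters through two dials:

- `ventricle_scale` scales each lobe axis by its cube root, so lobe volume
  grows approximately linearly with the dial (ex-vacuo dilation);
- `cortical_thinning` converts that fraction of GM voxels, outermost first,
  into sulcal CSF (sulcal widening), deterministically.

**Cohort model.** Per subject, two latent atrophy factors — cortical
(drives FA and PA severities) and temporal (drives MTAR and MTAL) — are
drawn uniform on [0, 1]; region severities add small independent jitter
(±0.075) and clip to [0, 1]. Regional grades correlate strongly within a
patient, and factoring them this way gives the temporal regions a signal
(ventricular enlargement: `ventricle_scale = 1 + 0.8 · mean(MTA
severities)`) distinct from the cortical one (`cortical_thinning = 0.35 ·
mean(FA, PA severities)`). GM rind thickness is additionally jittered per
subject (uniform 0.15–0.21) as severity-independent anatomical
variability, so the GM-ratio features carry natural variance that is not
atrophy. VRS scores are the equal-width-bin image of severity on the
region's scale (invertible per bin, convenient for tests); with probability
`rating_noise` (default 0.05) a score moves one step in a uniform
direction, clamped — a symmetric stand-in for inter-rater disagreement.

**What the phantom does not emulate:** real anatomy (gyri, asymmetry,
partial-volume gradients), beam-hardening and streak artifacts,
registration error, rater bias, and any lobar specificity of atrophy — the
features are global by design, so lobar shape is irrelevant downstream.
Passing tests therefore demonstrate that the pipeline's logic is correct
and recovers planted signal under its own generative assumptions, not that
clinical accuracy matches any published cohort.

## Numerical and design choices

- Brain-tissue window default [0, 80] HU; histogram equalization is
  per-volume over in-brain voxels (256 bins), preserving inter-slice
  intensity relations that 2D features rely on; the fixed preprocessing
  order is mask → window → normalize → equalize.
- `min_brain_fraction` default 0.01 defines "brain-invisible" slices.
- Label resizing is nearest-neighbor (never invents labels); intensity
  resizing is linear with anti-aliasing when shrinking.
- Dice on two empty masks raises (0/0 must surface, not default).
- Both the fold assignment and every stochastic stage derive from explicit
  seeds; the pipeline derives per-stage seeds from one global seed via
  CRC32-keyed seed sequences (process-stable, unlike Python's salted
  `hash`).
- Degenerate inputs are contracts, not crashes: out-of-set labels name the
  offending values, degenerate windows and single-class label sets raise,
  constant features are dropped with a warning.

## Problem sizes used in the checks

Unit and acceptance tests run phantoms at 20×32×32 and cohorts of 20–300
subjects; the network check trains depth 3 / 16 channels on 24 subjects
(~430 slices, 8 epochs) and evaluates 6 held-out subjects. These sizes are
the package's chosen desk-scale study conditions; the same code paths
accept clinical-scale volumes unchanged.

## Known limitations

- The trainable segmenter is a CPU NumPy implementation: fine for phantom
  scale, not for 128×128 clinical cohorts at many epochs.
- The operating point is selected on the evaluation predictions (see
  above); a nested selection would be unbiased but would not match the
  conventional single-curve presentation.
- The ventricle rule assumes the lateral ventricles do not touch the brain
  boundary after masking; severe masking errors violate it.
- Ratings are simulated; no claim is made about agreement with human
  raters beyond the planted monotone severity→score mapping.
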