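# Methods

## Scope and design

`lofisim` implements a virtual-trial loop for low-field MRI: degrade
high-field (HF) brain FLAIR volumes to simulated 64 mT (simLF) quality,
train matched slice classifiers on both arms of a cohort, and compare
detection statistically. Registration and skull-stripping are out of
scope: all inputs are assumed pre-aligned and masked, with background
exactly zero. Physics is deliberately not modelled — no relaxation-time
contrast changes, k-space sampling, or scanner artifacts; the transform
reproduces the *appearance statistics* (resolution, blur, noise,
histogram shape) of low-field images, which is also the main caveat when
extrapolating its results to real devices.

## Degradation transform

Input volumes are resliced to the LF acquisition grid, 1.6 × 1.6 mm
in-plane with 5 mm slices, by tri-linear interpolation on voxel centers;
the output grid covers the same physical extent (`ceil(extent/spacing)`
voxels per axis). Masks are interpolated tri-linearly and re-binarized at
0.5; label maps use nearest-neighbor so labels stay integral.

The cascade applied on the LF grid is

```
sim = G_b( v + a1 · M·G_0.5(eps1) ) + a2 · M·G_s2(eps2)
```

with `M` the brain mask, `G_sigma` Gaussian smoothing, and the fixed
pre-smoothing SD of 0.5 given in voxel units of the LF grid; the two
fitted SDs (`b`, `s2`) are physical (mm) and converted per axis by the
voxel spacing, so blur stays meaningful on anisotropic grids. Noise
fields are zero-mean unit-variance Gaussian; noise is confined to the
mask and the output is re-masked, keeping the background exactly zero as
in skull-stripped data. The final noise field is added last, with no
intensity clamping.

Default parameters `(a1, b, a2, s2) = (0.4, 2.5 mm, 0.25, 1.0 mm)` were
chosen so the pooled added-noise SD is ≈ 0.13 on a unit-mean brain —
SNR ≈ 8, the regime of portable 64 mT FLAIR — with blur somewhat above
the in-plane pixel size.

### Moment-matching fit

Calibration minimizes, over pairs of (HF resliced, real LF) volumes, the
mean of squared standardized differences of the in-mask histogram mean,
SD and skewness between the simulated and target images. Mean and SD
differences are divided by the target SD; skewness is already
dimensionless. Two normalization modes exist: `per_image` (default)
rescales every image — target and simulation alike — to unit in-mask
mean before computing moments, removing arbitrary scanner scaling (the
mean then acts as an exact constraint and the informative features are
the coefficient of variation and skewness); `none` compares raw moments
and is appropriate for synthetic pairs that share a scale by
construction. Rescaling only the target would bias the fit, because blur
lowers the in-mask mean by mixing in background zeros.

The objective averages moments over a fixed number of noise realizations
(default 5) whose fields are drawn once per fit seed and reused across
parameter evaluations (common random numbers), making the objective
deterministic and smooth. Optimization is bounded Nelder–Mead from a
small seeded multi-start; the best-so-far trace is monotone
non-increasing, and a fit that never improves on its initial point is
returned with a warning flag.

**Identifiability.** The final image is signal plus independent,
voxel-wise symmetric noise, so the pooled in-mask histogram depends on
the noise only through its voxel-averaged variance
`v = a1²·g(b) + a2²·h(s2)`: symmetric noise leaves the third central
moment unchanged and enters the SD through the average added variance.
Consequently only the blur SD and the total noise level are identifiable
from histogram moments; the split of `v` between the two noise
amplitudes (and `s2`) lies on an equal-objective valley. The calibration
self-test (`run_parameter_recovery`) reflects this: across fitting seeds
the blur recovers to well under 1% while the individual amplitudes
scatter along the valley. Any parameter vector on the valley produces
images with the same intensity statistics, so this does not affect the
simulated images themselves — but reported amplitude values should not
be interpreted individually. The residual moment mismatch after fitting
(~2·10⁻² standardized) is set by the Monte-Carlo noise of the single
target realization's skewness at the phantom sizes used (≈ 45k in-mask
voxels) and shrinks with volume size.

## Gradient entropy

Perceived quality is tracked by the entropy of the normalized absolute
horizontal gradient of each axial slice,
`F = −Σ h log2 h`, `h = |g * [1 −1]| / Σ|g * [1 −1]|`, computed with a
valid (unpadded) convolution along the in-plane horizontal axis as the
metric is defined; a constant slice returns 0 (the concentrated-mass
limit). Volume scores average slices that intersect the brain mask.
Whether both in-plane directions should be pooled is an open choice; the
single-direction form is implemented as printed in the metric's source.
`F` is exactly invariant to intensity scaling and offsets. Quality
comparisons between arms are made on the shared LF grid, because `F`'s
ceiling grows with the per-slice pixel count and comparing across grids
would confound degradation with grid size.

## Synthetic phantoms

Each phantom is an ellipsoidal "brain" (≈ 96 × 96 × 20 voxels at
1 × 1 × 5 mm) with white-matter bulk (intensity 1.0), a cortical
gray-matter band (1.25), two ventricle-like CSF lobes (0.35), ~6% smooth
random texture, normalized to unit in-brain mean, plus seeded Gaussian
acquisition noise inside the mask (default SD 0.02, SNR ≈ 50, typical of
3 T FLAIR). Noise can be injected separately (`add_acquisition_noise`)
so experiments that edit the clean tissue image first — contrast
modulation in particular — keep lesion and background noise statistics
identical.

Lesions are superellipsoids: the in-plane footprint at the widest slice
is chosen as exactly the pixel count matching the requested area (error
≤ 1 pixel), and cross-sections taper toward the lesion's z-ends like a
3-D cap, so a single patient contributes per-slice areas from near zero
up to the nominal size — as real tumors do, and as the per-slice size
analyses require. Sub-labels form concentric shells. The contrast
multiplier raises each sub-label's mean intensity additively while
tissue texture keeps its native amplitude (FLAIR lesions are
homogeneously bright, not texture-amplified). Mass effect is a radial
Gaussian-decay displacement field around the lesion centroid, applied to
the tissue by resampling before the lesion is painted, so isointense
lesions retain structural signal. Identical specs and seeds give
bit-identical phantoms.

What the phantom does **not** emulate: real anatomy (gyri, vessels,
periventricular detail), multi-sequence contrast, partial-volume effects
at tissue interfaces, scanner artifacts, or inter-site intensity
variation. Passing tests therefore demonstrate that the *harness*
behaves correctly and reproduces the expected qualitative relationships
at desk scale, not that any particular clinical sensitivity number
transfers to real cohorts.

## Contrast modulation

Per axial slice and lesion sub-label, intensities are multiplied by the
factor that moves the sub-label's mean linearly toward the slice's
non-lesional in-mask mean `m`: at scale 100 the volume is returned
bit-identical, at scale 0 every sub-label's mean equals `m` exactly
(isointense). Multiplicative scaling preserves relative within-lesion
heterogeneity; a per-voxel affine pull toward `m` was rejected because
it collapses the lesion to a constant patch whose anomalous smoothness
*increases* detectability as contrast falls, inverting the expected
contrast–detectability relationship. Non-lesion voxels are never
touched. "Non-lesional tissue" means in-mask, label-0 pixels of the same
slice; a slice with lesion but no such tissue is skipped with a warning.
Within-lesion SNR (mean/SD of lesion voxels, population SD) ranks lesion
homogeneity; cohort selection keeps the top `ceil(fraction·N)` patients,
ties broken by cohort order.

## Datasets and classifier

Slices intersecting the brain mask become records with label
(any lesion pixel), physical lesion area (pixel count × pixel area, so
sizes are comparable across grids), and lesion contrast ((mean lesion −
mean non-lesional)/non-lesional SD). Splits are patient-exclusive with
train size `floor(ratio·N)` clamped so both sides are non-empty.
Training augmentation flips slices horizontally with probability 0.5 via
a seeded iterator and refuses test records.

The default backbone (`baseline_small_cnn`) is a compact convolutional
model chosen to train in seconds on one CPU while sharing the inductive
bias of the full-scale CNN it stands in for: slices are resized to
64 × 64 and standardized per slice; a fixed filter bank of
scale-normalized Laplacian-of-Gaussian kernels (SDs 1, 2, 4 px) is
reduced by signed max pooling on a 4 × 4 grid plus global statistics,
concatenated with an 8 × 8 mean-pooled copy of the image, and classified
by an MLP head (layers 64/32, Adam, lr 2·10⁻³, batch 32, 60 epochs,
seeded). Trial experiments average scores over a small ensemble of 3
seeds for variance reduction. A `densenet121` configuration records the
full-scale transfer-learning hyperparameters (100 epochs, Nadam-class
adaptive optimizer, lr 0.002, batch 32) but requires an external
deep-learning backend.

## Evaluation harness

AUC uses the rank-average (Mann–Whitney) tie convention; F1 is
2PR/(P+R) with 0 for degenerate cases; the chance benchmark draws
uniform coin-flip predictions (probability 0.5 per slice, configurable)
for 1000 trials. DeLong's test uses the structural-components covariance
estimator on paired scores; both arms of a phantom trial share their
axial grid by construction (HF phantoms use 5 mm slices), so pairing is
exact. Detection outcomes for the sensitivity analyses use the
Youden-optimal threshold from training data. The logistic regression of
detection on area and contrast reports Wald z and two-sided p per
covariate, falling back to a penalized fit (flagged) under separation.
Sensitivity-ratio curves divide LF by HF sensitivity over positive
slices below each size threshold, flagging bins with < 5 slices as
unstable and zero HF sensitivity as undefined. Patient-level decisions
take the maximum of a truncated moving mean of slice scores
(window `max(1, round(15 mm / thickness))` = 3 slices at 5 mm) against a
threshold chosen from observed training max-scores by maximizing
patient accuracy, ties toward the higher threshold (favoring
specificity); all-identical traces trigger a midpoint fallback with a
flag. p-values are reported unadjusted.

## Study conditions of the packaged experiments

* **Two-arm trial** — 60 patients (42 lesional, 18 control), split 0.7
  patient-exclusively. Lesion areas: 70% "prominent" uniform 5–20 cm²,
  30% "subtle" log-uniform 1.5–5 cm² (a pooled cohort dominated by
  tumor-scale pathology); contrast multipliers uniform 1.5–2.0; z-extent
  3–6 slices; 3 sub-labels.
* **Contrast ladder** — 28 lesional (areas 2–6 cm², contrast 1.5–1.8,
  mass effect 1.5 mm) + 14 controls; top 50% by lesion homogeneity
  retained; scales 100/80/60/40/20/0%; modulation acts on the clean
  tissue image with acquisition noise added afterwards, then the LF
  transform; one classifier ensemble per scale on the simLF arm.
* **Patient-level study** — per-cohort design: a prominent-lesion
  training cohort (16 lesional, 10 control; 8–16 cm², contrast 1.7–2.0)
  matching the clean 12-patient test cohort (6 lesional, 6 control).
* **Calibration self-test** — 3 phantom pairs on a 128 × 128 × 24 grid,
  LF targets generated with the default parameters, 5 fitting seeds,
  2 optimizer starts, 120 iterations.

Problem sizes were fixed at these values as the package's desk-scale
defaults; all experiments complete in a few minutes on one CPU.

## Numerical choices and degenerate inputs

Population (biased) SD and skewness throughout; skewness of a constant
distribution is 0 with a degeneracy flag. Constant slices have gradient
entropy 0. Interpolation constants: tri-linear for intensities and
masks (re-binarized at 0.5), nearest for labels. Reslicing identity when
target spacing equals input spacing. NIfTI affines must be orthogonal up
to 10⁻³ (oblique volumes are rejected with advice to resample); voxel
spacing is rounded to 10⁻⁶ mm to absorb the format's float32 affine.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; experiment-level seeds derive per-stage
child seeds from a single stream, and no global RNG state is used.

## Known limitations

* Appearance-only degradation: no contrast-mechanism or artifact
  modelling; conclusions about pathologies whose conspicuity depends on
  relaxation-time changes at low field are out of reach.
* The two noise amplitudes of the transform are not separately
  identifiable from histogram moments (see above).
* Isointense phantom lesions remain partially detectable through
  residual cues (global-versus-local mean mismatch inherent in the
  per-slice isointensity definition, texture-amplitude differences,
  deformation); the same caveat applies to the original experimental
  design this mirrors.
* The baseline classifier is far weaker than a pretrained deep network;
  absolute sensitivities are phantom- and model-specific, and only the
  qualitative relationships (arm parity on prominent lesions,
  size-dependent low-field loss, contrast ladder direction) are claimed.
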