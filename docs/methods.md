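# Methods

## Problem and measurement model

The analysis asks whether the high-uptake subvolume of a baseline FDG-PET
scan of a pancreatic tumour spatially predicts residual metabolic activity
after chemoradiotherapy. Its primitive objects are:

* **SUV images.** Reconstructed activity concentration (Bq/ml) is converted
  to the body-weight standardized uptake value,
  `SUV = activity × body_weight[g] / injected_dose[Bq]`, dimensionless under
  the 1 g/ml density convention. No decay correction is applied beyond the
  vendor reconstruction; uptake time is recorded but unused. SUVmax is the
  single hottest voxel inside an axis-aligned elliptical ROI drawn around
  the tumour (ties broken at the smallest linear index). SUVpeak-style
  neighbourhood averaging is deliberately not used.
* **Threshold subvolumes.** A voxel joins a subvolume when its center lies
  inside the ROI and its SUV is **at or above** `fraction × SUVmax(ROI)`
  (relative mode) or a fixed SUV (absolute mode). The inclusive comparison
  makes `fraction = 1` return exactly the SUVmax voxel. By default only the
  26-connected component containing the SUVmax voxel is kept: the analysis
  concerns a single tumour focus, and the rule preserves threshold nesting
  (`mask(f1) ⊆ mask(f2)` whenever `f1 > f2`). Whether the original analysis
  kept disconnected islands is not documented; our default is a declared
  choice and can be switched off.
* **Contour propagation.** Post-treatment subvolumes are segmented on the
  post-scan grid and carried to the planning grid through a dense
  displacement field `d(x)` in the pull-back convention: the propagated mask
  at planning point `x` is the post-scan mask sampled at `x + d(x)`
  (trilinear, re-binarized at 0.5, out-of-grid = background). Float
  resampling rather than nearest-neighbour keeps volumes well behaved under
  shrinkage (a uniform scaling by `s` about a point changes a propagated
  mask volume by `1/s³`, which the tests verify against the analytic
  Jacobian). The non-rigid registration *optimizer* is explicitly out of
  scope — clinically it was a validated commercial tool; here fields are
  inputs with exact phantom ground truth — but the field is validated
  (finite-difference Jacobian determinant, folding fraction, maximum
  displacement) and a translation-only rigid search (normalized
  cross-correlation, coarse-to-fine, deterministic tie-breaks) stands in
  for the rigid pre-alignment step. Rotation is omitted: patients are
  scanned immobilised in the treatment position.
* **Overlap statistics.** `OF(A|B) = 100·|A∩B|/|B|` on voxel counts, with
  the post-CRT subvolume (or the GTV, for coverage) as reference B.
  Full precision is kept internally; table output rounds half-up to one
  decimal. Cohort summaries use the arithmetic mean, extrema, and the
  midpoint-of-two-central-values median. Response of SUVmax is tested with
  a two-tailed paired t-test (`t = mean(d)/(sd(d)/√n)`, df `n−1`); identical
  pre/post vectors return `t = 0, p = 1`, while a zero-variance non-zero
  shift is an error (t would be infinite).

## Phantom generator

Real scan pairs from the cohort are not available, so the study conditions
are emulated by paired phantoms with exact ground truth:

* **Baseline uptake**: a 3D Gaussian profile truncated at an ellipsoidal GTV
  and rescaled so the hottest voxel equals the requested peak, over a
  uniform background. Gaussian iso-surfaces give analytic oracles for the
  threshold subvolumes (semi-axis of the `f·peak` iso-ellipsoid:
  `σ·√(−2·ln g)` with `g = (f·peak − bg)/(peak − bg)`, `σ = radius/2`).
* **Residual uptake**: a smaller truncated-Gaussian region whose
  voxel-counted containment inside the baseline 40 %-of-peak region is a
  controlled parameter ρ ∈ [0, 1]. The residual center is moved outward
  from the baseline peak along the first grid axis; the offset solving the
  requested ρ is found by bisection on the voxel-counted containment
  (tolerance 0.005 mm; recovery error on default grids ≈ 0.003). If ρ is
  geometrically unreachable the error names the limiting axis.
* **Response geometry**: uniform scaling by `shrinkage` about the tumour
  center composed with a caudal translation. The post image is evaluated
  analytically through the inverse map, and the exact forward displacement
  field `d(x) = (s−1)(x−c) + t` is returned as ground truth. The caudal
  axis is the third grid axis (increasing index = inferior), configurable.
* **Measurement physics**: normalized Gaussian PSF blur
  (`σ = FWHM/2.355` per axis, reflective boundary) — this reproduces the
  recovery-coefficient effect, a monotone decrease of measured SUVmax in
  FWHM for small volumes, which is why post-CRT segmentation needs ≥60 %
  thresholds — followed by additive zero-mean Gaussian voxel noise in SUV
  units, seeded (identical spec + seed ⇒ bit-identical phantoms). Noise is
  additive in SUV rather than Poisson in counts because the pipeline
  operates on reconstructed SUV images.

**Default conditions** (chosen once, as cohort-scale values): 64³ grid at
2 mm; GTV radii (25, 22, 18) mm ≈ 41.5 cm³ (the cohort mean GTV); baseline
peak SUV 8.0 and post peak 3.6 (cohort medians); background SUV 1.0
(abdominal soft tissue); residual radii (10, 9, 8) mm ≈ 3 cm³; containment
0.8; shrinkage 0.8 with a 10 mm caudal shift (the documented
shrink-and-move response pattern); PSF FWHM 6 mm (clinical whole-body PET);
noise sd 0.2 SUV. The containment fraction has no published quantitative
counterpart; it is the generator's free parameter, and only qualitative
agreement with the published overlap tables (high containment in most
patients) constrains its default.

**What the phantoms do not model**: respiratory motion, attenuation and
reconstruction artefacts, irregular tumour shapes, non-affine deformation,
heterogeneous background organs (liver, bowel) that complicate absolute-SUV
thresholding. Passing phantom tests therefore demonstrates correctness of
the geometry/statistics chain under the stated model, not clinical
segmentation accuracy.

## Cohort fixtures

Per-patient SUVmax, subvolume volumes and overlap fractions for the
17-patient cohort are shipped as CSV transcriptions, with the print's
symbols (`mCR`, `±`, `§`, `¢`, `¤`) preserved as missing-data codes. The
analysis set for summary statistics is the 9 patients with a complete
overlap row (1, 2, 4, 5, 7, 8, 14, 16, 17); only this set reproduces the
published means and ranges. `reproduce_tables` recomputes the analysis-set
statistics at full precision, rounds half-up to one decimal, and compares
to the published values at ±0.05 (one-decimal rounding slack).

The eligibility-flag table is a *synthetic* reconstruction
(`cohort_flags_synthetic.csv`): the published accounting gives the reason
counts (4 metabolic complete responses, 1 non-avid, 1 missing post scan,
1 inseparable uptake, 1 elevated glucose; 9 analysable pairs), but not
which symbol row carries which reason, and individual glucose values are
unpublished. Only the counts are asserted. The source also mentions a
sixth reason (progression with new liver metastases) that cannot be
reconciled with the five-reason accounting; the five-reason version is
used. Similarly, the published SUVmax medians (8.0 / 3.6) are not
recoverable from the printed per-patient columns under any inclusion rule
we could construct, and the per-patient GTV-coverage values behind the
published 50.8 % (elsewhere 50.3 %) mean are unprinted — neither is
asserted or reported.

## Numerical choices and degenerate inputs

* Voxel-center in/out tests everywhere (no partial-volume weighting), so
  mask volume = count × voxel volume.
* Relative-mode segmentation of an all-zero ROI raises a "non-avid" error,
  mirroring the excluded non-avid tumour; empty reference volumes are
  errors in `overlap_fraction`, but the per-patient pipeline records a
  missing value (NaN) when a tiny high-threshold post subvolume disappears
  under propagation — the published tables show exactly such near-voxel
  Post90 volumes.
* Rigid search ties resolve to the smaller translation norm, then
  lexicographic order; sub-voxel refinement only replaces an integer
  optimum on strict NCC improvement, so exact integer shifts are recovered
  exactly.
* Field inversion uses fixed-point iteration `d⁻¹ ← −d(x + d⁻¹(x))`
  (30 iterations), adequate for the smooth affine-plus-translation phantom
  fields (round-trip Dice ≥ 0.99).
* The paradoxical SUV rise seen in one cohort patient (4.0 → 7.9) is
  representable but must be requested explicitly
  (`allow_post_increase=True`).

## Problem sizes

Default test and acceptance runs use 64³ phantom grids at 2 mm spacing
(≈ 0.26 M voxels), 20-seed nesting batteries, 4 containment-recovery
levels and 3–5 noisy replicates per containment level; a full suite run
completes in well under a minute of CPU on these sizes. The brute-force
oracle comparisons use 32³ volumes.

## Known limitations

The deformation-field contract (positive Jacobian, pull-back sampling) is
verified on phantom fields only; no per-patient registration accuracy can
be reproduced since the original fields are not recoverable. Absolute-SUV
segmentation is implemented but, as in the original analysis, is of limited
use near high-background organs, which the phantom's uniform background
does not emulate. The t-test is reported without a published reference
value because the source's three printed p-values are mutually
inconsistent and the entering pairs are unstated.
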