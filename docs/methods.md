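# Methods

## Scope and model

The package quantifies carotid plaques on a 3D intensity volume in slices
perpendicular to the vessel axis and evaluates the resulting scores as
predictors of intraoperative microembolic signals (MES). Two per-patient
scores are produced. POR (plaque occupation rate) is plaque
cross-sectional area over vessel cross-sectional area × 100 per slice; the
slice maximizing it is the anatomic stenosis landmark. CR (contrast
ratio) is mean plaque intensity divided by a single muscle reference
intensity; it is evaluated both at the max-POR slice (CR_max occupation)
and at the slice of maximum plaque intensity within ±25 mm of it (CR_max
intensity). A patient is *identified* when those two slices lie within
0–2 mm (inclusive) of each other. The statistics layer then measures how
each score discriminates MES-positive from MES-negative patients.

## Reformation geometry

* The centerline is an interpolating spline through the supplied lumen
  reference points (cubic for ≥ 4 points, lower order otherwise),
  re-parameterized by arc length on a dense polyline (200 samples/mm) and
  sampled every 1.0 mm. The trailing remainder shorter than one spacing
  is dropped, so sample spacing is uniform by construction;
  `CenterlinePath.total_length` retains the full spline length.
* In-plane frames are rotation-minimizing (double-reflection transport),
  not Frenet: Frenet frames are undefined on straight segments and twist
  at inflections, while RMF transport accumulates zero rotation on a
  straight vessel (tested to 1e-6). The initial axis is the world x-axis
  projected onto the first normal plane (y-axis fallback).
* Slices are point samples on perpendicular planes (no slab averaging by
  default; `slab_half_width` exposes a 3-plane average) on a 40 × 40 mm
  field of view at 0.5 mm — wide enough to cover the vessel and the
  adjacent sternocleidomastoid muscle. Values are trilinear; label
  volumes use nearest-neighbor. Samples outside the volume are NaN and
  excluded from every statistic; a centerline leaving the volume raises
  an error naming the first offending arc length.
* Linearity of trilinear interpolation makes reformation commute with
  global intensity scaling (bit-for-bit for power-of-two factors, to ~1
  ulp otherwise), which is why CR is invariant to scanner gain.

## Measurement conventions

Decisions the measurement stage fixes where the procedure is otherwise
underdetermined:

* ROI "signal intensity" is the arithmetic mean over the traced mask —
  the standard ROI statistic, and the natural match to the muscle
  denominator.
* The POR denominator is the outer-wall-bounded vessel cross-section
  *including* the plaque, so POR ∈ [0, 100] by construction; a
  patent-lumen denominator could exceed 100 and is rejected by the
  containment check.
* All argmax selections (POR, plaque intensity, muscle area) break ties
  to the lowest (most caudal) slice index, deterministically.
* The ±25 mm window at 1.0 mm spacing contains 51 candidate slices;
  windows clipped by the stack boundary are used as-is, with a warning
  reporting the reduced candidate count.
* The muscle reference is the in-window slice with the largest traced
  muscle area ("displayed as larger" read as area, not conspicuity); its
  mean intensity is the single denominator for both CRs. This shared
  denominator plus the window containing the max-POR slice guarantees
  CR_max intensity ≥ CR_max occupation for every patient, with equality
  under identification — an invariant asserted on every profile.

## Synthetic data

**Score-level cohorts.** The study conditions are group sizes 19/56
(MES+/MES−) for the full cohort, 11/32 for the non-identified subgroup
and 8/24 for the identified subgroup. Within-group CR distributions are
not published beyond scatter; the simulator adopts equal-variance normals
with sd 0.20 (a realistic spread for muscle-normalized T1 ratios, where
tissue classes span roughly 0.9–2.2) and a fixed MES-negative mean of
1.30 (the lipid/fibrous range). MES-positive means (1.742, 1.640, 1.664,
1.563) are then fixed by inverting the binormal closed form
AUC = Φ((μ⁺−μ⁻)/√(2σ²)) at the published AUC values 0.941, 0.885, 0.901
and 0.824. The identified subgroup uses disjoint uniform supports
(1.70–2.20 vs 1.00–1.50), reproducing its perfect empirical separation on
every draw. Scores are drawn independently per column (calibration mode)
because each published AUC is a marginal, per-score quantity; the
optional `enforce_order` mode instead derives CR_max occupation from
CR_max intensity minus an exponential decrement, restoring the row-wise
ordering the measurement stage guarantees at the cost of an exactly
calibrated occupation marginal. Covariate columns are Bernoulli/normal
conditional on the MES label with defaults matching the published
risk-factor table (e.g. ulceration 10/19 vs 13/56, symptomatic lesion
16/19 vs 31/56, age 69.6 ± 7.8 vs 69.9 ± 6.8).

**Phantoms.** A phantom is a voxelized tube (default 96 × 96 × 160 at
0.5 mm — comfortably covering a 50+ mm lesion): outer radius 5 mm, 1 mm
wall, black-blood lumen, an angular plaque wedge whose triangular
thickness profile sets the designed per-slice POR analytically, a linear
plaque intensity fall-off from `cr_target × 100` at the designed peak
slice, and a parallel muscle cylinder at intensity 100 whose radius
profile peaks at a designed slice. Intensities are arbitrary units with
muscle pinned at 100, so CR targets are read directly; noise is additive
Gaussian (not Rician — a deliberate simplification of MR magnitude
statistics). Voxels are classified by center point; labels partition the
grid. Straight phantoms are built grid-aligned so that perpendicular
reformation samples land exactly on voxel centers: trilinear
interpolation then introduces no partial-volume blending and designed CR
values are recovered exactly (the coincident-peak phantom yields
1.85/1.85 identified; the 10 mm-offset phantom yields 1.69/1.91, not
identified). Curved phantoms (circular arc, default radius 400 mm) are
used for geometry checks, where interpolation blur limits agreement to a
few percent. Voxel-count POR differs from the analytic design by at most
the perimeter-voxel bound 100 · perimeter count · voxel area / vessel
area, which the tests assert slice by slice.

What the phantoms do *not* emulate: partial-volume averaging, motion,
coil sensitivity, Rician noise, irregular plaque morphology, or tracing
variability. Passing phantom tests therefore demonstrates the
correctness of the geometry and bookkeeping, not robustness to real MR
artifacts.

## Statistics

* AUC is the rank-based (Mann–Whitney) estimator with mid-rank ties;
  tested identical to the trapezoidal area under the empirical ROC to
  1e-12 and cross-checked against scikit-learn.
* The operating points use positivity = score ≥ threshold over observed
  thresholds; the reported cutoff minimizes √(FPR² + (1−TPR)²), ties
  broken toward higher specificity and then the higher threshold (for
  separated groups this returns the smallest positive-group score).
* Proportion CIs are Clopper–Pearson exact. The published table's CI
  method is unstated and its identified-column values are not consistent
  with Clopper–Pearson, so printed CIs are not used as calibration
  targets.
* Paired AUC comparison uses DeLong's structural components (the cited
  paired-ROC procedure's internals are not reproduced; the two are
  asymptotically equivalent). The variance estimator is algebraically
  identical to a grouped delete-one jackknife — the test suite asserts
  agreement to 1e-9 — and the p-value is cross-checked against an
  independent R implementation (pROC). Empirical type-I error at nominal
  0.05 is verified to lie in [0.03, 0.07] over 5000 null replicates at
  the study's 19/56 group sizes. A paired-bootstrap alternative
  (stratified patient resampling) is provided.
* Binary covariates are screened with Fisher's exact test by default
  (two-sided by summing hypergeometric probabilities ≤ the observed
  table's; a zero margin gives p = 1); χ² with optional Yates correction
  is available since both appear in standard practice. Continuous
  covariates use Mann–Whitney (exact when n_x·n_y ≤ 400 and tie-free,
  asymptotic with tie correction otherwise). Screening admits p < 0.2.
* The logistic model is Newton ML (relative log-likelihood tolerance
  1e-10) with Wald CIs on the odds-ratio scale; CR enters per 1.0 ratio
  unit, unstandardized. Complete or quasi-complete separation (detected
  via the optimizer and a |β| > 30 guard) raises an error instead of
  returning estimates — on 75-patient cohorts with strong predictors
  this is a real occurrence, and the pipeline records it rather than
  reporting divergent odds ratios.
* Historical-control comparisons use the CI-overlap rule (significant
  only for strictly disjoint 95% CIs; touching intervals are NS). The
  published 2D single-slice control row is consumed as printed constants.

## Problem sizes and determinism

The simulation summary uses 1000 replicate cohorts for the full-cohort
means and 2000 for the smaller non-identified subgroup (whose per-cohort
AUC is noisier), giving Monte-Carlo standard errors of ~0.001 — an
order of magnitude below the ±0.01 calibration tolerance. All
randomness flows from one integer seed through `numpy` `SeedSequence`
spawning, so every output (CSV/JSON included) is bit-reproducible;
pipeline artifacts carry the config hash and seed.

## Known limitations

* The binormal score model is a modeling choice, not an empirical fit;
  only its AUC structure, not its tails or calibration, matches reality.
* Phantom exactness relies on grid alignment; oblique vessels measure
  with interpolation blur that the CR tolerance tests deliberately avoid.
* `enforce_order` trades marginal calibration of the occupation score
  for the row-wise ordering constraint; the two modes cannot be combined.
* The logistic model reports Wald inference only; profile-likelihood CIs
  are not implemented.
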