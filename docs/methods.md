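# Methods

## Calibration model

Opportunistic QCT replaces the in-scan calibration phantom of conventional
QCT with a fixed per-scanner conversion, fitted once from phantom scans
acquired separately from the patient ("asynchronous" calibration). The
conversion is affine, `BMD = a · HU + b`, estimated by ordinary least squares
with nominal hydroxyapatite density as the response and measured HU as the
predictor, so the stored pair (a, b) maps attenuation directly to density in
the printed form. Fit diagnostics are R² and the standard error of the
estimate, SEE = √(RSS / (n − 2)), in mg/cm³ (defined as 0 for n = 2, where
the fit is exact).

For decommissioned scanners calibrated retrospectively from an in-plane
phantom, all dated observations over the phantom-present period are pooled
into a single fit rather than fitted per date and averaged: one scanner, one
conversion equation, regardless of how many years of routine scans
contributed. The registry shipped with the package carries the conversion
equations of five clinical MDCT scanners at 120 kVp.

Contrast-enhanced scans are corrected with additive BMD offsets applied
*after* conversion (0 for non-enhanced, −8.6 mg/cm³ arterial, −15.8 mg/cm³
portal-venous). The offsets are in density units, hence additive on the BMD
side of the affine map; they were established on a different scanner model
and therefore live in an editable table rather than in the conversion
itself. Converted BMD is never clamped: negative values are representable
and left to downstream classification to flag.

Because the conversion is affine, averaging HU over vertebrae and then
converting equals converting per vertebra and then averaging (within one
scan, where a single offset applies); the implementation averages HU first.

## Scanner stability

Long-term stability is quantified per phantom insert by OLS of measured HU
on elapsed time — in fractional years of 365.25 days since the first
observation — giving the drift slope SL (HU/year), the SEE (HU), and
CV = 100 · SEE / |mean HU| (percent). Per-scanner CVs are averaged across
inserts by root-mean-square, √(Σ CVᵢ²/k). "Two phases of the calibration
phantom" is read as two density inserts (water- and bone-equivalent rods);
the headline per-scanner slope is taken from the densest insert, with all
per-insert fits retained on the report so either convention is inspectable.

## Densitometry

ROIs are circles of configurable radius on a midsagittal stack
(default 15 mm thick): a voxel belongs to the ROI when its center lies
within the radius in the in-plane directions and within half the stack
thickness along the sagittal (first array) axis. Voxel membership is a
voxel-center test with no partial-volume weighting — deterministic and
exactly reproducible by an independent oracle. Coordinates are 0-based voxel
indices; distances are in mm via the voxel spacing. The default ROI radius
in synthetic volumes is 40 % of the trabecular compartment's minor in-plane
radius, which keeps the circle strictly inside trabecular bone for the
shipped geometry.

Patient-level HU is the unweighted mean over included vertebrae; vertebrae
flagged for fracture, degeneration, or hemangioma are excluded (the flags
are inputs — a radiologist's call, not detected from images). A patient with
no assessable vertebra raises a not-assessable error rather than returning a
value.

Classification partitions the real line: QCT osteoporosis below 80 mg/cm³,
osteopenia 80–120 inclusive; DXA osteoporosis T ≤ −2.5, osteopenia
−2.5 < T ≤ −1. The reported DXA T-score is the minimum over remaining
lumbar (L1–L4) and total-femur sites; when at most one lumbar site survives
exclusion, the minimum is taken over the femur sites alone.

## Fracture grading and incident definition

Deformity grade derives from the worst of the anterior, middle, and
posterior height ratios against a reference height: reduction ≥ 20 % is
grade 1, ≥ 25 % grade 2, ≥ 40 % grade 3 (left-closed intervals, standard
semiquantitative thresholds, stored in an editable table). A tolerance of
10⁻¹² on the threshold comparison keeps ratios that land exactly on a
boundary from being pushed below it by floating-point division.

A vertebra counts as an incident fracture when it was normal at baseline and
deformed at follow-up, or when a consolidated baseline fracture (no marrow
edema on recent MRI) progressed by at least one grade. A vertebra with
active fracture signs at baseline is excluded from ascertainment entirely,
not merely blocked from progression. A patient is incident-positive when any
vertebra is.

## Risk statistics

**Baseline tests.** Continuous variables: two-sample t-test, Welch by
default (the pooled-variance variant is a config switch). Categorical
variables: Pearson χ² on the contingency table without continuity
correction.

**Cox models.** Hazard ratios are reported per SD *decrease*: the predictor
is standardized as z = −(x − mean)/SD with mean and SD computed over the
full cohort at baseline (not within outcome groups), so exp(β̂) is the risk
multiplier per one-SD reduction. Covariates enter untransformed: age in
years, sex as a male indicator, prevalent maximum deformity grade as an
ordinal (category dummies were considered and rejected as the default
because a single maximum grade is naturally ordered; the ordinal encoding is
what the orchestrator uses). Ties are handled by the Breslow approximation,
fitted by the package's own Newton-Raphson on the Breslow partial likelihood
with analytic gradient and Hessian, step-halving, and SEs from the inverse
observed information; Efron tie-handling is available through lifelines, and
on tie-free data the two agree to numerical precision (verified in tests).
95 % CIs are Wald, exp(β̂ ± 1.96 · SE). Zero events raise a no-information
error; a singular Hessian or non-convergence raises a diagnostic error
carrying the likelihood trace.

Note on coverage: because the standardization uses the sample SD, the
coefficient's estimand in any one dataset is the generating log-HR scaled by
(sample SD / generating SD); Wald CIs attain nominal coverage against that
estimand, and the recovery tests check them against it.

**Kaplan-Meier.** Product-limit estimates per diagnostic stratum via
lifelines; censored subjects leave the risk set at their censoring time.
With no censoring the estimate equals the empirical survival function.

**ROC.** Lower predictor values indicate higher risk, so the AUC is the
Mann-Whitney statistic on negated scores with ties counted one half; the CI
uses the DeLong placement-value variance (a bootstrap CI was considered and
left out: DeLong is deterministic and standard). For each target specificity
the reported cutoff is the largest threshold c such that classifying
score ≤ c as positive keeps specificity ≥ target — which maximizes
sensitivity — with ties between equally sensitive thresholds broken toward
the lower cutoff. When no threshold attains the target, the row is omitted.

**Orchestration.** `run_study` executes the baseline tests, the 2 × 4 Cox
grid ({BMD, T-score} × {unadjusted, +age, +age+sex, +age+sex+prevalent
fractures}), KM strata per modality, and both ROC analyses, returning a
JSON-serializable report (byte-identical across runs at a fixed seed);
not-estimable cells (e.g. zero events) are null rather than errors.

## Synthetic data

The generators define the study conditions; all are deterministic under a
fixed seed (numpy `default_rng`).

**Cohorts.** Default size 16 fracture / 68 non-fracture patients.
*Group-conditional* mode draws (BMD, T-score) per outcome group from a
bivariate normal — fracture group BMD 56.7 (31.6), non-fracture 93.3 (41.7)
mg/cm³; T-scores −2.2 (1.8) and −1.6 (1.7) — with BMD truncated at zero by
resampling (the fracture group's SD admits negative draws). The BMD–T-score
correlation defaults to 0.6; no empirical value is available, and it is
documented as a free parameter. Ages are group-conditional normals
(73.9 ± 7.4 vs 67.7 ± 8.6 years), 80 % women, prevalent-grade probabilities
(0.46, 0.13, 0.19, 0.21), contrast phases 48 % non-enhanced with the
remainder split evenly. Follow-up times are drawn uniformly from the
emulated cohort's observed ranges (events 19–1891 d, censoring 373–2425 d).
*Hazard-driven* mode draws a standard-normal per-SD-decrease score z, sets
BMD = pooled mean − pooled SD · z (86.3, 42.4; untruncated, so z stays
exactly standard normal), and assigns exponential event times with hazard
h₀ · HRᶻ (default HR 4.07 per SD decrease) under uniform censoring in the
window. When h₀ is not given it is calibrated by root-finding on the
closed-form marginal event probability (Gauss-Hermite over z) to hit the
target event rate — 0.19 by default, matching the emulated cohort; recovery
experiments use 0.40.

**Phantom series.** For each insert density d and visit at elapsed time t
(bimonthly, 61-day cadence, default 4 years):
HU = ((d − b)/a + drift · t) · (1 + ε), ε ~ N(0, (CV/100)²) — linear drift in
HU with multiplicative measurement noise. Defaults mirror a decommissioned
scanner's QA record: conversion (0.985, 15.516), drift −2.29 HU/year, CV 1 %.

**Volumes.** An elliptic-cylinder vertebral body (default semi-axes
18 × 14 mm, height 30 mm, 1 mm isotropic voxels) with a 2-voxel cortical
shell at 400 HU around a trabecular interior whose HU is the inverse
calibration of the requested true BMD, on a −50 HU background, plus optional
i.i.d. Gaussian noise. A fracture compresses the body height uniformly by
the given fraction; ground truth carries the true BMD, an ROI guaranteed to
lie inside the trabecular compartment, and the resulting heights against the
uncompressed reference.

What the generators do *not* emulate: CT physics (beam hardening, scatter,
patient-size effects), anatomical shape variation, correlated age–BMD–grade
structure (independent unless configured), informative censoring, and
inter-reader variability in ROI placement and grading. Passing tests
therefore validate the computational pipeline and its statistical
properties under the stated model, not clinical performance on real scans.

## Problem sizes and numerical choices

Recovery experiments use 200 replicates (drift: bimonthly 4-year series;
hazard ratio: n = 500 per replicate, with a single n = 5000 fit for the
headline check) and a 20 000-patient cohort for the AUC check — sizes at
which Monte Carlo error is a small fraction of the tolerance bands. Newton
iterations stop at a gradient sup-norm below 10⁻¹⁰; the brute-force oracles
(grid search over β with step 10⁻⁴, exhaustive pair counting, hand
product-limit) are implemented in the tests, independent of the library
paths they check. Elapsed phantom time is day-quantized by calendar dates
before conversion to years, and test oracles evaluate at the same quantized
times.
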