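# oppqct — opportunistic QCT osteodensitometry and fracture-risk analysis

Routine CT scans acquired for unrelated indications contain enough
information to screen for osteoporosis: the mean attenuation of trabecular
bone in the lumbar vertebrae, converted to volumetric bone mineral density
(BMD, mg/cm³ hydroxyapatite equivalent) through a per-scanner calibration,
predicts future vertebral fractures. `oppqct` implements this opportunistic
quantitative-CT (QCT) workflow end to end for radiologists and biostatistical
researchers studying fracture risk:

- **Asynchronous calibration** — per-scanner affine conversions
  `BMD = a · HU + b` fitted by least squares on density-reference phantom
  measurements, with additive BMD offsets for arterial (−8.6 mg/cm³) and
  portal-venous (−15.8 mg/cm³) contrast phases. A registry of published
  conversion equations for five clinical MDCT scanners ships with the package.
- **Scanner-drift QA** — per-insert linear drift SL (HU/year) and the
  coefficient of variation of the standard error of the estimate,
  CV = 100 · SEE / |mean HU|, RMS-averaged across inserts.
- **Densitometry** — circular trabecular ROIs on midsagittal stacks of
  vertebral volumes, per-patient averaging over assessable vertebrae, and
  diagnostic classification (QCT: osteoporosis < 80, osteopenia 80–120 mg/cm³;
  DXA/WHO: T ≤ −2.5, −2.5 < T ≤ −1), including the lowest-T-score reporting
  rule with fallback to the hips.
- **Fracture ascertainment** — semiquantitative vertebral deformity grades
  0–3 from height reductions (20 / 25 / 40 % thresholds) and the
  incident-fracture rule (new deformity, or ≥ 1 grade progression of a
  consolidated fracture; vertebrae with active fracture signs excluded).
- **Risk statistics** — Welch/pooled t and χ² baseline tests, Cox
  proportional-hazards models reporting the hazard ratio per SD *decrease*
  exp(β̂) with Wald 95 % CI (Breslow ties by the package's own Newton solver,
  Efron via lifelines), Kaplan-Meier strata per diagnostic category, and ROC
  analysis (Mann-Whitney AUC, DeLong CI, cutoff-at-target-specificity table).
- **Synthetic data** — seeded generators for phantom QA series, cohorts
  (group-conditional or hazard-driven), and toy vertebral volumes, so the
  whole pipeline is testable without any clinical data.

## Worked example

```python
from oppqct import (CohortSimConfig, simulate_cohort, run_study)

cohort = simulate_cohort(CohortSimConfig(seed=11))   # 84 patients, 16 events
report = run_study(cohort)
cell = report["cox"]["bmd_qct"]["unadjusted"]
print(cell["hr_per_sd_decrease"], cell["ci95"])
print(report["roc"]["bmd_qct"]["auc"])
```

prints

```
2.262833029104152 [1.3044794086182714, 3.925254230749651]
0.7683823529411765
```

meaning: in this simulated cohort each one-standard-deviation reduction in
QCT BMD multiplies the incident-fracture hazard by ≈ 2.3 (CI excluding 1),
and baseline BMD separates future fracture patients from the rest with an
AUC of ≈ 0.77. The scripts in `examples/` walk through each capability
(calibration, drift QA, ROI measurement and classification, fracture
grading, the full study) and print annotated output.

A thin CLI mirrors the library:

```bash
oppqct simulate cohort --out cohort.csv --seed 11
oppqct analyze --cohort cohort.csv --out report.json --markdown report.md
```

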