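"""Quantify long-term scanner drift from a bimonthly phantom QA series.

Four years of simulated in-plane phantom measurements with a true drift of
-2.29 HU/year and 1% multiplicative noise are fitted per insert; the report
gives the drift slope, the per-insert CV of the standard error of the
estimate, and the RMS-averaged CV for the scanner.
"""

from collections import defaultdict

from oppqct import PhantomSimConfig, fit_drift, simulate_phantom_series, summarize_stability

cfg = PhantomSimConfig(drift_per_year=-2.29, noise_cv=1.0, duration_years=4.0, seed=42)
observations = simulate_phantom_series(cfg)

by_insert = defaultdict(list)
for obs in observations:
    by_insert[obs.insert_id].append(obs)

fits = [fit_drift(series) for series in by_insert.values()]
report = summarize_stability(fits)

for f in report.fits:
    print(
        f"insert {f.insert_id:>8}: drift {f.slope_per_year:+.2f} HU/year over "
        f"{f.observation_period:.2f} y, CV {f.cv:.2f}%"
    )
print(f"scanner headline drift: {report.headline_slope_per_year:+.2f} HU/year")
print(f"RMS-averaged CV:        {report.rms_cv:.2f}%")

# A drift of a few HU/year corresponds to only a few mg/cm^3 of BMD over the
# study horizon, small against the 40 mg/cm^3 gap between the diagnostic
# cutoffs; the RMS CV summarizes measurement stability across inserts.
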