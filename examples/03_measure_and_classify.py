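"""Measure trabecular BMD in a toy vertebral volume and classify the patient.

A synthetic vertebral body (cortical shell around a trabecular interior of
known density) is sampled with a circular midsagittal ROI; the mean HU is
converted to volumetric BMD and classified by the QCT cutoffs, alongside the
DXA classification of the same patient's reported T-score.
"""

from oppqct import (
    DxaSiteMeasurements,
    VolumeSimConfig,
    apply_calibration,
    classify_dxa,
    classify_qct,
    default_registry,
    measure_vertebra,
    reported_dxa_tscore,
    simulate_volume,
)

model = default_registry()["philips_ict_256"]
volume, truth = simulate_volume(
    VolumeSimConfig(trabecular_bmd=70.5, model=model, noise_sd=8.0, seed=7)
)

hu = measure_vertebra(volume, truth.spacing, truth.roi)
bmd = apply_calibration(hu, model)
print(f"ROI mean attenuation: {hu:.1f} HU")
print(f"volumetric BMD:       {bmd:.1f} mg/cm^3 (true {truth.true_bmd})")
print(f"QCT category:         {classify_qct(bmd).value}")

sites = DxaSiteMeasurements(
    tscores={
        "L1": -1.2,
        "L2": -1.7,
        "total_femur_left": -1.4,
        "total_femur_right": -0.9,
    },
    excluded=frozenset({"L3", "L4"}),  # degenerative change at L3/L4
)
t, basis = reported_dxa_tscore(sites)
print(f"reported DXA T-score: {t:.1f} ({basis.value})")
print(f"DXA category:         {classify_dxa(t).value}")

# The same patient can be osteoporotic by QCT (BMD < 80 mg/cm^3) yet only
# osteopenic by DXA: projectional DXA is inflated by degenerative change,
# which volumetric trabecular QCT bypasses.
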