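"""ROI sampling, vertebral aggregation, and diagnostic classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oppqct import (
    DiagnosticCategory,
    DxaSiteMeasurements,
    ExclusionReason,
    RoiSpec,
    TScoreBasis,
    VertebraMeasurement,
    VertebralLevel,
    aggregate_patient_hu,
    apply_calibration,
    classify_dxa,
    classify_qct,
    measure_vertebra,
    reported_dxa_tscore,
    simulate_volume,
    VolumeSimConfig,
)
from oppqct.errors import GeometryError, InputError, NotAssessableError


class TestMeasureVertebra:
    def test_uniform_volume_any_roi(self):
        vol = np.full((40, 40, 40), 100.0)
        for radius, stack in [(3.0, 5.0), (8.0, 15.0), (12.0, 30.0)]:
            roi = RoiSpec(center=(20, 20, 20), radius=radius, stack_thickness=stack)
            assert measure_vertebra(vol, (1, 1, 1), roi) == pytest.approx(100.0)

    def test_synthetic_two_compartment_geometry(self):
        """ROI strictly inside the trabecular compartment ignores the shell."""
        vol, truth = simulate_volume(
            VolumeSimConfig(trabecular_bmd=80.0, cortical_hu=400.0, noise_sd=0.0)
        )
        hu = measure_vertebra(vol, truth.spacing, truth.roi)
        assert hu == pytest.approx(truth.trabecular_hu, abs=1e-9)

    def test_noisy_mean_within_clt_bound(self):
        rng = np.random.default_rng(3)
        vol = 80.0 + rng.normal(0, 10.0, (40, 40, 40))
        roi = RoiSpec(center=(20, 20, 20), radius=10.0, stack_thickness=16.0)
        n_vox = int(
            (np.abs(np.arange(40) - 20) <= 8).sum()
            * (
                (np.arange(40)[:, None] - 20) ** 2 + (np.arange(40)[None, :] - 20) ** 2
                <= 100
            ).sum()
        )
        assert n_vox >= 500
        hu = measure_vertebra(vol, (1, 1, 1), roi)
        assert abs(hu - 80.0) < 3 * 10.0 / np.sqrt(n_vox)

    def test_roi_outside_bounds(self):
        vol = np.zeros((20, 20, 20))
        with pytest.raises(GeometryError):
            measure_vertebra(vol, (1, 1, 1), RoiSpec(center=(19, 10, 10), radius=3))
        with pytest.raises(GeometryError):
            measure_vertebra(vol, (1, 1, 1), RoiSpec(center=(10, 1, 10), radius=3))

    def test_anisotropic_spacing_uses_mm(self):
        vol = np.full((30, 30, 30), 55.0)
        vol[:, 20:, :] = 999.0  # 10 voxels = 5 mm away at 0.5 mm spacing
        roi = RoiSpec(center=(15, 10, 15), radius=4.0, stack_thickness=4.0)
        assert measure_vertebra(vol, (1.0, 0.5, 0.5), roi) == pytest.approx(55.0)


class TestAggregate:
    def test_mean_over_included(self):
        ms = [
            VertebraMeasurement(VertebralLevel.L1, 100.0),
            VertebraMeasurement(VertebralLevel.L2, 120.0),
            VertebraMeasurement(VertebralLevel.L3, 90.0, ExclusionReason.FRACTURE),
        ]
        assert aggregate_patient_hu(ms) == pytest.approx(110.0)

    def test_single_vertebra_identity(self):
        assert aggregate_patient_hu(
            [VertebraMeasurement(VertebralLevel.L4, 77.0)]
        ) == pytest.approx(77.0)

    def test_all_excluded_not_assessable(self):
        ms = [
            VertebraMeasurement(VertebralLevel.L1, 1.0, ExclusionReason.FRACTURE),
            VertebraMeasurement(VertebralLevel.L2, 2.0, ExclusionReason.DEGENERATION),
            VertebraMeasurement(VertebralLevel.L3, 3.0, ExclusionReason.HEMANGIOMA),
            VertebraMeasurement(VertebralLevel.L4, 4.0, ExclusionReason.FRACTURE),
        ]
        with pytest.raises(NotAssessableError):
            aggregate_patient_hu(ms)

    def test_aggregate_commutes_with_calibration(self, ict_model):
        """Averaging HU then converting equals converting then averaging."""
        hus = [88.0, 103.0, 131.5]
        bmd_first = apply_calibration(np.mean(hus), ict_model, "arterial")
        bmd_each = np.mean([apply_calibration(h, ict_model, "arterial") for h in hus])
        assert bmd_first == pytest.approx(bmd_each, abs=1e-10)


class TestClassification:
    @pytest.mark.parametrize(
        "bmd,expected",
        [
            (70.5, DiagnosticCategory.OSTEOPOROSIS),
            (79.999, DiagnosticCategory.OSTEOPOROSIS),
            (80.0, DiagnosticCategory.OSTEOPENIA),
            (120.0, DiagnosticCategory.OSTEOPENIA),
            (120.001, DiagnosticCategory.NORMAL),
            (150.0, DiagnosticCategory.NORMAL),
        ],
    )
    def test_qct_boundaries(self, bmd, expected):
        assert classify_qct(bmd) is expected

    @pytest.mark.parametrize(
        "t,expected",
        [
            (-2.5, DiagnosticCategory.OSTEOPOROSIS),
            (-2.499, DiagnosticCategory.OSTEOPENIA),
            (-1.7, DiagnosticCategory.OSTEOPENIA),
            (-1.0, DiagnosticCategory.OSTEOPENIA),
            (-0.999, DiagnosticCategory.NORMAL),
            (0.5, DiagnosticCategory.NORMAL),
        ],
    )
    def test_dxa_boundaries(self, t, expected):
        assert classify_dxa(t) is expected

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(x=st.floats(-500, 500, allow_nan=False))
    def test_partition_of_real_line(self, x):
        """Every finite value maps to exactly one category for each modality."""
        assert classify_qct(x) in DiagnosticCategory
        assert classify_dxa(x / 100) in DiagnosticCategory


class TestReportedTScore:
    def test_two_lumbar_sites_spine_and_hip(self):
        sites = DxaSiteMeasurements(
            tscores={
                "L1": -1.0,
                "L2": -2.0,
                "total_femur_left": -1.5,
                "total_femur_right": -0.8,
            },
            excluded=frozenset({"L3", "L4"}),
        )
        t, basis = reported_dxa_tscore(sites)
        assert t == -2.0 and basis is TScoreBasis.SPINE_AND_HIP

    def test_single_lumbar_falls_back_to_hip(self):
        sites = DxaSiteMeasurements(
            tscores={"L2": -3.0, "total_femur_left": -1.5, "total_femur_right": -0.8},
            excluded=frozenset({"L1", "L3", "L4"}),
        )
        t, basis = reported_dxa_tscore(sites)
        assert t == -1.5 and basis is TScoreBasis.HIP_ONLY

    def test_all_sites_equal(self):
        sites = DxaSiteMeasurements(
            tscores={s: -1.0 for s in ("L1", "L2", "L3", "L4", "total_femur_left", "total_femur_right")}
        )
        t, _ = reported_dxa_tscore(sites)
        assert t == -1.0

    def test_all_excluded(self):
        with pytest.raises(NotAssessableError):
            reported_dxa_tscore(DxaSiteMeasurements(tscores={}))

    def test_excluded_site_with_tscore_rejected(self):
        with pytest.raises(InputError):
            DxaSiteMeasurements(tscores={"L1": -1.0}, excluded=frozenset({"L1"}))
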