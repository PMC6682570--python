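"""Readers and writers for the package's tabular and volume formats.

All tables are plain CSV with the column layouts documented per function;
volumes are NIfTI (via nibabel) or in-memory arrays with voxel spacing.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationModel,
    PhantomMode,
    PhantomObservation,
    registry_from_json,
    registry_to_json,
)
from .densitometry import (
    DxaSiteMeasurements,
    ExclusionReason,
    VertebraMeasurement,
    VertebralLevel,
)
from .errors import InputError
from .fractures import VertebraFollowUp
from .risk import validate_cohort

__all__ = [
    "read_phantom_csv",
    "write_phantom_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_vertebra_csv",
    "read_dxa_csv",
    "read_followup_csv",
    "load_registry",
    "save_registry",
    "load_volume",
    "save_volume",
]

PHANTOM_COLUMNS = (
    "scanner_id",
    "date",
    "insert_id",
    "nominal_density_mg_cm3",
    "measured_hu",
    "mode",
)


def read_phantom_csv(path: str | Path) -> list[PhantomObservation]:
    """Phantom log CSV: scanner_id,date,insert_id,nominal_density_mg_cm3,measured_hu,mode."""
    df = pd.read_csv(path)
    missing = [c for c in PHANTOM_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"phantom CSV missing columns: {missing}")
    return [
        PhantomObservation(
            scanner_id=str(r.scanner_id),
            acquisition_date=_dt.date.fromisoformat(str(r.date)),
            insert_id=str(r.insert_id),
            nominal_density=float(r.nominal_density_mg_cm3),
            measured_hu=float(r.measured_hu),
            mode=PhantomMode(r.mode),
        )
        for r in df.itertuples()
    ]


def write_phantom_csv(observations: Iterable[PhantomObservation], path: str | Path) -> None:
    rows = [
        {
            "scanner_id": o.scanner_id,
            "date": o.acquisition_date.isoformat(),
            "insert_id": o.insert_id,
            "nominal_density_mg_cm3": o.nominal_density,
            "measured_hu": o.measured_hu,
            "mode": o.mode.value,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=list(PHANTOM_COLUMNS)).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Cohort CSV: patient_id,age,sex,bmd_qct,dxa_tscore,prev_genant,phase,time_days,event."""
    df = pd.read_csv(path)
    df["event"] = df["event"].astype(bool)
    return validate_cohort(df)


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, index=False)


def read_vertebra_csv(path: str | Path) -> dict[str, list[VertebraMeasurement]]:
    """Per-vertebra HU CSV: patient_id,level,mean_hu,excluded,exclusion_reason."""
    df = pd.read_csv(path)
    out: dict[str, list[VertebraMeasurement]] = {}
    for r in df.itertuples():
        reason = ExclusionReason(
            str(r.exclusion_reason) if bool(r.excluded) else "none"
        )
        out.setdefault(str(r.patient_id), []).append(
            VertebraMeasurement(
                level=VertebralLevel(str(r.level)),
                mean_hu=float(r.mean_hu),
                exclusion_reason=reason,
            )
        )
    return out


def read_dxa_csv(path: str | Path) -> dict[str, DxaSiteMeasurements]:
    """DXA site CSV: patient_id,site,tscore,excluded (excluded rows carry no tscore)."""
    df = pd.read_csv(path)
    out: dict[str, DxaSiteMeasurements] = {}
    for pid, grp in df.groupby("patient_id"):
        tscores = {
            str(r.site): float(r.tscore) for r in grp.itertuples() if not bool(r.excluded)
        }
        excluded = frozenset(str(r.site) for r in grp.itertuples() if bool(r.excluded))
        out[str(pid)] = DxaSiteMeasurements(tscores=tscores, excluded=excluded)
    return out


def read_followup_csv(path: str | Path) -> dict[str, list[VertebraFollowUp]]:
    """Follow-up CSV: patient_id,level,baseline_grade,followup_grade,consolidated,active_signs."""
    df = pd.read_csv(path)
    out: dict[str, list[VertebraFollowUp]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.patient_id), []).append(
            VertebraFollowUp(
                level=str(r.level),
                baseline_grade=int(r.baseline_grade),
                followup_grade=int(r.followup_grade),
                consolidated_at_baseline=bool(r.consolidated),
                active_signs=bool(r.active_signs),
            )
        )
    return out


def load_registry(path: str | Path) -> dict[str, CalibrationModel]:
    return registry_from_json(Path(path).read_text())


def save_registry(registry: Mapping[str, CalibrationModel], path: str | Path) -> None:
    Path(path).write_text(registry_to_json(registry))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume; returns (array, voxel spacing in mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), float), spacing


def save_volume(
    volume: np.ndarray, spacing: Sequence[float], path: str | Path
) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, np.float32), affine), str(path))
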