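"""Trabecular densitometry and diagnostic classification.

Sampling: a circular region of interest is placed in the trabecular
compartment of each assessable lumbar vertebra (L1-L4) on a midsagittal stack
of configurable thickness (default 15 mm); its mean attenuation is averaged
over included vertebrae.  Vertebrae with fracture, degeneration, or
hemangioma are excluded by flag (the radiologist's call — not detected here).

Classification follows the standard QCT cutoffs (osteoporosis BMD < 80
mg/cm^3, osteopenia 80-120 inclusive) and the WHO DXA T-score cutoffs
(osteoporosis T <= -2.5, osteopenia -2.5 < T <= -1).  The reported DXA
T-score is the lowest over remaining lumbar and total-femur sites; if at most
one lumbar vertebra remains after exclusions the diagnosis is based on the
hips alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import GeometryError, InputError, NotAssessableError

__all__ = [
    "VertebralLevel",
    "ExclusionReason",
    "DiagnosticCategory",
    "TScoreBasis",
    "VertebraMeasurement",
    "RoiSpec",
    "DxaSiteMeasurements",
    "LUMBAR_SITES",
    "FEMUR_SITES",
    "measure_vertebra",
    "aggregate_patient_hu",
    "classify_qct",
    "classify_dxa",
    "reported_dxa_tscore",
    "QCT_OSTEOPOROSIS_CUTOFF",
    "QCT_OSTEOPENIA_CUTOFF",
    "DXA_OSTEOPOROSIS_CUTOFF",
    "DXA_OSTEOPENIA_CUTOFF",
]

QCT_OSTEOPOROSIS_CUTOFF = 80.0  # mg/cm^3, exclusive
QCT_OSTEOPENIA_CUTOFF = 120.0  # mg/cm^3, inclusive
DXA_OSTEOPOROSIS_CUTOFF = -2.5  # T-score, inclusive
DXA_OSTEOPENIA_CUTOFF = -1.0  # T-score, inclusive


class VertebralLevel(str, Enum):
    L1 = "L1"
    L2 = "L2"
    L3 = "L3"
    L4 = "L4"


class ExclusionReason(str, Enum):
    NONE = "none"
    FRACTURE = "fracture"
    DEGENERATION = "degeneration"
    HEMANGIOMA = "hemangioma"


class DiagnosticCategory(str, Enum):
    NORMAL = "normal"
    OSTEOPENIA = "osteopenia"
    OSTEOPOROSIS = "osteoporosis"


class TScoreBasis(str, Enum):
    SPINE_AND_HIP = "spine_and_hip"
    HIP_ONLY = "hip_only"


@dataclass(frozen=True)
class VertebraMeasurement:
    """Mean trabecular HU of one vertebra with its inclusion flag."""

    level: VertebralLevel
    mean_hu: float
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def included(self) -> bool:
        return self.exclusion_reason is ExclusionReason.NONE


@dataclass(frozen=True)
class RoiSpec:
    """Circular trabecular ROI on a midsagittal stack.

    ``center`` is a 0-based voxel index triple (sagittal, ap, axial); the
    sagittal axis is the first array axis by convention.  ``radius`` and
    ``stack_thickness`` are in mm; the stack extends symmetrically in the
    sagittal direction around the center.
    """

    center: tuple[int, int, int]
    radius: float
    stack_thickness: float = 15.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InputError("ROI radius must be positive")
        if self.stack_thickness <= 0:
            raise InputError("stack thickness must be positive")


LUMBAR_SITES = ("L1", "L2", "L3", "L4")
FEMUR_SITES = ("total_femur_left", "total_femur_right")


@dataclass(frozen=True)
class DxaSiteMeasurements:
    """Per-site DXA T-scores with site exclusions.

    ``tscores`` maps site name (L1..L4, total_femur_left/right) to T-score in
    SD units; sites in ``excluded`` carry no T-score.
    """

    tscores: Mapping[str, float]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        known = set(LUMBAR_SITES) | set(FEMUR_SITES)
        unknown = set(self.tscores) - known
        if unknown:
            raise InputError(f"unknown DXA sites: {sorted(unknown)}")
        overlap = set(self.tscores) & set(self.excluded)
        if overlap:
            raise InputError(f"excluded sites must carry no T-score: {sorted(overlap)}")


def measure_vertebra(
    volume: np.ndarray,
    spacing: Sequence[float],
    roi: RoiSpec,
) -> float:
    """Mean attenuation inside a circular ROI on a midsagittal stack.

    A voxel belongs to the ROI when its center lies within ``radius`` mm of
    the ROI center in the in-plane (2nd/3rd axis) directions and within
    ``stack_thickness / 2`` mm of it along the sagittal (1st) axis.

    Raises
    ------
    GeometryError
        If the ROI's bounding box extends outside the volume.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise InputError("volume must be a 3-D array")
    sp = np.asarray(spacing, dtype=float)
    if sp.shape != (3,) or np.any(sp <= 0):
        raise InputError("spacing must be three positive voxel sizes in mm")

    cx, cy, cz = roi.center
    half = roi.stack_thickness / 2.0
    lo = (cx - half / sp[0], cy - roi.radius / sp[1], cz - roi.radius / sp[2])
    hi = (cx + half / sp[0], cy + roi.radius / sp[1], cz + roi.radius / sp[2])
    if any(l < -0.5 for l in lo) or any(
        h > n - 0.5 for h, n in zip(hi, volume.shape)
    ):
        raise GeometryError("ROI exceeds volume bounds")

    idx = [np.arange(n, dtype=float) for n in volume.shape]
    sag = np.abs(idx[0] - cx) * sp[0] <= half
    dy = (idx[1] - cy) * sp[1]
    dz = (idx[2] - cz) * sp[2]
    inplane = dy[:, None] ** 2 + dz[None, :] ** 2 <= roi.radius**2
    mask = sag[:, None, None] & inplane[None, :, :]
    if not mask.any():
        raise GeometryError("ROI contains no voxel centers")
    return float(volume[mask].mean())


def aggregate_patient_hu(measurements: Iterable[VertebraMeasurement]) -> float:
    """Average mean HU over included vertebrae (unweighted).

    Raises ``NotAssessableError`` when every vertebra is excluded, mirroring
    the inclusion requirement of at least one assessable lumbar vertebra.
    """
    included = [m.mean_hu for m in measurements if m.included]
    if not included:
        raise NotAssessableError("no assessable lumbar vertebra")
    return float(np.mean(included))


def classify_qct(bmd: float) -> DiagnosticCategory:
    """Classify volumetric BMD (mg/cm^3) by the standard QCT cutoffs."""
    if not np.isfinite(bmd):
        raise InputError("BMD must be finite")
    if bmd < QCT_OSTEOPOROSIS_CUTOFF:
        return DiagnosticCategory.OSTEOPOROSIS
    if bmd <= QCT_OSTEOPENIA_CUTOFF:
        return DiagnosticCategory.OSTEOPENIA
    return DiagnosticCategory.NORMAL


def classify_dxa(t: float) -> DiagnosticCategory:
    """Classify a DXA T-score (SD units) by the WHO cutoffs."""
    if not np.isfinite(t):
        raise InputError("T-score must be finite")
    if t <= DXA_OSTEOPOROSIS_CUTOFF:
        return DiagnosticCategory.OSTEOPOROSIS
    if t <= DXA_OSTEOPENIA_CUTOFF:
        return DiagnosticCategory.OSTEOPENIA
    return DiagnosticCategory.NORMAL


def reported_dxa_tscore(sites: DxaSiteMeasurements) -> tuple[float, TScoreBasis]:
    """Overall lowest T-score with the site basis used.

    With two or more lumbar sites remaining, the minimum is taken over the
    remaining lumbar and femur T-scores.  With at most one lumbar site left
    after exclusions, the diagnosis rests on the hips alone.
    """
    lumbar = {s: t for s, t in sites.tscores.items() if s in LUMBAR_SITES}
    femur = {s: t for s, t in sites.tscores.items() if s in FEMUR_SITES}
    if not lumbar and not femur:
        raise NotAssessableError("all DXA sites excluded")

    if len(lumbar) >= 2:
        pool = {**lumbar, **femur}
        return float(min(pool.values())), TScoreBasis.SPINE_AND_HIP
    if not femur:
        raise NotAssessableError(
            "fewer than two lumbar sites and no femur site assessable"
        )
    return float(min(femur.values())), TScoreBasis.HIP_ONLY
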