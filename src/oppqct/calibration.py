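"""Asynchronous HU-to-BMD calibration of CT scanners.

Opportunistic QCT converts trabecular attenuation (Hounsfield units) into
volumetric bone mineral density (mg/cm^3 hydroxyapatite equivalent) using a
per-scanner affine conversion, ``BMD = slope * HU + intercept``, fitted by
ordinary least squares on measurements of a density-reference phantom whose
inserts have known hydroxyapatite concentrations.  The phantom is scanned
separately from the patient ("asynchronous" calibration), either in dedicated
calibration scans or retrospectively from an in-plane phantom that lay in the
scanner couch during routine scans.

Contrast-enhanced scans are corrected by an additive BMD offset per contrast
phase, applied after conversion.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

from .errors import DegenerateDesignError, InputError

__all__ = [
    "PhantomMode",
    "ContrastPhase",
    "PhantomObservation",
    "CalibrationModel",
    "ContrastOffsetTable",
    "DEFAULT_CONTRAST_OFFSETS",
    "fit_calibration",
    "apply_calibration",
    "default_registry",
    "registry_to_json",
    "registry_from_json",
]


class PhantomMode(str, Enum):
    """How the phantom was scanned."""

    DEDICATED_SCAN = "dedicated_scan"
    INPLANE_ROUTINE = "inplane_routine"


class ContrastPhase(str, Enum):
    NON_ENHANCED = "non_enhanced"
    ARTERIAL = "arterial"
    PORTAL_VENOUS = "portal_venous"


@dataclass(frozen=True)
class PhantomObservation:
    """One dated HU measurement of a phantom insert of known density.

    Parameters
    ----------
    scanner_id : str
        Scanner the measurement was made on.
    acquisition_date : datetime.date
        Date of the scan.
    insert_id : str
        Identifier of the phantom insert (rod).
    nominal_density : float
        Known hydroxyapatite concentration of the insert, mg/cm^3 (>= 0).
    measured_hu : float
        Mean attenuation measured in the insert, HU.
    mode : PhantomMode
        Dedicated calibration scan or retrospective in-plane measurement.
    """

    scanner_id: str
    acquisition_date: _dt.date
    insert_id: str
    nominal_density: float
    measured_hu: float
    mode: PhantomMode = PhantomMode.DEDICATED_SCAN

    def __post_init__(self) -> None:
        if self.nominal_density < 0:
            raise InputError("nominal_density must be >= 0 mg/cm^3")
        if not np.isfinite(self.measured_hu):
            raise InputError("measured_hu must be finite")


@dataclass(frozen=True)
class CalibrationModel:
    """Affine HU -> BMD conversion for one scanner, with fit diagnostics.

    ``bmd = slope * hu + intercept`` with slope in mg/cm^3 per HU and
    intercept in mg/cm^3.  ``see`` is the standard error of the estimate of
    the calibration regression, sqrt(RSS / (n - 2)), in mg/cm^3.
    """

    scanner_id: str
    slope: float
    intercept: float
    tube_voltage: float = 120.0
    phantom_id: str = ""
    r_squared: float = 1.0
    see: float = 0.0
    n_points: int = 2

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InputError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InputError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise InputError("a calibration needs at least 2 points")

    def convert(self, hu: float) -> float:
        """Convert attenuation (HU) to BMD (mg/cm^3), without contrast offset."""
        return self.slope * hu + self.intercept

    def invert(self, bmd: float) -> float:
        """Attenuation that maps to ``bmd`` — used to synthesize phantom data."""
        return (bmd - self.intercept) / self.slope


class ContrastOffsetTable(Mapping[ContrastPhase, float]):
    """Additive BMD offsets (mg/cm^3) per contrast phase.

    The non-enhanced offset is pinned at zero; enhanced phases carry negative
    offsets because intravenous contrast inflates trabecular attenuation.
    """

    def __init__(self, offsets: Mapping[ContrastPhase | str, float]):
        self._offsets = {ContrastPhase(k): float(v) for k, v in offsets.items()}
        if self._offsets.get(ContrastPhase.NON_ENHANCED, 0.0) != 0.0:
            raise InputError("non-enhanced offset must be exactly 0")
        self._offsets.setdefault(ContrastPhase.NON_ENHANCED, 0.0)

    def __getitem__(self, phase: ContrastPhase | str) -> float:
        try:
            return self._offsets[ContrastPhase(phase)]
        except (KeyError, ValueError):
            raise InputError(f"unknown contrast phase: {phase!r}") from None

    def __iter__(self):
        return iter(self._offsets)

    def __len__(self) -> int:
        return len(self._offsets)


#: Offsets adopted from a dedicated contrast-phase calibration study; editable.
DEFAULT_CONTRAST_OFFSETS = ContrastOffsetTable(
    {
        ContrastPhase.NON_ENHANCED: 0.0,
        ContrastPhase.ARTERIAL: -8.6,
        ContrastPhase.PORTAL_VENOUS: -15.8,
    }
)


def fit_calibration(
    observations: Iterable[PhantomObservation],
    *,
    tube_voltage: float = 120.0,
) -> CalibrationModel:
    """Fit the HU -> BMD conversion for one scanner by least squares.

    Nominal density (response) is regressed on measured HU (predictor), so the
    fitted line maps attenuation directly to density.  In-plane retrospective
    observations spanning the phantom-present period are pooled into a single
    fit; no per-date averaging is performed.

    Raises
    ------
    InputError
        If observations mix scanners or the collection is empty.
    DegenerateDesignError
        If fewer than two distinct nominal densities (or HU values) remain.
    """
    obs = list(observations)
    if not obs:
        raise InputError("no phantom observations supplied")
    scanners = {o.scanner_id for o in obs}
    if len(scanners) != 1:
        raise InputError(f"observations mix scanners: {sorted(scanners)}")
    (scanner_id,) = scanners

    hu = np.array([o.measured_hu for o in obs], dtype=float)
    dens = np.array([o.nominal_density for o in obs], dtype=float)
    if len(np.unique(dens)) < 2:
        raise DegenerateDesignError("need >= 2 distinct nominal densities")
    if len(np.unique(hu)) < 2:
        raise DegenerateDesignError("all HU values identical; slope undefined")

    # Normal equations for simple OLS; kept explicit because the fitted pair
    # is the scanner's conversion equation and must be exactly reproducible.
    n = len(obs)
    hu_c = hu - hu.mean()
    slope = float(hu_c @ (dens - dens.mean()) / (hu_c @ hu_c))
    intercept = float(dens.mean() - slope * hu.mean())
    resid = dens - (slope * hu + intercept)
    rss = float(resid @ resid)
    tss = float(((dens - dens.mean()) ** 2).sum())
    r_squared = 1.0 if tss == 0 else max(0.0, min(1.0, 1.0 - rss / tss))
    see = 0.0 if n <= 2 else float(np.sqrt(rss / (n - 2)))

    phantoms = {o.insert_id.split(":")[0] for o in obs}
    return CalibrationModel(
        scanner_id=scanner_id,
        slope=slope,
        intercept=intercept,
        tube_voltage=tube_voltage,
        phantom_id=phantoms.pop() if len(phantoms) == 1 else "",
        r_squared=r_squared,
        see=see,
        n_points=n,
    )


def apply_calibration(
    hu: float,
    model: CalibrationModel,
    phase: ContrastPhase | str = ContrastPhase.NON_ENHANCED,
    offsets: ContrastOffsetTable = DEFAULT_CONTRAST_OFFSETS,
) -> float:
    """Convert attenuation to volumetric BMD with contrast-phase correction.

    Returns ``slope * hu + intercept + offset(phase)`` in mg/cm^3.  Negative
    BMD is representable (no clamping) and is flagged downstream.
    """
    return model.convert(hu) + offsets[phase]


# Published conversion equations for the five scanners of the source clinic,
# fitted from QRM phantoms (dedicated scans) or the in-plane Siemens Osteo
# phantom (decommissioned scanners).  All at 120 kVp.
_DEFAULT_MODELS = [
    ("philips_brilliance_64", 0.778, -4.693, "QRM-BDC/3"),
    ("philips_ict_256", 0.855, 1.172, "QRM-Abdomen-Phantom"),
    ("siemens_somatom_definition_as_plus", 1.011, -3.385, "QRM-Abdomen-Phantom"),
    ("siemens_somatom_definition_as", 0.985, 15.516, "Siemens Osteo"),
    ("siemens_somatom_sensation_cardiac_64", 0.971, 13.249, "Siemens Osteo"),
]


def default_registry() -> dict[str, CalibrationModel]:
    """Calibration registry pre-populated with the shipped scanner equations."""
    return {
        sid: CalibrationModel(
            scanner_id=sid, slope=a, intercept=b, tube_voltage=120.0, phantom_id=ph
        )
        for sid, a, b, ph in _DEFAULT_MODELS
    }


def registry_to_json(registry: Mapping[str, CalibrationModel]) -> str:
    """Serialize a calibration registry to a JSON document keyed by scanner."""
    doc = {
        sid: {
            "slope": m.slope,
            "intercept": m.intercept,
            "tube_voltage": m.tube_voltage,
            "phantom_id": m.phantom_id,
            "r_squared": m.r_squared,
            "see": m.see,
            "n_points": m.n_points,
        }
        for sid, m in sorted(registry.items())
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def registry_from_json(text: str) -> dict[str, CalibrationModel]:
    doc = json.loads(text)
    return {
        sid: CalibrationModel(scanner_id=sid, **fields) for sid, fields in doc.items()
    }
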