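"""Long-term scanner stability from dated phantom measurements.

A scanner whose calibration is asynchronous must hold its attenuation scale
over years.  Stability is quantified per phantom insert by the slope of a
linear regression of measured HU on elapsed time (drift, HU/year) and by the
coefficient of variation of the regression's standard error of the estimate,
CV = 100 * SEE / |mean HU|.  Per-scanner CVs are averaged across inserts by
the root-mean-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .calibration import PhantomObservation
from .errors import DegenerateDesignError, InputError

__all__ = ["DriftFit", "StabilityReport", "fit_drift", "summarize_stability"]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class DriftFit:
    """Linear drift of one phantom insert on one scanner.

    ``slope_per_year`` is in HU/year; ``see`` the standard error of the
    estimate in HU; ``cv`` the coefficient of variation in percent,
    100 * see / |mean_hu|.  ``insert_density`` (mg/cm^3) is carried so a
    report can single out the bone-equivalent insert.
    """

    scanner_id: str
    insert_id: str
    slope_per_year: float
    observation_period: float
    see: float
    mean_hu: float
    cv: float
    insert_density: float | None = None

    def __post_init__(self) -> None:
        if self.observation_period <= 0:
            raise InputError("observation_period must be positive")
        if self.cv < 0:
            raise InputError("cv cannot be negative")


@dataclass(frozen=True)
class StabilityReport:
    """Per-scanner stability: per-insert drift fits plus RMS-averaged CV."""

    scanner_id: str
    fits: tuple[DriftFit, ...]
    rms_cv: float
    headline_slope_per_year: float


def fit_drift(series: Iterable[PhantomObservation]) -> DriftFit:
    """Fit HU drift over time for one scanner/insert series.

    Elapsed time is measured in fractional years of 365.25 days from the first
    observation.  Requires at least 3 observations spanning more than one day.
    """
    obs = sorted(series, key=lambda o: o.acquisition_date)
    if len(obs) < 3:
        raise InputError("need >= 3 observations to fit drift")
    scanners = {o.scanner_id for o in obs}
    inserts = {o.insert_id for o in obs}
    if len(scanners) != 1 or len(inserts) != 1:
        raise InputError("drift series must cover one scanner and one insert")

    t0 = obs[0].acquisition_date
    t = np.array([(o.acquisition_date - t0).days for o in obs], float) / DAYS_PER_YEAR
    hu = np.array([o.measured_hu for o in obs], float)
    if np.ptp(t) == 0:
        raise DegenerateDesignError("all observations at a single time point")

    tc = t - t.mean()
    slope = float(tc @ (hu - hu.mean()) / (tc @ tc))
    intercept = float(hu.mean() - slope * t.mean())
    resid = hu - (slope * t + intercept)
    see = float(np.sqrt(resid @ resid / (len(obs) - 2)))
    mean_hu = float(hu.mean())
    cv = 100.0 * see / abs(mean_hu) if mean_hu != 0 else float("inf")

    densities = {o.nominal_density for o in obs}
    return DriftFit(
        scanner_id=scanners.pop(),
        insert_id=inserts.pop(),
        slope_per_year=slope,
        observation_period=float(np.ptp(t)),
        see=see,
        mean_hu=mean_hu,
        cv=cv,
        insert_density=densities.pop() if len(densities) == 1 else None,
    )


def summarize_stability(fits: Sequence[DriftFit]) -> StabilityReport:
    """Combine per-insert drift fits into a per-scanner report.

    The CV is averaged over inserts by root-mean-square.  The headline drift
    slope is taken from the densest (bone-equivalent) insert; with no density
    information it falls back to the first insert.  Per-insert slopes remain
    available on the report.
    """
    fits = list(fits)
    if not fits:
        raise InputError("no drift fits supplied")
    scanners = {f.scanner_id for f in fits}
    if len(scanners) != 1:
        raise InputError("stability report covers a single scanner")

    rms_cv = float(np.sqrt(np.mean([f.cv**2 for f in fits])))
    with_density = [f for f in fits if f.insert_density is not None]
    headline = (
        max(with_density, key=lambda f: f.insert_density) if with_density else fits[0]
    )
    return StabilityReport(
        scanner_id=scanners.pop(),
        fits=tuple(fits),
        rms_cv=rms_cv,
        headline_slope_per_year=headline.slope_per_year,
    )
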