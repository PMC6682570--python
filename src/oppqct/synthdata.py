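"""Synthetic inputs for every pipeline stage.

Three generators stand in for data that cannot be shipped: a clinical cohort
with the published group-conditional BMD/T-score structure (or an explicit
proportional-hazards event process), dated phantom QA series with linear
drift and multiplicative noise, and toy vertebral volumes with a cortical
shell, a trabecular compartment of known density, and optional
height-reduction deformities.

Defaults reproduce the source study's conditions: 16 fracture / 68
non-fracture patients, fracture-group BMD 56.7 (31.6) vs 93.3 (41.7) mg/cm^3,
T-scores -2.2 (1.8) vs -1.6 (1.7), 80% women, bimonthly phantom sampling over
four years.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .calibration import CalibrationModel, PhantomMode, PhantomObservation, default_registry
from .densitometry import RoiSpec
from .errors import ConfigError
from .fractures import VertebralHeights

__all__ = [
    "CohortSimConfig",
    "PhantomSimConfig",
    "VolumeSimConfig",
    "VolumeGroundTruth",
    "simulate_cohort",
    "simulate_phantom_series",
    "simulate_volume",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort generator settings.

    ``group_conditional`` mode draws (BMD, T-score) per outcome group from a
    bivariate normal (BMD truncated at 0 by resampling) and assigns follow-up
    times from the observed follow-up ranges.  ``hazard_driven`` mode draws a
    standard-normal per-SD-decrease BMD score z, assigns exponential event
    times with hazard h0 * hr_per_sd**z, and censors uniformly inside the
    censor window; BMD is the affine image of z under the pooled marginal and
    is not truncated, so that z stays exactly standard normal.
    """

    n_fracture: int = 16
    n_nonfracture: int = 68
    bmd_mean_fracture: float = 56.7
    bmd_sd_fracture: float = 31.6
    bmd_mean_nonfracture: float = 93.3
    bmd_sd_nonfracture: float = 41.7
    tscore_mean_fracture: float = -2.2
    tscore_sd_fracture: float = 1.8
    tscore_mean_nonfracture: float = -1.6
    tscore_sd_nonfracture: float = 1.7
    bmd_tscore_correlation: float = 0.6
    mode: str = "group_conditional"  # or "hazard_driven"
    hr_per_sd: float = 4.07
    baseline_hazard: float | None = None  # events/year; None -> calibrated
    target_event_rate: float = 0.19
    censor_window_days: float = 2425.0
    bmd_mean_pooled: float = 86.3
    bmd_sd_pooled: float = 42.4
    tscore_mean_pooled: float = -1.7
    tscore_sd_pooled: float = 1.7
    age_mean_fracture: float = 73.9
    age_sd_fracture: float = 7.4
    age_mean_nonfracture: float = 67.7
    age_sd_nonfracture: float = 8.6
    female_fraction: float = 0.80
    prevalent_grade_probs: tuple[float, float, float, float] = (
        39 / 84,
        11 / 84,
        16 / 84,
        18 / 84,
    )
    phase_probs: tuple[float, float, float] = (0.48, 0.26, 0.26)
    truncate_at_zero: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.bmd_tscore_correlation <= 1.0:
            raise ConfigError("correlation must lie in [-1, 1]")
        for name in (
            "bmd_sd_fracture",
            "bmd_sd_nonfracture",
            "tscore_sd_fracture",
            "tscore_sd_nonfracture",
            "bmd_sd_pooled",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.mode not in ("group_conditional", "hazard_driven"):
            raise ConfigError(f"unknown mode: {self.mode!r}")
        if self.mode == "group_conditional":
            if self.n_fracture < 1 or self.n_nonfracture < 1:
                raise ConfigError("group sizes must be >= 1")
        elif self.n_fracture + self.n_nonfracture < 1:
            raise ConfigError("total cohort size must be >= 1")


@dataclass(frozen=True)
class PhantomSimConfig:
    """Phantom QA series settings: a scanner's true conversion line, a linear
    HU drift, and multiplicative measurement noise of given CV (percent)."""

    true_slope: float = 0.985
    true_intercept: float = 15.516
    drift_per_year: float = -2.29
    noise_cv: float = 1.0
    cadence_days: float = 61.0  # bimonthly
    duration_years: float = 4.0
    insert_densities: tuple[float, ...] = (100.0, 200.0)
    scanner_id: str = "siemens_somatom_definition_as"
    start_date: _dt.date = _dt.date(2010, 1, 6)
    mode: PhantomMode = PhantomMode.INPLANE_ROUTINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_years <= 0:
            raise ConfigError("duration must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise CV cannot be negative")


@dataclass(frozen=True)
class VolumeSimConfig:
    """Toy vertebral volume: elliptic-cylinder body with a 2-voxel cortical
    shell, trabecular interior of known density, optional axial compression."""

    shape: tuple[int, int, int] = (60, 80, 70)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    trabecular_bmd: float = 100.0
    cortical_hu: float = 400.0
    background_hu: float = -50.0
    model: CalibrationModel | None = None  # None -> Philips iCT 256 equation
    noise_sd: float = 0.0
    fracture_fraction: float = 0.0
    body_semiaxes_mm: tuple[float, float] = (18.0, 14.0)
    body_height_mm: float = 30.0
    shell_voxels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in self.spacing):
            raise ConfigError("shape and spacing must be positive")
        if not 0.0 <= self.fracture_fraction < 1.0:
            raise ConfigError("fracture fraction must lie in [0, 1)")


@dataclass(frozen=True)
class VolumeGroundTruth:
    """What the volume generator actually put into the array."""

    true_bmd: float
    trabecular_hu: float
    roi: RoiSpec
    heights: VertebralHeights
    spacing: tuple[float, float, float]


# ---------------------------------------------------------------------------


def _bivariate(rng, n, mean_a, sd_a, mean_b, sd_b, rho, truncate_a_at_zero):
    """Correlated normal pair, optionally resampling until a >= 0."""
    out_a = np.empty(n)
    out_b = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        z1 = rng.standard_normal(m)
        z2 = rng.standard_normal(m)
        a = mean_a + sd_a * z1
        b = mean_b + sd_b * (rho * z1 + np.sqrt(1 - rho**2) * z2)
        if truncate_a_at_zero:
            keep = a >= 0
            a, b = a[keep], b[keep]
        out_a[filled : filled + len(a)] = a
        out_b[filled : filled + len(a)] = b
        filled += len(a)
    return out_a, out_b


def _expected_event_rate(h0_per_year: float, hr: float, window_days: float) -> float:
    """Marginal event probability under z ~ N(0,1) and uniform censoring.

    P(event | z) = 1 - (1 - exp(-lam W)) / (lam W) with lam = h0 * hr**z,
    integrated over z by Gauss-Hermite quadrature.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    lam = h0_per_year * hr**nodes / DAYS_PER_YEAR
    lw = lam * window_days
    p = 1.0 - (1.0 - np.exp(-lw)) / lw
    return float((weights / np.sqrt(2 * np.pi)) @ p)


def _calibrated_baseline_hazard(cfg: CohortSimConfig) -> float:
    f = lambda h: _expected_event_rate(h, cfg.hr_per_sd, cfg.censor_window_days) - (
        cfg.target_event_rate
    )
    return float(optimize.brentq(f, 1e-6, 50.0))


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Generate a cohort table consumable by the risk module."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    phases = np.array(["non_enhanced", "arterial", "portal_venous"])

    if cfg.mode == "group_conditional":
        bmd_f, ts_f = _bivariate(
            rng,
            cfg.n_fracture,
            cfg.bmd_mean_fracture,
            cfg.bmd_sd_fracture,
            cfg.tscore_mean_fracture,
            cfg.tscore_sd_fracture,
            cfg.bmd_tscore_correlation,
            cfg.truncate_at_zero,
        )
        bmd_n, ts_n = _bivariate(
            rng,
            cfg.n_nonfracture,
            cfg.bmd_mean_nonfracture,
            cfg.bmd_sd_nonfracture,
            cfg.tscore_mean_nonfracture,
            cfg.tscore_sd_nonfracture,
            cfg.bmd_tscore_correlation,
            cfg.truncate_at_zero,
        )
        bmd = np.concatenate([bmd_f, bmd_n])
        tscore = np.concatenate([ts_f, ts_n])
        event = np.concatenate(
            [np.ones(cfg.n_fracture, bool), np.zeros(cfg.n_nonfracture, bool)]
        )
        age = np.concatenate(
            [
                rng.normal(cfg.age_mean_fracture, cfg.age_sd_fracture, cfg.n_fracture),
                rng.normal(
                    cfg.age_mean_nonfracture, cfg.age_sd_nonfracture, cfg.n_nonfracture
                ),
            ]
        )
        # follow-up ranges of the emulated cohort: events 19-1891 d, censor 373-2425 d
        time = np.where(
            event,
            rng.uniform(19.0, 1891.0, len(event)),
            rng.uniform(373.0, cfg.censor_window_days, len(event)),
        )
    else:  # hazard_driven
        n = cfg.n_fracture + cfg.n_nonfracture
        z = rng.standard_normal(n)  # per-SD-decrease standardized BMD
        bmd = cfg.bmd_mean_pooled - cfg.bmd_sd_pooled * z
        z2 = rng.standard_normal(n)
        rho = cfg.bmd_tscore_correlation
        tscore = cfg.tscore_mean_pooled - cfg.tscore_sd_pooled * (
            rho * z + np.sqrt(1 - rho**2) * z2
        )
        h0 = (
            cfg.baseline_hazard
            if cfg.baseline_hazard is not None
            else _calibrated_baseline_hazard(cfg)
        )
        lam = h0 * cfg.hr_per_sd**z / DAYS_PER_YEAR  # events/day
        t_event = rng.exponential(1.0 / lam)
        censor = rng.uniform(1.0, cfg.censor_window_days, n)
        event = t_event <= censor
        time = np.minimum(t_event, censor)
        age = rng.normal(68.9, 8.7, n)

    n = len(bmd)
    sex = np.where(rng.random(n) < cfg.female_fraction, "F", "M")
    prev = rng.choice(4, size=n, p=np.asarray(cfg.prevalent_grade_probs))
    phase = rng.choice(phases, size=n, p=np.asarray(cfg.phase_probs))

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmd_qct": bmd,
            "dxa_tscore": tscore,
            "prev_genant": prev,
            "phase": phase,
            "time_days": time,
            "event": event,
        }
    )


def simulate_phantom_series(config: PhantomSimConfig) -> list[PhantomObservation]:
    """Dated phantom insert measurements with linear drift and noise.

    For insert density d at elapsed time t (years):
    HU = ((d - intercept) / slope + drift * t) * (1 + eps),
    eps ~ Normal(0, (CV/100)^2).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_times = int(np.floor(cfg.duration_years * DAYS_PER_YEAR / cfg.cadence_days)) + 1
    out: list[PhantomObservation] = []
    for k in range(n_times):
        days = k * cfg.cadence_days
        date = cfg.start_date + _dt.timedelta(days=round(days))
        t_years = days / DAYS_PER_YEAR
        for d in cfg.insert_densities:
            clean = (d - cfg.true_intercept) / cfg.true_slope + cfg.drift_per_year * t_years
            eps = rng.normal(0.0, cfg.noise_cv / 100.0)
            out.append(
                PhantomObservation(
                    scanner_id=cfg.scanner_id,
                    acquisition_date=date,
                    insert_id=f"rod_{d:g}",
                    nominal_density=d,
                    measured_hu=clean * (1.0 + eps),
                    mode=cfg.mode,
                )
            )
    return out


def simulate_volume(config: VolumeSimConfig) -> tuple[np.ndarray, VolumeGroundTruth]:
    """Build a toy vertebral volume and its ground truth.

    The vertebral body is an elliptic cylinder along the cranio-caudal (3rd)
    axis: a cortical shell of ``shell_voxels`` thickness at ``cortical_hu``
    around a trabecular interior whose HU is the inverse calibration of
    ``trabecular_bmd``.  A fracture uniformly compresses the body height by
    ``fracture_fraction``.  The returned ground truth carries the true BMD,
    an ROI guaranteed to lie inside the trabecular compartment, and the
    resulting vertebral heights against the uncompressed reference.
    """
    cfg = config
    model = cfg.model if cfg.model is not None else default_registry()["philips_ict_256"]
    rng = np.random.default_rng(cfg.seed)
    sp = np.asarray(cfg.spacing, float)
    shape = cfg.shape
    a_mm, b_mm = cfg.body_semiaxes_mm
    height_mm = cfg.body_height_mm * (1.0 - cfg.fracture_fraction)

    extent = np.array(shape) * sp
    if 2 * a_mm >= extent[0] or 2 * b_mm >= extent[1] or height_mm >= extent[2]:
        raise ConfigError("vertebral body does not fit inside the grid")

    center = (np.array(shape) - 1) / 2.0
    xi = (np.arange(shape[0]) - center[0]) * sp[0]
    yi = (np.arange(shape[1]) - center[1]) * sp[1]
    zi = (np.arange(shape[2]) - center[2]) * sp[2]
    x, y, z = np.meshgrid(xi, yi, zi, indexing="ij")

    shell = cfg.shell_voxels * sp.min()
    in_body = ((x / a_mm) ** 2 + (y / b_mm) ** 2 <= 1.0) & (
        np.abs(z) <= height_mm / 2.0
    )
    a_in, b_in = a_mm - shell, b_mm - shell
    if a_in <= 0 or b_in <= 0 or height_mm / 2.0 - shell <= 0:
        raise ConfigError("cortical shell leaves no trabecular compartment")
    in_trab = ((x / a_in) ** 2 + (y / b_in) ** 2 <= 1.0) & (
        np.abs(z) <= height_mm / 2.0 - shell
    )

    trab_hu = model.invert(cfg.trabecular_bmd)
    vol = np.full(shape, cfg.background_hu, float)
    vol[in_body] = cfg.cortical_hu
    vol[in_trab] = trab_hu
    if cfg.noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.noise_sd, shape)

    # ROI: 40% of the trabecular minor in-plane radius, centered
    radius = 0.4 * min(a_in, b_in)
    stack = min(15.0, 2 * 0.45 * a_in)
    roi = RoiSpec(
        center=tuple(int(round(c)) for c in center),
        radius=radius,
        stack_thickness=stack,
    )
    heights = VertebralHeights(
        level="sim",
        anterior=height_mm,
        middle=height_mm,
        posterior=height_mm,
        reference_height=cfg.body_height_mm,
    )
    truth = VolumeGroundTruth(
        true_bmd=cfg.trabecular_bmd,
        trabecular_hu=trab_hu,
        roi=roi,
        heights=heights,
        spacing=tuple(float(s) for s in sp),
    )
    return vol, truth
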