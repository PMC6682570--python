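"""Fracture-risk statistics: baseline tests, Cox models, KM curves, ROC.

The cohort is a pandas DataFrame with one row per patient and columns

    patient_id, age, sex, bmd_qct, dxa_tscore, prev_genant, phase,
    time_days, event

(``sex`` in {"F", "M"}; ``prev_genant`` the maximum Genant grade of prevalent
fractures, 0-3; ``time_days`` the fracture-free follow-up time from baseline
CT; ``event`` a boolean incident-fracture indicator).

Hazard ratios are expressed per SD *decrease* in the predictor: the predictor
is standardized as z = -(x - mean) / SD over the full cohort, so exp(beta)
is the risk multiplier for each one-SD reduction in BMD or T-score.  Ties in
event times are handled by the Breslow approximation (Efron available via
lifelines).  AUC is the Mann-Whitney statistic with ties counted one half;
its confidence interval uses the DeLong variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .densitometry import DiagnosticCategory, classify_dxa, classify_qct
from .errors import ConvergenceError, InputError, NoEventsError

__all__ = [
    "COHORT_COLUMNS",
    "CoxResult",
    "RocResult",
    "KmStratum",
    "validate_cohort",
    "two_group_tests",
    "welch_t_from_summary",
    "cox_per_sd",
    "breslow_partial_loglik",
    "km_estimate",
    "roc_analysis",
    "run_study",
    "render_markdown",
]

COHORT_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "bmd_qct",
    "dxa_tscore",
    "prev_genant",
    "phase",
    "time_days",
    "event",
)

DEFAULT_TARGET_SPECIFICITIES = (75.0, 81.0, 88.0, 94.0)


@dataclass(frozen=True)
class CoxResult:
    """Proportional-hazards fit for one predictor, per SD decrease."""

    predictor: str
    hr_per_sd_decrease: float
    ci95: tuple[float, float]
    beta: float
    se: float
    adjusted_for: tuple[str, ...]
    sd_used: float
    n: int
    n_events: int

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "hr_per_sd_decrease": self.hr_per_sd_decrease,
            "ci95": list(self.ci95),
            "beta": self.beta,
            "se": self.se,
            "adjusted_for": list(self.adjusted_for),
            "sd_used": self.sd_used,
            "n": self.n,
            "n_events": self.n_events,
        }


@dataclass(frozen=True)
class RocResult:
    """AUC with DeLong CI and the cutoff-at-target-specificity table."""

    auc: float
    ci95: tuple[float, float]
    cutoffs: tuple[tuple[float, float, float], ...]  # (target spec %, cutoff, sens %)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci95": list(self.ci95),
            "cutoffs": [
                {"specificity_pct": s, "cutoff": c, "sensitivity_pct": v}
                for s, c, v in self.cutoffs
            ],
        }


@dataclass(frozen=True)
class KmStratum:
    """Product-limit survival estimate for one diagnostic stratum."""

    stratum: str
    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n: int
    n_events: int


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise InputError(f"cohort table missing columns: {missing}")
    if (cohort["time_days"] <= 0).any():
        raise InputError("follow-up times must be positive")
    return cohort


# ---------------------------------------------------------------------------
# Baseline group comparisons


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t statistic and p-value from group summaries."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def two_group_tests(
    cohort: pd.DataFrame,
    continuous: Sequence[str] = ("age", "bmd_qct", "dxa_tscore"),
    categorical: Sequence[str] = ("sex", "prev_genant"),
    *,
    equal_var: bool = False,
) -> dict:
    """Compare baseline variables between event and non-event patients.

    Continuous variables use the two-sample t-test (Welch by default);
    categorical variables use the Pearson chi-square test on the contingency
    table without continuity correction.
    """
    validate_cohort(cohort)
    grp = cohort.groupby(cohort["event"].astype(bool))
    if len(grp) < 2:
        raise InputError("both event and non-event groups must be non-empty")
    g0 = cohort[~cohort["event"].astype(bool)]
    g1 = cohort[cohort["event"].astype(bool)]

    out: dict[str, dict] = {}
    for var in continuous:
        a, b = g1[var].dropna(), g0[var].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        out[var] = {
            "mean_event": float(a.mean()),
            "sd_event": float(a.std(ddof=1)),
            "mean_noevent": float(b.mean()),
            "sd_noevent": float(b.std(ddof=1)),
            "t": float(t),
            "p": float(p),
        }
    for var in categorical:
        table = pd.crosstab(cohort[var], cohort["event"].astype(bool))
        if table.shape[0] < 2 or table.shape[1] < 2:
            out[var] = {"counts": table.to_dict(), "chi2": None, "p": None}
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.values, correction=False)
        out[var] = {
            "counts": {str(k): row for k, row in zip(table.index, table.values.tolist())},
            "chi2": float(chi2),
            "p": float(p),
        }
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties), fitted by Newton-Raphson


def breslow_partial_loglik(
    beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow log partial likelihood at ``beta`` (reference formula).

    Every event at a tied time uses the full risk set.  Quadratic in n; meant
    for small data, grid oracles, and the fitter's own line search.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    eta = x @ beta
    ll = 0.0
    for t_k in np.unique(time[event]):
        dead = (time == t_k) & event
        at_risk = time >= t_k
        ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[at_risk]).sum())
    return float(ll)


def _cox_breslow_fit(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, *, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    Returns (beta_hat, covariance, loglik trace).  Risk-set sums are
    accumulated over descending event times so the fit is O(n p^2) per
    iteration after an initial sort.
    """
    n, p = x.shape
    order = np.argsort(-time, kind="stable")
    xs, ts, es = x[order], time[order], event[order]

    beta = np.zeros(p)
    trace: list[float] = []
    ll_old = -np.inf
    for it in range(max_iter):
        eta = xs @ beta
        eta -= eta.max()  # guard exp overflow; cancels in ratios
        w = np.exp(eta)
        cw = np.cumsum(w)
        cwx = np.cumsum(w[:, None] * xs, axis=0)
        cwxx = np.cumsum(w[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)

        # index of the last subject sharing each subject's time (risk-set end)
        _, inv, counts = np.unique(-ts, return_inverse=True, return_counts=True)
        last = np.cumsum(counts) - 1
        end = last[inv]

        ll = 0.0
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        ev = np.flatnonzero(es)
        for i in ev:
            j = end[i]
            s0 = cw[j]
            s1 = cwx[j]
            s2 = cwxx[j]
            ll += eta[i] - np.log(s0)
            m = s1 / s0
            grad += xs[i] - m
            hess -= s2 / s0 - np.outer(m, m)
        trace.append(float(ll))

        g_norm = float(np.abs(grad).max())
        if g_norm < 1e-10 and it > 0:
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}") from exc
        # step halving on likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = breslow_partial_loglik(cand, x, time, event)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        beta = beta + scale * step
        if abs(ll - ll_old) < 1e-12 and g_norm < 1e-8:
            break
        ll_old = ll
    else:
        raise ConvergenceError(
            f"Cox fit did not converge in {max_iter} iterations; "
            f"log-likelihood trace: {trace[-5:]}"
        )

    # final information matrix at beta_hat
    eta = xs @ beta
    eta -= eta.max()
    w = np.exp(eta)
    cw = np.cumsum(w)
    cwx = np.cumsum(w[:, None] * xs, axis=0)
    cwxx = np.cumsum(w[:, None, None] * (xs[:, :, None] * xs[:, None, :]), axis=0)
    _, inv, counts = np.unique(-ts, return_inverse=True, return_counts=True)
    last = np.cumsum(counts) - 1
    end = last[inv]
    info = np.zeros((p, p))
    for i in np.flatnonzero(es):
        j = end[i]
        m = cwx[j] / cw[j]
        info += cwxx[j] / cw[j] - np.outer(m, m)
    cov = np.linalg.inv(info)
    return beta, cov, trace


def _design_matrix(
    cohort: pd.DataFrame, predictor: str, covariates: Sequence[str]
) -> tuple[np.ndarray, float, float, list[str]]:
    x = cohort[predictor].to_numpy(float)
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        raise InputError(f"predictor {predictor!r} has zero SD")
    z = -(x - mean) / sd  # per SD *decrease*
    cols = [z]
    names = [predictor]
    for cov in covariates:
        if cov == "sex":
            cols.append((cohort["sex"].astype(str) == "M").to_numpy(float))
        else:
            cols.append(cohort[cov].to_numpy(float))
        names.append(cov)
    return np.column_stack(cols), mean, sd, names


def cox_per_sd(
    cohort: pd.DataFrame,
    predictor: str,
    covariates: Sequence[str] = (),
    *,
    ties: str = "breslow",
) -> CoxResult:
    """Cox proportional-hazards HR per SD decrease in ``predictor``.

    The predictor is standardized over the full cohort; covariates enter
    untransformed (age in years, sex as a male indicator, prevalent maximum
    Genant grade as an ordinal).  The 95% CI is the Wald interval
    exp(beta +/- 1.96 SE).  ``ties="breslow"`` uses the package's own
    Newton-Raphson fitter; ``ties="efron"`` delegates to lifelines.
    """
    validate_cohort(cohort)
    event = cohort["event"].to_numpy(bool)
    if not event.any():
        raise NoEventsError("cohort has no incident fractures; HR not estimable")
    time = cohort["time_days"].to_numpy(float)
    x, _, sd, names = _design_matrix(cohort, predictor, covariates)

    if ties == "breslow":
        beta_vec, cov, _ = _cox_breslow_fit(x, time, event)
        beta, se = float(beta_vec[0]), float(np.sqrt(cov[0, 0]))
    elif ties == "efron":
        from lifelines import CoxPHFitter

        df = pd.DataFrame(x, columns=names)
        df["_t"], df["_e"] = time, event.astype(int)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="_t", event_col="_e")
        beta = float(cph.params_[names[0]])
        se = float(cph.standard_errors_[names[0]])
    else:
        raise InputError(f"unknown ties method: {ties!r}")

    lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    return CoxResult(
        predictor=predictor,
        hr_per_sd_decrease=float(np.exp(beta)),
        ci95=(float(lo), float(hi)),
        beta=beta,
        se=se,
        adjusted_for=tuple(covariates),
        sd_used=sd,
        n=len(cohort),
        n_events=int(event.sum()),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_estimate(
    cohort: pd.DataFrame, strata: Sequence[str] | pd.Series
) -> dict[str, KmStratum]:
    """Product-limit survival estimate per diagnostic stratum.

    ``strata`` assigns each row a stratum label (e.g. a DiagnosticCategory
    value).  Censored subjects leave the risk set at their censoring time.
    """
    from lifelines import KaplanMeierFitter

    validate_cohort(cohort)
    labels = pd.Series([getattr(s, "value", s) for s in strata], index=cohort.index)
    out: dict[str, KmStratum] = {}
    for label in sorted(labels.unique()):
        sub = cohort[labels == label]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], event_observed=sub["event"].astype(bool))
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).fillna(0).astype(int)
        out[str(label)] = KmStratum(
            stratum=str(label),
            times=tuple(float(t) for t in sf.index),
            survival=tuple(float(v) for v in sf.values),
            at_risk=tuple(int(v) for v in at_risk.values),
            n=len(sub),
            n_events=int(sub["event"].astype(bool).sum()),
        )
    return out


# ---------------------------------------------------------------------------
# ROC


def _midrank_auc(risk_pos: np.ndarray, risk_neg: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted one half (midranks)."""
    ranks = stats.rankdata(np.concatenate([risk_pos, risk_neg]))
    n1, n0 = len(risk_pos), len(risk_neg)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(risk_pos: np.ndarray, risk_neg: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC via placement values."""
    n1, n0 = len(risk_pos), len(risk_neg)
    all_r = np.concatenate([risk_pos, risk_neg])
    r_all = stats.rankdata(all_r)
    r_pos = stats.rankdata(risk_pos)
    r_neg = stats.rankdata(risk_neg)
    v10 = (r_all[:n1] - r_pos) / n0  # placement of each positive among negatives
    v01 = 1.0 - (r_all[n1:] - r_neg) / n1
    s10 = v10.var(ddof=1) if n1 > 1 else 0.0
    s01 = v01.var(ddof=1) if n0 > 1 else 0.0
    return s10 / n1 + s01 / n0


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    target_specificities: Sequence[float] = DEFAULT_TARGET_SPECIFICITIES,
) -> RocResult:
    """ROC analysis for a predictor where *lower* values indicate higher risk.

    AUC is computed on negated scores by the Mann-Whitney statistic (ties one
    half) with a DeLong 95% CI.  For each target specificity (percent), the
    reported cutoff is the largest threshold c such that classifying
    ``score <= c`` as positive keeps specificity >= target; among cutoffs with
    equal sensitivity the lower one is reported.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    pos, neg = scores[labels], scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both classes must be present for ROC analysis")

    auc = _midrank_auc(-pos, -neg)
    var = _delong_variance(-pos, -neg, auc)
    half = 1.96 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    cutoffs: list[tuple[float, float, float]] = []
    cand = np.unique(scores)
    spec = np.array([(neg > c).mean() for c in cand])
    sens = np.array([(pos <= c).mean() for c in cand])
    for target in sorted(target_specificities):
        ok = spec >= target / 100.0
        if not ok.any():
            continue
        best_sens = sens[ok].max()
        chosen = float(cand[ok & (sens == best_sens)].min())
        cutoffs.append((float(target), chosen, float(100.0 * best_sens)))
    return RocResult(auc=auc, ci95=ci, cutoffs=tuple(cutoffs))


# ---------------------------------------------------------------------------
# Orchestration

COX_ADJUSTMENTS: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "age": ("age",),
    "age_sex": ("age", "sex"),
    "age_sex_prevfx": ("age", "sex", "prev_genant"),
}


def run_study(
    cohort: pd.DataFrame,
    *,
    target_specificities: Sequence[float] = DEFAULT_TARGET_SPECIFICITIES,
    ties: str = "breslow",
    equal_var: bool = False,
) -> dict:
    """Run the full QCT-vs-DXA comparison and return a JSON-ready report.

    Executes baseline two-group tests, the 2 x 4 grid of Cox models
    (BMD and T-score, unadjusted and progressively adjusted), Kaplan-Meier
    strata per diagnostic modality, and ROC analyses for both predictors.
    Cells that are not estimable (e.g. with zero events) are reported as null.
    """
    validate_cohort(cohort)
    report: dict = {"n": len(cohort), "n_events": int(cohort["event"].sum())}

    try:
        report["baseline"] = two_group_tests(cohort, equal_var=equal_var)
    except InputError:
        report["baseline"] = None

    report["cox"] = {}
    for predictor in ("bmd_qct", "dxa_tscore"):
        report["cox"][predictor] = {}
        for name, covs in COX_ADJUSTMENTS.items():
            try:
                res = cox_per_sd(cohort, predictor, covs, ties=ties)
                report["cox"][predictor][name] = res.as_dict()
            except (NoEventsError, ConvergenceError):
                report["cox"][predictor][name] = None

    qct_cat = [classify_qct(b).value for b in cohort["bmd_qct"]]
    dxa_cat = [classify_dxa(t).value for t in cohort["dxa_tscore"]]
    report["km"] = {}
    for modality, cats in (("qct", qct_cat), ("dxa", dxa_cat)):
        strata = km_estimate(cohort, cats)
        report["km"][modality] = {
            k: {
                "times": list(v.times),
                "survival": list(v.survival),
                "at_risk": list(v.at_risk),
                "n": v.n,
                "n_events": v.n_events,
            }
            for k, v in strata.items()
        }

    report["roc"] = {}
    for predictor in ("bmd_qct", "dxa_tscore"):
        try:
            res = roc_analysis(
                cohort[predictor].to_numpy(float),
                cohort["event"].to_numpy(bool),
                target_specificities,
            )
            report["roc"][predictor] = res.as_dict()
        except InputError:
            report["roc"][predictor] = None
    return report


def render_markdown(report: Mapping) -> str:
    """Render the study report as human-readable Markdown tables."""
    lines = [f"# Study report (n = {report['n']}, events = {report['n_events']})", ""]
    if report.get("baseline"):
        lines += ["## Baseline comparison", "", "| variable | event | no event | p |", "|---|---|---|---|"]
        for var, d in report["baseline"].items():
            if "t" in d:
                lines.append(
                    f"| {var} | {d['mean_event']:.1f} ({d['sd_event']:.1f}) "
                    f"| {d['mean_noevent']:.1f} ({d['sd_noevent']:.1f}) | {d['p']:.3g} |"
                )
            elif d.get("p") is not None:
                lines.append(f"| {var} (chi2) | | | {d['p']:.3g} |")
    lines += ["", "## Hazard ratios per SD decrease", "", "| predictor | adjustment | HR (95% CI) |", "|---|---|---|"]
    for pred, grid in report["cox"].items():
        for adj, cell in grid.items():
            if cell is None:
                lines.append(f"| {pred} | {adj} | not estimable |")
            else:
                lo, hi = cell["ci95"]
                lines.append(
                    f"| {pred} | {adj} | {cell['hr_per_sd_decrease']:.2f} ({lo:.2f}-{hi:.2f}) |"
                )
    lines += ["", "## ROC", "", "| predictor | AUC (95% CI) | cutoffs (spec%: cutoff, sens%) |", "|---|---|---|"]
    for pred, cell in report["roc"].items():
        if cell is None:
            lines.append(f"| {pred} | not estimable | |")
        else:
            cuts = "; ".join(
                f"{c['specificity_pct']:.0f}%: {c['cutoff']:.1f} ({c['sensitivity_pct']:.0f}%)"
                for c in cell["cutoffs"]
            )
            lo, hi = cell["ci95"]
            lines.append(f"| {pred} | {cell['auc']:.2f} ({lo:.2f}-{hi:.2f}) | {cuts} |")
    return "\n".join(lines) + "\n"
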