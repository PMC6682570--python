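"""Cox models, KM estimates, ROC analysis, and baseline tests vs oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oppqct import (
    CohortSimConfig,
    cox_per_sd,
    km_estimate,
    roc_analysis,
    run_study,
    simulate_cohort,
    two_group_tests,
)
from oppqct.errors import InputError, NoEventsError
from oppqct.risk import breslow_partial_loglik, render_markdown, welch_t_from_summary


def toy_cohort(bmd, time, event, **extra):
    n = len(bmd)
    base = {
        "patient_id": [f"p{i}" for i in range(n)],
        "age": extra.get("age", np.full(n, 70.0)),
        "sex": extra.get("sex", ["F"] * n),
        "bmd_qct": bmd,
        "dxa_tscore": extra.get("tscore", -np.asarray(bmd) / 50),
        "prev_genant": extra.get("prev_genant", np.zeros(n, int)),
        "phase": ["non_enhanced"] * n,
        "time_days": time,
        "event": event,
    }
    return pd.DataFrame(base)


class TestTwoGroupTests:
    def test_welch_t_from_published_group_summaries(self):
        """Summary-statistic Welch t for 93.3 (41.7, n=68) vs 56.7 (31.6, n=16)."""
        t, p = welch_t_from_summary(93.3, 41.7, 68, 56.7, 31.6, 16)
        assert t == pytest.approx(3.90, abs=0.01)
        assert p < 0.005

    def test_identical_groups(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 10, 40)
        cohort = toy_cohort(
            np.concatenate([x, x]),
            np.full(80, 500.0),
            np.array([True] * 40 + [False] * 40),
            age=np.concatenate([x, x]),
            tscore=np.concatenate([x, x]) / -50,
        )
        res = two_group_tests(cohort)
        assert res["bmd_qct"]["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["age"]["p"] == pytest.approx(1.0)

    def test_chi_square_hand_contingency(self):
        """2x2 table {{10,10},{20,0}} gives the closed-form Pearson chi2 40/3."""
        sex = ["F"] * 10 + ["M"] * 20 + ["F"] * 10
        event = [True] * 10 + [True] * 20 + [False] * 10
        cohort = toy_cohort(np.arange(40.0) + 50, np.full(40, 100.0), event, sex=sex)
        res = two_group_tests(cohort, continuous=(), categorical=("sex",))
        assert res["sex"]["chi2"] == pytest.approx(40 / 3, rel=1e-9)

    def test_welch_vs_hand_formula_on_cohort(self):
        cohort = simulate_cohort(CohortSimConfig(seed=5))
        res = two_group_tests(cohort)
        d = res["bmd_qct"]
        t, p = welch_t_from_summary(
            d["mean_event"], d["sd_event"], 16, d["mean_noevent"], d["sd_noevent"], 68
        )
        assert d["t"] == pytest.approx(t, rel=1e-9)
        assert d["p"] == pytest.approx(p, rel=1e-9)

    def test_single_group_rejected(self):
        cohort = toy_cohort([1.0, 2.0], [10.0, 20.0], [True, True])
        with pytest.raises(InputError):
            two_group_tests(cohort)


def grid_breslow_beta(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force maximizer of the Breslow partial likelihood (oracle)."""
    grid = np.arange(lo, hi + step, step)
    x2 = np.asarray(x, float).reshape(-1, 1)
    ll = [breslow_partial_loglik(np.array([b]), x2, np.asarray(time, float), np.asarray(event, bool)) for b in grid]
    return grid[int(np.argmax(ll))]


class TestCox:
    def test_toy_fit_matches_grid_oracle(self):
        """4 subjects, all events: Newton beta equals exhaustive grid search."""
        bmd = np.array([80.0, 60.0, 120.0, 100.0])
        time = np.array([100.0, 250.0, 400.0, 700.0])
        event = np.array([True, True, True, True])
        cohort = toy_cohort(bmd, time, event)
        res = cox_per_sd(cohort, "bmd_qct")
        z = -(bmd - bmd.mean()) / bmd.std(ddof=1)
        beta_grid = grid_breslow_beta(z, time, event)
        assert abs(res.beta - beta_grid) < 1e-3

    def test_toy_fit_with_censoring_matches_grid(self):
        bmd = np.array([55.0, 70.0, 90.0, 110.0, 130.0, 150.0])
        time = np.array([80.0, 150.0, 900.0, 300.0, 1200.0, 500.0])
        event = np.array([True, True, False, True, False, True])
        cohort = toy_cohort(bmd, time, event)
        res = cox_per_sd(cohort, "bmd_qct")
        z = -(bmd - bmd.mean()) / bmd.std(ddof=1)
        assert abs(res.beta - grid_breslow_beta(z, time, event)) < 1e-3

    def test_null_predictor_hr_near_one(self):
        rng = np.random.default_rng(11)
        n = 2000
        bmd = rng.normal(90, 40, n)
        time = rng.exponential(1000, n)
        censor = rng.uniform(1, 2425, n)
        cohort = toy_cohort(
            bmd, np.minimum(time, censor), time <= censor
        )
        res = cox_per_sd(cohort, "bmd_qct")
        assert abs(res.beta) < 3 * res.se

    def test_sign_flip_inverts_hr(self):
        cohort = simulate_cohort(
            CohortSimConfig(seed=3, mode="hazard_driven", n_fracture=0, n_nonfracture=500)
        )
        res = cox_per_sd(cohort, "bmd_qct")
        flipped = cohort.assign(bmd_qct=-cohort["bmd_qct"])
        res_f = cox_per_sd(flipped, "bmd_qct")
        assert res_f.hr_per_sd_decrease == pytest.approx(
            1 / res.hr_per_sd_decrease, rel=1e-6
        )

    def test_breslow_agrees_with_lifelines_on_tie_free_data(self):
        """Independent cross-check: with no tied event times the Breslow and
        Efron partial likelihoods coincide, so our Newton fitter must agree
        with lifelines."""
        cohort = simulate_cohort(
            CohortSimConfig(seed=9, mode="hazard_driven", n_fracture=0, n_nonfracture=600)
        )
        a = cox_per_sd(cohort, "bmd_qct", ("age", "sex"), ties="breslow")
        b = cox_per_sd(cohort, "bmd_qct", ("age", "sex"), ties="efron")
        assert a.beta == pytest.approx(b.beta, abs=1e-5)
        assert a.se == pytest.approx(b.se, rel=1e-4)

    def test_adjusted_model_runs(self):
        cohort = simulate_cohort(CohortSimConfig(seed=4))
        res = cox_per_sd(cohort, "bmd_qct", ("age", "sex", "prev_genant"))
        assert res.adjusted_for == ("age", "sex", "prev_genant")
        assert res.ci95[0] <= res.hr_per_sd_decrease <= res.ci95[1]

    def test_zero_events_rejected(self):
        cohort = toy_cohort([60.0, 90.0, 120.0], [100.0, 200.0, 300.0], [False] * 3)
        with pytest.raises(NoEventsError):
            cox_per_sd(cohort, "bmd_qct")


class TestKm:
    def test_three_subject_hand_product_limit(self):
        """Events at 100 and 200 d, censor at 300 d: S(100)=2/3, S(200)=1/3."""
        cohort = toy_cohort(
            [60.0, 80.0, 100.0],
            [100.0, 200.0, 300.0],
            [True, True, False],
        )
        strata = km_estimate(cohort, ["all"] * 3)["all"]
        sf = dict(zip(strata.times, strata.survival))
        assert sf[100.0] == pytest.approx(2 / 3)
        assert sf[200.0] == pytest.approx(1 / 3)

    def test_no_events_flat_survival(self):
        cohort = toy_cohort([60.0, 80.0], [100.0, 200.0], [False, False])
        strata = km_estimate(cohort, ["all", "all"])["all"]
        assert all(s == pytest.approx(1.0) for s in strata.survival)

    def test_km_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(21)
        t = rng.exponential(300, 50).round(2)
        cohort = toy_cohort(rng.normal(90, 30, 50), t, [True] * 50)
        strata = km_estimate(cohort, ["all"] * 50)["all"]
        for ti, si in zip(strata.times, strata.survival):
            if ti > 0:
                assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_merging_identical_strata_unchanged(self):
        cohort = toy_cohort(
            [60.0, 80.0, 100.0, 60.0, 80.0, 100.0],
            [100.0, 200.0, 300.0, 100.0, 200.0, 300.0],
            [True, True, False, True, True, False],
        )
        split = km_estimate(cohort, ["a", "a", "a", "b", "b", "b"])
        pooled = km_estimate(cohort, ["all"] * 6)["all"]
        assert split["a"].survival == pytest.approx(pooled.survival)
        assert split["a"].times == pooled.times


def auc_pair_counting(scores, labels):
    """Exhaustive concordant-pair oracle; lower score = higher risk."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p < q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


class TestRoc:
    def test_perfect_separation(self):
        scores = [50.0, 60.0, 110.0, 120.0]
        labels = [True, True, False, False]
        assert roc_analysis(scores, labels).auc == pytest.approx(1.0)

    def test_four_point_example(self):
        res = roc_analysis([1.0, 2.0, 3.0, 4.0], [True, False, True, False])
        assert res.auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        scores = np.round(rng.normal(80, 30, 150), 0)  # rounding forces ties
        labels = rng.random(150) < 0.3
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(14)
        scores = rng.normal(80, 30, 300)
        labels = rng.random(300) < 0.25
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(roc_auc_score(labels, -scores), abs=1e-12)

    def test_cutoff_rule(self):
        """Cutoff = largest threshold keeping specificity >= target."""
        scores = [40.0, 55.0, 62.0, 70.0, 85.0, 90.0, 100.0, 120.0]
        labels = [True, True, True, False, True, False, False, False]
        res = roc_analysis(scores, labels, target_specificities=(75.0,))
        (target, cutoff, sens) = res.cutoffs[0]
        # spec at cutoff 62: negs > 62 are 70,90,100,120 -> 4/4 = 100% >= 75%
        # cutoff 85 gives spec 3/4 = 75% >= 75% with sens 4/4
        assert target == 75.0
        assert cutoff == 85.0
        assert sens == pytest.approx(100.0)

    def test_ci_contains_auc(self):
        rng = np.random.default_rng(15)
        scores = np.concatenate([rng.normal(60, 30, 40), rng.normal(95, 40, 160)])
        labels = np.array([True] * 40 + [False] * 160)
        res = roc_analysis(scores, labels)
        assert res.ci95[0] <= res.auc <= res.ci95[1]

    def test_one_class_rejected(self):
        with pytest.raises(InputError):
            roc_analysis([1.0, 2.0], [True, True])


class TestRunStudy:
    def test_all_cox_cells_populated(self):
        cohort = simulate_cohort(CohortSimConfig(seed=8))
        report = run_study(cohort)
        cells = [
            report["cox"][p][a]
            for p in ("bmd_qct", "dxa_tscore")
            for a in ("unadjusted", "age", "age_sex", "age_sex_prevfx")
        ]
        assert len(cells) == 8
        assert all(c is not None for c in cells)
        assert set(report["km"]) == {"qct", "dxa"}

    def test_zero_event_cohort_marked_not_estimable(self):
        cohort = simulate_cohort(CohortSimConfig(seed=8))
        cohort = cohort.assign(event=False)
        report = run_study(cohort)
        assert all(
            report["cox"][p][a] is None
            for p in ("bmd_qct", "dxa_tscore")
            for a in report["cox"][p]
        )
        for strata in report["km"]["qct"].values():
            assert all(s == pytest.approx(1.0) for s in strata["survival"])
        assert report["roc"]["bmd_qct"] is None

    def test_deterministic_report(self):
        import json

        a = run_study(simulate_cohort(CohortSimConfig(seed=8)))
        b = run_study(simulate_cohort(CohortSimConfig(seed=8)))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_markdown_renders(self):
        report = run_study(simulate_cohort(CohortSimConfig(seed=8)))
        md = render_markdown(report)
        assert "Hazard ratios" in md and "| bmd_qct |" in md
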