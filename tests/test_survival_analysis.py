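import numpy as np
import pandas as pd
import pytest

import petmtv as pm
from petmtv.survival_analysis import HORIZON_5Y_DAYS, binary_outcome

from oracles import (
    breslow_loglik_by_hand,
    km_by_hand,
    logrank_by_hand,
    roc_table_enumerate,
)


class TestBinaryOutcome:
    def test_event_within_horizon_is_positive(self):
        out, inc = binary_outcome([100, 3000], [1, 0], horizon_days=1826)
        assert out.tolist() == [1, 0]
        assert inc.tolist() == [True, True]

    def test_censored_before_horizon_excluded(self):
        out, inc = binary_outcome([500], [0], horizon_days=1826)
        assert inc.tolist() == [False]


class TestRocCurve:
    def test_perfect_separation(self):
        roc = pm.roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        thr, sens, spec = pm.optimal_cutoff(roc)
        assert (thr, sens, spec) == (3.0, 1.0, 1.0)

    def test_uninformative_marker(self):
        rng = np.random.default_rng(9)
        mtv = rng.lognormal(6, 1, 2000)
        y = rng.integers(0, 2, 2000)
        roc = pm.roc_curve(mtv, y)
        assert roc.auc == pytest.approx(0.5, abs=0.05)
        assert roc.auc_ci[0] < 0.5 < roc.auc_ci[1]

    def test_sens_spec_match_2x2_enumeration(self):
        mtv = [10.0, 20.0, 20.0, 30.0, 40.0, 50.0]
        y = [0, 0, 1, 0, 1, 1]
        roc = pm.roc_curve(mtv, y)
        expected = roc_table_enumerate(mtv, y)
        assert roc.thresholds.tolist() == [t for t, _, _ in expected]
        for i, (_, s, sp) in enumerate(expected):
            assert roc.sensitivity[i] == pytest.approx(s)
            assert roc.specificity[i] == pytest.approx(sp)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        mtv = rng.lognormal(6, 1, 300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(np.log(mtv) - 6)))).astype(int)
        roc = pm.roc_curve(mtv, y)
        assert roc.auc == pytest.approx(roc_auc_score(y, mtv), abs=1e-10)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        mtv = rng.lognormal(6, 1, 200)
        y = (mtv > np.median(mtv)).astype(int) ^ (rng.random(200) < 0.2).astype(int)
        a1 = pm.roc_curve(mtv, y).auc
        a2 = pm.roc_curve(np.cbrt(mtv), y).auc
        a3 = pm.roc_curve(0.27 * mtv, y).auc
        assert a1 == pytest.approx(a2) == pytest.approx(a3)

    def test_bootstrap_ci_close_to_delong(self):
        rng = np.random.default_rng(12)
        mtv = rng.lognormal(6, 1, 150)
        y = (mtv > 400).astype(int) ^ (rng.random(150) < 0.25).astype(int)
        d = pm.roc_curve(mtv, y, ci_method="delong")
        b = pm.roc_curve(mtv, y, ci_method="bootstrap", n_boot=500,
                         rng=np.random.default_rng(0))
        assert d.auc_ci[0] == pytest.approx(b.auc_ci[0], abs=0.06)
        assert d.auc_ci[1] == pytest.approx(b.auc_ci[1], abs=0.06)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            pm.roc_curve([1, 2, 3], [1, 1, 1])


class TestOptimalCutoff:
    def test_exhaustive_search_equivalence(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            mtv = rng.lognormal(6, 1, n)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            roc = pm.roc_curve(mtv, y)
            thr, sens, spec = pm.optimal_cutoff(roc)
            d2 = (1 - roc.sensitivity) ** 2 + (1 - roc.specificity) ** 2
            best = d2.min()
            i = roc.thresholds.tolist().index(thr)
            assert d2[i] == pytest.approx(best)
            ties = roc.thresholds[np.isclose(d2, best)]
            assert thr == min(ties)  # smallest threshold among minimisers

    def test_degenerate_single_candidate(self):
        roc = pm.roc_curve([5.0, 5.0, 5.0, 5.0], [0, 1, 0, 1])
        thr, sens, spec = pm.optimal_cutoff(roc)
        assert thr == 5.0 and sens == 1.0 and spec == 0.0


class TestDichotomize:
    def test_inclusive_at_cutoff(self):
        assert pm.dichotomize([400.0, 399.9, 500.0], 400.0).tolist() == [
            "high", "low", "high",
        ]

    def test_cutoff_above_max_all_low(self):
        assert set(pm.dichotomize([10.0, 20.0], 1e6)) == {"low"}


class TestKMEstimate:
    def test_product_limit_by_hand(self):
        g = pm.km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        t, s = km_by_hand([1, 2, 3, 4], [1, 1, 1, 1])
        # S(2.5) = 0.5 after two of four events
        idx = np.searchsorted(g.km_curve[0], 2.5, side="right") - 1
        assert g.km_curve[1][idx] == pytest.approx(0.5)
        for ti, si in zip(t, s):
            j = np.searchsorted(g.km_curve[0], ti, side="right") - 1
            assert g.km_curve[1][j] == pytest.approx(si)

    def test_no_events_flat_curve(self):
        g = pm.km_estimate([100, 200, 300], [0, 0, 0])
        assert g.surv_5y == 1.0
        assert np.isnan(g.median_survival)

    def test_censoring_shrinks_risk_set(self):
        # censor at t=1.5 before the event at t=2: S(2)=1-1/2=0.5... with
        # risk set {2,3} of size 2 at t=2 and {3} at t=3
        g = pm.km_estimate([1.5, 2, 3], [0, 1, 1])
        t, s = km_by_hand([1.5, 2, 3], [0, 1, 1])
        for ti, si in zip(t, s):
            j = np.searchsorted(g.km_curve[0], ti, side="right") - 1
            assert g.km_curve[1][j] == pytest.approx(si)

    def test_uncensored_equals_empirical_survival(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(1000, 80)
        g = pm.km_estimate(times, np.ones(80, int))
        for t in [100, 500, 1500]:
            emp = np.mean(times > t)
            j = np.searchsorted(g.km_curve[0], t, side="right") - 1
            got = g.km_curve[1][j] if j >= 0 else 1.0
            assert got == pytest.approx(emp)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [100.0, 200, 300, 400, 500]
        e = [1, 1, 0, 1, 0]
        chi2, p = pm.logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_toy(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 1, 1]
        chi2, _ = pm.logrank_test(ta, ea, tb, eb)
        assert chi2 == pytest.approx(logrank_by_hand(ta, ea, tb, eb), rel=1e-6)

    def test_strong_hazard_ratio_detected(self):
        detected = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ta = rng.exponential(5000, 100)
            tb = rng.exponential(1000, 100)
            cen = 4000.0
            _, p = pm.logrank_test(
                np.minimum(ta, cen), (ta <= cen).astype(int),
                np.minimum(tb, cen), (tb <= cen).astype(int),
            )
            detected += p < 0.001
        assert detected >= 38  # >= 95% of replicates

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            pm.logrank_test([], [], [1.0], [1])


class TestCox:
    def test_identical_hazards(self):
        rng = np.random.default_rng(15)
        t = rng.exponential(1000, 200)
        e = np.ones(200, int)
        g = np.array(["high", "low"] * 100)
        hr, lo, hi, p = pm.cox_univariate(t, e, g)
        assert lo < 1 < hi
        assert hr == pytest.approx(1.0, abs=0.35)

    def test_breslow_matches_hand_partial_likelihood(self):
        # tied event times exercise the Breslow risk-set convention
        t = np.array([2.0, 2.0, 3.0, 5.0])
        e = np.array([1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        g = np.where(x == 1, "high", "low")
        hr, _, _, _ = pm.cox_univariate(t, e, g)
        beta_hat = np.log(hr)
        grid = np.linspace(beta_hat - 2, beta_hat + 2, 2001)
        lls = [breslow_loglik_by_hand(b, t, e, x) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - beta_hat) < 2e-3

    def test_efron_route_agrees_without_ties(self):
        rng = np.random.default_rng(16)
        t = rng.exponential(1000, 120) * np.where(np.arange(120) < 60, 1.0, 0.3)
        e = np.ones(120, int)
        g = np.where(np.arange(120) < 60, "low", "high")
        hr_b, lo_b, hi_b, _ = pm.cox_univariate(t, e, g, ties="breslow")
        hr_e, lo_e, hi_e, _ = pm.cox_univariate(t, e, g, ties="efron")
        assert hr_b == pytest.approx(hr_e, rel=1e-4)
        assert lo_b == pytest.approx(lo_e, rel=1e-3)

    def test_complete_separation_diagnosed(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        g = np.array(["high"] * 3 + ["low"] * 3)
        with pytest.raises(RuntimeError, match="converge|separation|monotone"):
            pm.cox_univariate(t, e, g)

    def test_missing_group_raises(self):
        with pytest.raises(ValueError):
            pm.cox_univariate([1, 2, 3], [1, 1, 1], ["high"] * 3)


class TestSurvivalReport:
    def test_report_on_calibrated_cohort(self, cohort):
        rep = pm.survival_report(cohort, "mtv_fixed25")
        assert rep["logrank_p"] < 0.001
        assert rep["cox_hr"] > 2
        assert rep["groups"]["low"]["surv_5y"] > rep["groups"]["high"]["surv_5y"]
        assert rep["optimal_threshold_cm3"] in cohort["mtv_fixed25"].to_numpy()

    def test_schema_violation_rejected(self, cohort):
        bad = cohort.drop(columns=["event_pfs"])
        with pytest.raises(ValueError, match="missing"):
            pm.survival_report(bad, "mtv_fixed25")
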