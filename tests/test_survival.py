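"""Kaplan–Meier, log-rank and Cox against hand computations, brute-force
oracles and the lifelines reference implementation."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ihcmil.survival import (SurvivalRecord, auc_ci_delong, cox_fit,
                             km_estimate, logrank_test)

lifelines = pytest.importorskip("lifelines")


class TestKaplanMeier:
    def test_product_limit_hand_computation(self):
        # times 1..5 all events: S = 0.8, 0.6, 0.4, 0.2, 0.0; median = 3
        km = km_estimate(times=[1, 2, 3, 4, 5], events=[1, 1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert km.median == 3

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate(times=[2, 5, 9], events=[0, 0, 0])
        assert km.times.size == 0
        assert np.isnan(km.median)
        np.testing.assert_array_equal(km.survival_at([1, 4, 10]), [1, 1, 1])

    def test_single_event_drops_to_zero(self):
        km = km_estimate(times=[2.0], events=[1])
        assert km.survival_at(2.0) == 0.0
        assert km.median == 2.0

    def test_no_censoring_equals_empirical_survivor(self):
        """Without censoring the KM estimate is the empirical S(t) = P(T > t)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            t = np.round(rng.exponential(5, n), 1) + 0.1
            km = km_estimate(times=t, events=np.ones(n, int))
            grid = np.unique(t)
            emp = np.array([(t > g).mean() for g in grid])
            np.testing.assert_allclose(km.survival_at(grid), emp, atol=1e-12)

    def test_median_and_quartiles_match_lifelines(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(6, 120)
        e = (rng.random(120) > 0.25).astype(int)
        km = km_estimate(times=t, events=e)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        assert km.median == pytest.approx(kmf.median_survival_time_)
        grid = np.linspace(0.5, 20, 13)
        ours = km.survival_at(grid)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestLogRank:
    def test_identical_groups_give_null(self):
        t, e = [1, 3, 5, 7], [1, 1, 0, 1]
        res = logrank_test(times_a=t, events_a=e, times_b=t, events_b=e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_observed_equals_expected_total(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.exponential(3, 40), rng.exponential(6, 50)
        ea = (rng.random(40) > 0.2).astype(int)
        eb = (rng.random(50) > 0.2).astype(int)
        res = logrank_test(times_a=ta, events_a=ea, times_b=tb, events_b=eb)
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test(times_a=[1, 2], events_a=[0, 0],
                         times_b=[3], events_b=[0])

    def test_matches_lifelines_statistic(self):
        rng = np.random.default_rng(8)
        ta, tb = rng.exponential(3, 60), rng.exponential(5, 45)
        ea = (rng.random(60) > 0.3).astype(int)
        eb = (rng.random(45) > 0.3).astype(int)
        ours = logrank_test(times_a=ta, events_a=ea, times_b=tb, events_b=eb)
        ref = lifelines.statistics.logrank_test(ta, tb, ea, eb)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_to_monotone_time_rescaling(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(2, 30), rng.exponential(4, 30)
        ea = np.ones(30, int)
        eb = (rng.random(30) > 0.2).astype(int)
        r1 = logrank_test(times_a=ta, events_a=ea, times_b=tb, events_b=eb)
        r2 = logrank_test(times_a=np.sqrt(ta), events_a=ea,
                          times_b=np.sqrt(tb), events_b=eb)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_power_against_planted_hazard_ratio(self):
        """HR=3 with n=200 per arm should be detected essentially always."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(40):
            ta = rng.exponential(1.0, 200)
            tb = rng.exponential(3.0, 200)
            res = logrank_test(times_a=ta, events_a=np.ones(200, int),
                               times_b=tb, events_b=np.ones(200, int))
            hits += res.p_value < 0.01
        assert hits >= 38


class TestCox:
    def test_symmetric_groups_give_unit_hr(self):
        t = [1, 2, 3, 5, 8]
        recs = [SurvivalRecord(f"p{i}", ti, 1, g)
                for g in (0, 1) for i, ti in enumerate(t)]
        res = cox_fit(recs)
        assert res.beta == pytest.approx(0.0, abs=1e-8)
        assert res.hr == pytest.approx(1.0, abs=1e-8)

    def test_toy_matches_partial_likelihood_grid_oracle(self):
        """4-record set: beta must equal the brute-force likelihood maximizer."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        g = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_ll(b):
            out = 0.0
            for i in range(4):
                risk = t >= t[i]
                out += b * g[i] - np.log(np.sum(np.exp(b * g[risk])))
            return -out

        oracle = minimize_scalar(neg_ll, bounds=(-5, 5), method="bounded",
                                 options={"xatol": 1e-12}).x
        res = cox_fit(times=t, events=[1, 1, 1, 1], covariate=g)
        assert res.beta == pytest.approx(oracle, abs=1e-4)

    def test_relabeling_negates_beta(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(3, 80)
        e = (rng.random(80) > 0.2).astype(int)
        g = (rng.random(80) > 0.5).astype(float)
        r1 = cox_fit(times=t, events=e, covariate=g)
        r2 = cox_fit(times=t, events=e, covariate=1 - g)
        assert r1.beta == pytest.approx(-r2.beta, abs=1e-6)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines_with_ties(self, ties):
        rng = np.random.default_rng(12)
        t = np.ceil(rng.exponential(4, 100))      # heavy ties, like PFS months
        e = (rng.random(100) > 0.25).astype(int)
        g = (rng.random(100) > 0.5).astype(float)
        ours = cox_fit(times=t, events=e, covariate=g, ties=ties)
        import pandas as pd
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame(dict(T=t, E=e, g=g)), "T", "E")
        if ties == "efron":  # lifelines implements Efron only
            assert ours.beta == pytest.approx(cph.params_.iloc[0], abs=1e-5)
            assert ours.se == pytest.approx(cph.standard_errors_.iloc[0], abs=1e-5)

    def test_score_test_equals_logrank_on_tie_free_data(self):
        """Cox score statistic at beta=0 (Breslow) is the log-rank chi-square."""
        from ihcmil.survival import _cox_loglik

        rng = np.random.default_rng(21)
        ta, tb = rng.exponential(2, 50), rng.exponential(4, 50)
        t = np.concatenate([ta, tb])
        e = np.ones(100, int)
        g = np.concatenate([np.zeros(50), np.ones(50)])
        _, score, info = _cox_loglik(0.0, t, e.astype(int), g, "breslow")
        lr = logrank_test(times_a=ta, events_a=np.ones(50, int),
                          times_b=tb, events_b=np.ones(50, int))
        assert score**2 / info == pytest.approx(lr.statistic, rel=1e-9)

    def test_complete_separation_raises(self):
        # group 1 always fails first: monotone likelihood
        t = np.r_[np.arange(1, 11), np.arange(11, 21)].astype(float)
        g = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(RuntimeError, match="infinite HR"):
            cox_fit(times=t, events=np.ones(20, int), covariate=g)


def test_delong_ci_brackets_auc():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 80)
    s = y + rng.normal(0, 1, 80)
    auc, (lo, hi) = auc_ci_delong(s, y)
    assert lo <= auc <= hi
    assert 0.5 < auc < 1.0
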