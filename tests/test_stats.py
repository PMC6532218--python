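"""Rank tests, dichotomization and survival procedures vs independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import oracles
from ihczone.stats import (
    CoxBackwardModel,
    cox_backward,
    km_estimate,
    km_logrank,
    kruskal_wallis,
    logrank,
    mann_whitney,
    q3_dichotomize,
)
from ihczone.synthetic import CohortSimParams, simulate_cohort


class TestQ3Dichotomize:
    def test_one_to_eight(self):
        res = q3_dichotomize(np.arange(1, 9))
        assert res.threshold == pytest.approx(6.25)
        assert list(np.flatnonzero(res.high)) == [6, 7]  # values 7 and 8

    def test_all_equal_is_degenerate_all_high(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = q3_dichotomize([3.0] * 6)
        assert res.degenerate
        assert res.high.all()

    def test_permutation_invariance(self, rng):
        values = rng.uniform(0, 10, 20)
        perm = rng.permutation(20)
        a = q3_dichotomize(values)
        b = q3_dichotomize(values[perm])
        assert a.threshold == b.threshold
        assert np.array_equal(a.high[perm], b.high)

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            q3_dichotomize([1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_complete_separation_is_maximal_u(self):
        res = mann_whitney([10, 11, 12, 1, 2, 3, 4],
                           [1, 1, 1, 0, 0, 0, 0])
        assert res.u == 3 * 4

    def test_identical_samples_give_half_maximal_u(self):
        res = mann_whitney([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert res.u == 3 * 3 / 2

    def test_u_matches_pairwise_counting_oracle(self, rng):
        a = rng.integers(0, 8, 5).astype(float)
        b = rng.integers(0, 8, 5).astype(float)
        values = np.concatenate([a, b])
        groups = np.array([1] * 5 + [0] * 5)
        res = mann_whitney(values, groups)
        assert res.u == pytest.approx(oracles.mann_whitney_u_pairs(a, b),
                                      abs=1e-9)

    def test_matches_scipy_asymptotic(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 9)
        values = np.concatenate([a, b])
        groups = np.array([1] * 12 + [0] * 9)
        ours = mann_whitney(values, groups)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert ours.u == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 2, 3], [1, 1, 1])


class TestKruskalWallis:
    def test_identical_values_give_zero_h(self):
        h, p = kruskal_wallis([5.0] * 9, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert h == 0.0
        assert p == 1.0

    def test_two_groups_consistent_with_mann_whitney(self, rng):
        values = rng.normal(0, 1, 16)
        groups = np.array([0] * 8 + [1] * 8)
        _, p_kw = kruskal_wallis(values, groups)
        p_mw = mann_whitney(values, groups).p_value
        assert p_kw == pytest.approx(p_mw, abs=0.01)

    def test_matches_hand_rank_formula(self, rng):
        values = rng.integers(0, 6, 15).astype(float)
        groups = np.array([0] * 5 + [1] * 5 + [2] * 5)
        h, _ = kruskal_wallis(values, groups)
        assert h == pytest.approx(oracles.kruskal_h(values, groups), abs=1e-9)
        href, _ = sps.kruskal(values[:5], values[5:10], values[10:])
        assert h == pytest.approx(href, abs=1e-9)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], [0, 0, 0])


class TestKaplanMeier:
    def test_uncensored_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        for t, want in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert km.survival_at(t) == pytest.approx(want)
        assert km.survival_at(0.5) == 1.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.survival_at(10) == 1.0

    def test_mixed_data_matches_hand_product_limit(self):
        times = [1, 1, 2, 3, 3, 4, 5, 6, 6, 7]
        events = [1, 0, 1, 1, 1, 0, 1, 0, 1, 0]
        km = km_estimate(times, events)
        steps = oracles.km_hand(times, events)
        for t in np.linspace(0, 8, 33):
            assert km.survival_at(t) == pytest.approx(
                oracles.km_survival_at(steps, t), abs=1e-9)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        stat, p = logrank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_tabulation(self, rng):
        times = rng.exponential(2.0, 20)
        events = rng.random(20) < 0.8
        groups = rng.random(20) < 0.5
        if not (groups.any() and (~groups).any() and events.any()):
            pytest.skip("degenerate draw")
        stat, _ = logrank(times, events, groups)
        assert stat == pytest.approx(
            oracles.logrank_hand(times, events, groups), abs=1e-9)

    def test_symmetric_under_label_swap(self, rng):
        times = rng.exponential(2.0, 30)
        events = rng.random(30) < 0.7
        groups = rng.random(30) < 0.4
        s1, p1 = logrank(times, events, groups)
        s2, p2 = logrank(times, events, ~groups)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])


def _binary_cohort_frame(n, hr, seed, p_exposed=0.5, baseline=0.3):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < p_exposed).astype(int)
    lam = baseline * hr**x
    t = rng.exponential(1 / lam)
    return pd.DataFrame({"time": t, "event": np.ones(n, dtype=int), "x": x})


class TestCoxBackward:
    def test_single_covariate_recovers_hazard_ratio(self):
        df = _binary_cohort_frame(500, hr=3.0, seed=5)
        res = cox_backward(df, "time", "event", ["x"], alpha_stay=0.1)
        assert res.table.loc["x", "ExpB"] == pytest.approx(3.0, rel=0.15)

    def test_expb_and_ci_are_transforms_of_b(self):
        df = _binary_cohort_frame(200, hr=2.0, seed=6)
        res = cox_backward(df, "time", "event", ["x"])
        b = res.table.loc["x", "B"]
        se = res.table.loc["x", "SE"]
        assert res.table.loc["x", "ExpB"] == pytest.approx(np.exp(b), rel=1e-12)
        assert res.table.loc["x", "ci_lower"] == pytest.approx(
            np.exp(b - 1.96 * se), rel=1e-12)
        assert res.table.loc["x", "ci_upper"] == pytest.approx(
            np.exp(b + 1.96 * se), rel=1e-12)
        assert res.table.loc["x", "Wald"] == pytest.approx((b / se) ** 2)

    def test_duplicating_subjects_preserves_b(self):
        # duplication creates tied event times, so under Efron tie handling
        # B is preserved only up to the (small) tie correction
        df = _binary_cohort_frame(150, hr=2.5, seed=7)
        doubled = pd.concat([df, df], ignore_index=True)
        b1 = cox_backward(df, "time", "event", ["x"]).table.loc["x", "B"]
        res2 = cox_backward(doubled, "time", "event", ["x"])
        assert res2.table.loc["x", "B"] == pytest.approx(b1, rel=0.01)
        assert res2.table.loc["x", "SE"] < \
            cox_backward(df, "time", "event", ["x"]).table.loc["x", "SE"]

    def test_pure_noise_covariate_is_usually_eliminated(self):
        rng = np.random.default_rng(8)
        eliminated = 0
        reps = 200
        for i in range(reps):
            df = _binary_cohort_frame(120, hr=3.0, seed=1000 + i)
            df["noise"] = (rng.random(len(df)) < 0.5).astype(int)
            res = cox_backward(df, "time", "event", ["x", "noise"],
                               alpha_stay=0.1)
            if "noise" not in res.table.index:
                eliminated += 1
        assert eliminated >= 0.85 * reps

    def test_elimination_trace_records_dropped_terms(self):
        rng = np.random.default_rng(9)
        df = _binary_cohort_frame(400, hr=3.0, seed=10)
        df["noise"] = (rng.random(len(df)) < 0.5).astype(int)
        res = cox_backward(df, "time", "event", ["x", "noise"],
                           alpha_stay=0.05)
        if "noise" not in res.table.index:
            assert any(name == "noise" for _, name, _ in res.trace)
        assert "backward Wald" in res.summary()

    def test_no_events_raises(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError, match="no events"):
            CoxBackwardModel(df, "time", "event", ["x"])


class TestKmLogrank:
    def test_five_year_rates_reported_per_group(self):
        params = CohortSimParams(n_cases=200, hr_terr_vn=3.0, seed=21,
                                 censoring_rate=0.1)
        records = simulate_cohort(params)
        df = pd.DataFrame([r.as_row() for r in records])
        high = q3_high = df["terr_vn_sa"] >= df["terr_vn_sa"].quantile(0.75)
        fit = km_logrank(df["efs_time"], df["efs_event"], high)
        hi, lo = fit.five_year_rates
        assert 0.0 <= hi <= 1.0 and 0.0 <= lo <= 1.0
        assert hi < lo  # high territorial staining fares worse
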