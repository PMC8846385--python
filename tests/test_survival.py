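import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter

from m6apattern.data_model import SurvivalOutcome
from m6apattern.survival import (
    cox_fit,
    cox_fit_univariate_many,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    two_group_logrank_z,
)


def outcome(time, event):
    return SurvivalOutcome([f"S{i}" for i in range(len(time))],
                           np.asarray(time, float), np.asarray(event, int))


class TestKaplanMeier:
    def test_hand_computed_fixture(self):
        km = km_estimate(outcome([1, 2, 3], [1, 0, 1]))
        assert km.survival_at(0.5) == 1.0
        assert km.survival_at(1.5) == pytest.approx(2 / 3, abs=1e-12)
        assert km.survival_at(2.5) == pytest.approx(2 / 3, abs=1e-12)  # censor: no step
        assert km.survival_at(3.0) == pytest.approx(0.0, abs=1e-12)

    def test_all_censored_flat_curve(self):
        km = km_estimate(outcome([5, 2, 9], [0, 0, 0]))
        np.testing.assert_array_equal(km.survival, 1.0)

    def test_duplicating_subjects_leaves_curve_unchanged(self):
        t, e = [1, 4, 6, 8], [1, 1, 0, 1]
        km1 = km_estimate(outcome(t, e))
        km2 = km_estimate(outcome(t + t, e + e))
        np.testing.assert_allclose(km1.survival, km2.survival, atol=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 40)
        km = km_estimate(outcome(t, np.ones(40)))
        for ti in km.time:
            assert km.survival_at(ti) == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        e[0] = 1
        km = km_estimate(outcome(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ours = [km.survival_at(ti) for ti in km.time]
        ref = kmf.survival_function_at_times(km.time).to_numpy()
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(outcome([], []))


def logrank_oracle(time, event, group):
    """Brute-force O-E and hypergeometric variance over the event grid."""
    o_minus_e, var = 0.0, 0.0
    for ti in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        at = np.asarray(time) >= ti
        n, n1 = at.sum(), (at & group).sum()
        d = int(((np.asarray(time) == ti) & (np.asarray(event) == 1)).sum())
        d1 = int(((np.asarray(time) == ti) & (np.asarray(event) == 1) & group).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e, var


class TestLogrank:
    # printed 6-subject two-group fixture
    TIME = [2.0, 4.0, 5.0, 7.0, 9.0, 12.0]
    EVENT = [1, 1, 0, 1, 1, 0]
    GROUP = ["a", "b", "a", "b", "a", "b"]

    def test_two_group_statistic_matches_oracle(self):
        out = outcome(self.TIME, self.EVENT)
        grp = np.array([g == "a" for g in self.GROUP])
        ome, var = logrank_oracle(out.time, out.event, grp)
        z = two_group_logrank_z(out.time, out.event, grp)
        assert z == pytest.approx(ome / np.sqrt(var), abs=1e-12)
        chi2, df, p = logrank_test(out, self.GROUP)
        assert df == 1
        assert chi2 == pytest.approx(z**2, abs=1e-10)

    def test_identical_groups_null(self):
        out = outcome([1, 2, 3, 1, 2, 3], [1, 0, 1, 1, 0, 1])
        chi2, df, p = logrank_test(out, ["a", "a", "a", "b", "b", "b"])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_group_swap_invariance(self):
        out = outcome(self.TIME, self.EVENT)
        grp = np.array([g == "a" for g in self.GROUP])
        assert two_group_logrank_z(out.time, out.event, grp) == pytest.approx(
            -two_group_logrank_z(out.time, out.event, ~grp), abs=1e-12)

    def test_three_groups_df(self):
        out = outcome([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])
        _, df, _ = logrank_test(out, ["a", "a", "b", "b", "c", "c"])
        assert df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(outcome([1, 2], [1, 1]), ["a", "a"])


class TestCox:
    def test_recovers_planted_beta(self):
        rng = np.random.default_rng(7)
        n = 500
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.01 * np.exp(0.7 * x)))
        res = cox_fit(outcome(t, np.ones(n)), pd.DataFrame({"x": x}))
        row = res["x"]
        assert abs(row["beta"] - 0.7) < 3 * row["se"]
        assert row["ci_low"] < row["hr"] < row["ci_high"]
        assert row["hr"] == pytest.approx(np.exp(row["beta"]), rel=1e-10)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(outcome([1, 2, 3], [1, 1, 0]), pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(outcome([1, 2, 3], [0, 0, 0]), pd.DataFrame({"x": [1.0, 2.0, 3.0]}))

    def test_univariate_many_matches_lifelines(self):
        rng = np.random.default_rng(8)
        n = 120
        X = pd.DataFrame(rng.normal(0, 1, (4, n)), index=list("abcd"),
                         columns=[f"S{i}" for i in range(n)])
        t = rng.exponential(1.0 / (0.02 * np.exp(0.5 * X.loc["a"].to_numpy())))
        e = (rng.random(n) < 0.8).astype(int)
        e[:5] = 1
        out = outcome(t, e)
        many = cox_fit_univariate_many(out, X)
        for g in X.index:
            cph = CoxPHFitter().fit(
                pd.DataFrame({"x": X.loc[g].to_numpy(), "t": t, "e": e}),
                duration_col="t", event_col="e", fit_options={"precision": 1e-12})
            assert many.loc[g, "beta"] == pytest.approx(cph.summary["coef"]["x"], abs=1e-6)
            assert many.loc[g, "se"] == pytest.approx(cph.summary["se(coef)"]["x"], abs=1e-6)

    def test_univariate_many_with_ties_matches_lifelines_efron(self):
        rng = np.random.default_rng(9)
        n = 60
        x = rng.normal(0, 1, n)
        t = np.ceil(rng.exponential(1.0 / (0.05 * np.exp(0.6 * x))))  # heavy ties
        e = (rng.random(n) < 0.85).astype(int)
        out = outcome(t, e)
        many = cox_fit_univariate_many(out, pd.DataFrame([x], index=["g"]))
        cph = CoxPHFitter().fit(pd.DataFrame({"x": x, "t": t, "e": e}),
                                duration_col="t", event_col="e",
                                fit_options={"precision": 1e-12})
        assert many.loc["g", "beta"] == pytest.approx(cph.summary["coef"]["x"], abs=1e-5)

    def test_null_calibration_vectorized(self):
        rng = np.random.default_rng(10)
        n = 200
        X = pd.DataFrame(rng.normal(0, 1, (100, n)),
                         index=[f"g{i}" for i in range(100)],
                         columns=[f"S{i}" for i in range(n)])
        t = rng.exponential(100, n)
        out = outcome(t, np.ones(n))
        many = cox_fit_univariate_many(out, X)
        assert (many["z"].abs() < 1.96).mean() >= 0.93

    def test_constant_feature_flagged_not_raised(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame([[1.0] * 30, rng.normal(0, 1, 30)], index=["flat", "ok"])
        X.columns = [f"S{i}" for i in range(30)]
        out = outcome(rng.exponential(10, 30), np.ones(30))
        many = cox_fit_univariate_many(out, X)
        assert many.loc["flat", "flag"] == "constant"
        assert np.isnan(many.loc["flat", "beta"])
        assert many.loc["ok", "flag"] == ""


class TestOptimalCutpoint:
    def test_exhaustive_scan_matches_per_candidate_oracle(self):
        rng = np.random.default_rng(12)
        n = 40
        score = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)])
        t = rng.exponential(1.0 / (0.05 * np.exp(0.8 * (score.to_numpy() > 0))))
        out = SurvivalOutcome(list(score.index), t, np.ones(n, int))
        res = optimal_cutpoint(score, out, minprop=0.1)
        best_abs = 0.0
        best_cut = None
        for c in res.scan["cutpoint"]:
            z = two_group_logrank_z(out.time, out.event, score.to_numpy() > c)
            row = res.scan[res.scan["cutpoint"] == c].iloc[0]
            assert row["statistic"] == pytest.approx(z, abs=1e-12)
            if abs(z) > best_abs:
                best_abs, best_cut = abs(z), c
        assert res.cutpoint == pytest.approx(best_cut, abs=1e-12)
        assert abs(res.statistic) == pytest.approx(best_abs, abs=1e-12)

    def test_perfect_separation_geometry(self):
        # high scorers die early, low scorers censored late
        score = pd.Series([5.0, 6.0, 7.0, -1.0, -2.0, -3.0, 0.5, 0.6, -0.5, 0.7],
                          index=[f"S{i}" for i in range(10)])
        time = np.where(score.to_numpy() > 2, 1.0 + score.to_numpy() / 10, 100.0)
        event = (score.to_numpy() > 2).astype(int)
        out = SurvivalOutcome(list(score.index), time, event)
        res = optimal_cutpoint(score, out, minprop=0.1)
        assert 0.7 <= res.cutpoint < 5.0

    def test_constant_score_rejected(self):
        out = outcome([1, 2, 3, 4], [1, 1, 1, 0])
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(pd.Series([2.0, 2.0, 2.0, 2.0], index=out.sample_ids), out)

    def test_cutpoint_within_minprop_window(self):
        rng = np.random.default_rng(13)
        n = 100
        score = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)])
        out = SurvivalOutcome(list(score.index), rng.exponential(10, n), np.ones(n, int))
        res = optimal_cutpoint(score, out, minprop=0.2)
        lo, hi = score.quantile([0.2, 0.8])
        assert lo <= res.cutpoint <= hi
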