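import itertools

import numpy as np
import pandas as pd
import pytest

from m6apattern.data_model import ExpressionMatrix, SurvivalOutcome, default_regulator_catalog
from m6apattern.scoring import (
    SignatureModel,
    associate_score,
    build_signature,
    m6a_score,
    regulator_network,
    stratify,
)


def make_cohort(n=120, n_genes=40, beta=0.0, seed=0, prognostic=()):
    """Expression + exponential survival; ``prognostic`` genes drive hazard."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:02d}" for i in range(n_genes)]
    vals = pd.DataFrame(rng.normal(8, 1, (n_genes, n)), index=genes,
                        columns=[f"S{i}" for i in range(n)])
    risk = np.zeros(n)
    for g in prognostic:
        risk += beta * (vals.loc[g].to_numpy() - 8.0)
    t = rng.exponential(1.0 / (0.01 * np.exp(risk)))
    out = SurvivalOutcome(list(vals.columns), t, np.ones(n, int))
    return ExpressionMatrix(vals), out


class TestBuildSignature:
    def test_threshold_saturation_keeps_all_degs(self):
        X, out = make_cohort()
        genes = list(X.values.index[:10])
        model = build_signature(X, genes, out, cox_p_threshold=1.0)
        assert sorted(model.genes) == sorted(genes)

    def test_planted_prognostic_genes_recovered(self):
        planted = [f"G{i:02d}" for i in range(20)]
        X, out = make_cohort(n=400, n_genes=220, beta=0.5, seed=4, prognostic=planted)
        model = build_signature(X, list(X.values.index), out)
        kept = set(model.genes)
        assert len(kept & set(planted)) >= 16          # >= 80% of planted
        nulls = set(X.values.index) - set(planted)
        assert len(kept & nulls) <= 0.10 * len(nulls)  # <= 10% of nulls

    def test_rank_one_matrix_degenerates_pc2(self):
        n = 30
        base = np.linspace(-1, 1, n)
        vals = pd.DataFrame({f"S{i}": base[i] * np.array([1.0, 2.0, -1.0]) for i in range(n)},
                            index=["A", "B", "C"])
        X = ExpressionMatrix(vals)
        out = SurvivalOutcome(list(vals.columns),
                              np.random.default_rng(0).exponential(10, n), np.ones(n, int))
        with pytest.warns(UserWarning, match="rank 1"):
            model = build_signature(X, ["A", "B", "C"], out, cox_p_threshold=1.0)
        assert model.degenerate_pc2
        assert model.variance_explained[0] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_array_equal(model.pc2, 0.0)

    def test_too_few_survivors_raises(self):
        X, out = make_cohort()
        with pytest.raises(ValueError, match="no signature genes"):
            build_signature(X, list(X.values.index[:5]), out, cox_p_threshold=1e-12)

    def test_bitwise_rerun_stability(self):
        X, out = make_cohort(seed=7)
        m1 = build_signature(X, list(X.values.index), out, cox_p_threshold=0.5)
        m2 = build_signature(X, list(X.values.index), out, cox_p_threshold=0.5)
        np.testing.assert_array_equal(m1.pc1, m2.pc1)
        np.testing.assert_array_equal(m1.pc2, m2.pc2)
        s1 = m6a_score(m1, X).scores
        s2 = m6a_score(m2, X).scores
        np.testing.assert_array_equal(s1.to_numpy(), s2.to_numpy())


class TestM6aScore:
    def hand_model(self):
        return SignatureModel(
            genes=["A", "B"], means=np.array([0.0, 0.0]), sds=np.array([1.0, 1.0]),
            pc1=np.array([1.0, 0.0]), pc2=np.array([0.0, 1.0]),
            variance_explained=(0.6, 0.4))

    def test_hand_projection(self):
        vals = pd.DataFrame({"S1": [1.5, -0.5], "S2": [0.0, 0.0]}, index=["A", "B"])
        scores = m6a_score(self.hand_model(), ExpressionMatrix(vals))
        assert scores.scores["S1"] == pytest.approx(1.0, abs=1e-12)

    def test_sample_at_training_mean_scores_zero(self):
        vals = pd.DataFrame({"S1": [0.0, 0.0], "S2": [2.0, 3.0]}, index=["A", "B"])
        scores = m6a_score(self.hand_model(), ExpressionMatrix(vals))
        assert scores.scores["S1"] == pytest.approx(0.0, abs=1e-12)

    def test_training_cohort_mean_zero(self):
        X, out = make_cohort(seed=3)
        model = build_signature(X, list(X.values.index), out, cox_p_threshold=0.8)
        scores = m6a_score(model, X)
        assert scores.scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_appending_genes(self):
        X, out = make_cohort(seed=5)
        model = build_signature(X, list(X.values.index[:15]), out, cox_p_threshold=1.0)
        base = m6a_score(model, X).scores
        extra = X.values.copy()
        extra.loc["NEWGENE"] = 99.0
        extra.loc["NEWGENE2"] = np.arange(extra.shape[1], dtype=float)
        widened = m6a_score(model, ExpressionMatrix(extra)).scores
        np.testing.assert_allclose(base.to_numpy(), widened.to_numpy(), rtol=0, atol=1e-12)

    def test_missing_genes_listed(self):
        vals = pd.DataFrame({"S1": [1.0, 2.0], "S2": [0.0, 1.0]}, index=["A", "X"])
        with pytest.raises(KeyError, match="B"):
            m6a_score(self.hand_model(), ExpressionMatrix(vals))


class TestStratify:
    def test_planted_score_effect_separates_survival(self):
        rng = np.random.default_rng(17)
        n = 400
        score = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)])
        t = rng.exponential(1.0 / (0.005 * np.exp(-0.8 * score.to_numpy())))
        out = SurvivalOutcome(list(score.index), t, np.ones(n, int))
        from m6apattern.scoring import ScoreTable
        grouped, summary = stratify(ScoreTable(score), out)
        assert summary["logrank_p"] < 0.01
        assert summary["median_survival_high"] > summary["median_survival_low"]
        # samples exactly at the cutpoint belong to "low"
        at_cut = grouped.scores == summary["cutpoint"]
        assert (grouped.groups[at_cut] == "low").all()

    def test_toy_obvious_split(self):
        score = pd.Series([10.0, 11.0, -10.0, -11.0], index=list("abcd"))
        out = SurvivalOutcome(list("abcd"), np.array([1.0, 2.0, 50.0, 60.0]),
                              np.array([1, 1, 1, 1]))
        from m6apattern.scoring import ScoreTable
        grouped, _ = stratify(ScoreTable(score), out, minprop=0.25)
        assert set(grouped.groups[["a", "b"]]) == {"high"}
        assert set(grouped.groups[["c", "d"]]) == {"low"}

    def test_null_score_selection_optimism_is_bounded(self):
        """Maximal selection inflates the naive log-rank rejection rate; the
        permutation p controls it."""
        naive = perm = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 120
            score = pd.Series(rng.normal(0, 1, n), index=[f"S{i}" for i in range(n)])
            t = rng.exponential(50, n)
            out = SurvivalOutcome(list(score.index), t, np.ones(n, int))
            from m6apattern.scoring import ScoreTable
            _, summary = stratify(ScoreTable(score), out, n_permutations=99, rng=rng)
            naive += summary["logrank_p"] < 0.05
            perm += summary["permutation_p"] < 0.05
        assert naive / n_seeds <= 0.5   # optimism present but not total
        assert perm / n_seeds <= 0.125  # permutation-corrected near nominal


class TestRegulatorNetwork:
    def _cohort(self, seed=0, protective=None, beta=-0.6, n=400):
        rng = np.random.default_rng(seed)
        cat = default_regulator_catalog()
        vals = pd.DataFrame(rng.normal(8, 1, (23, n)), index=cat.symbols,
                            columns=[f"S{i}" for i in range(n)])
        risk = np.zeros(n)
        if protective:
            risk = beta * (vals.loc[protective].to_numpy() - 8.0)
        t = rng.exponential(1.0 / (0.01 * np.exp(risk)))
        out = SurvivalOutcome(list(vals.columns), t, np.ones(n, int))
        return ExpressionMatrix(vals), out

    def test_duplicated_regulator_pair_correlation_one(self):
        X, out = self._cohort(seed=1)
        X.values.loc["FTO"] = X.values.loc["ALKBH5"]
        pairs, _ = regulator_network(X, out)
        row = pairs[(pairs["gene_a"].isin(["FTO", "ALKBH5"])) &
                    (pairs["gene_b"].isin(["FTO", "ALKBH5"]))]
        assert row["correlation"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_planted_protective_regulator_classified_favorable(self):
        hits = 0
        for seed in range(20):
            X, out = self._cohort(seed=seed, protective="HNRNPC")
            _, per_reg = regulator_network(X, out)
            hits += per_reg.loc["HNRNPC", "prognostic_class"] == "favorable"
        assert hits >= 18

    def test_null_pair_flag_rate_near_alpha(self):
        rates = []
        for seed in range(3):
            X, out = self._cohort(seed=100 + seed)
            pairs, _ = regulator_network(X, out)
            rates.append((pairs["p"] < 0.05).mean())
        assert 0.01 <= np.mean(rates) <= 0.09

    def test_absent_regulator_dropped_with_warning(self):
        X, out = self._cohort(seed=2)
        X2 = ExpressionMatrix(X.values.drop(index=["FTO"]))
        with pytest.warns(UserWarning, match="FTO"):
            pairs, per_reg = regulator_network(X2, out)
        assert "FTO" not in per_reg.index


class TestAssociateScore:
    def test_kruskal_toy_exact_and_permutation_oracle(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=list("abcdef"))
        groups = pd.Series(["g1", "g1", "g2", "g2", "g3", "g3"], index=list("abcdef"))
        h, p = associate_score(scores, groups, kind="kruskal")
        # hand rank formula: H = 12/(6*7) * (2*2^2 + 0 + 2*2^2) = 32/7
        assert h == pytest.approx(32 / 7, abs=1e-12)
        # exhaustive permutation of group assignments: 32/7 is the maximum,
        # attained only by the arrangements splitting ranks (12|34|56)
        def kw_h(ranks_by_group):
            n = 6
            return 12 / (n * (n + 1)) * sum(
                len(r) * (np.mean(r) - (n + 1) / 2) ** 2 for r in ranks_by_group)
        count_ge = 0
        total = 0
        ranks = [1, 2, 3, 4, 5, 6]
        for perm in itertools.permutations(ranks):
            g = [perm[:2], perm[2:4], perm[4:]]
            total += 1
            if kw_h(g) >= 32 / 7 - 1e-12:
                count_ge += 1
        assert count_ge / total == pytest.approx(6 / 90, abs=1e-12)

    def test_kruskal_exchangeable_groups_null(self):
        scores = pd.Series([1.0, 2.0, 3.0] * 3, index=[f"s{i}" for i in range(9)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=scores.index)
        h, p = associate_score(scores, groups, kind="kruskal")
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_spearman_perfect_monotone(self):
        s = pd.Series([0.1, 0.5, 1.2, 3.0], index=list("abcd"))
        rho, _ = associate_score(s, pd.Series([1, 4, 9, 100], index=list("abcd")),
                                 kind="spearman")
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_wilcoxon_needs_two_groups(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            associate_score(s, pd.Series(["x", "y", "z"], index=list("abc")),
                            kind="wilcoxon")

    def test_anova_runs(self):
        s = pd.Series(np.arange(9, dtype=float), index=[f"s{i}" for i in range(9)])
        g = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=s.index)
        f, p = associate_score(s, g, kind="anova")
        assert f > 0 and 0 < p < 1

    def test_covariate_must_cover_samples(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="cover"):
            associate_score(s, pd.Series({"a": 1.0}), kind="spearman")
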