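"""The m6A gene signature and per-sample m6Ascore.

The signature is built by univariate-Cox filtering of the cluster-overlap
DEGs (keep prognostic genes at p < 0.05), z-scoring the survivors, and PCA
by SVD; the m6Ascore of a sample is its projection onto principal component
1 plus its projection onto principal component 2 — the GGI-style reading of
the sum-over-signature-genes construction, since each projection is itself
the sum over signature genes i of loading_i x standardized expression_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionMatrix, RegulatorCatalog, SurvivalOutcome, default_regulator_catalog
from . import survival as surv

__all__ = [
    "SignatureModel",
    "ScoreTable",
    "build_signature",
    "m6a_score",
    "stratify",
    "regulator_network",
    "associate_score",
]


@dataclass
class SignatureModel:
    """Prognostic-gene PCA model behind the m6Ascore."""

    genes: list[str]
    means: np.ndarray                  # per-gene centering mean (training)
    sds: np.ndarray                    # per-gene scaling sd (training, ddof=0)
    pc1: np.ndarray                    # unit-norm loading vector
    pc2: np.ndarray                    # unit-norm, or zeros when rank-deficient
    variance_explained: tuple[float, float]
    training_cohort: str = "training"
    degenerate_pc2: bool = False
    cox_table: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class ScoreTable:
    """Per-sample m6Ascore with optional high/low grouping."""

    scores: pd.Series
    cutpoint: float | None = None
    groups: pd.Series | None = None    # "high" (score > cutpoint) / "low"

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(float)).all():
            raise ValueError("non-finite m6Ascores")
        if (self.groups is None) != (self.cutpoint is None):
            raise ValueError("groups present iff cutpoint set")


def _orient_sign(v: np.ndarray, genes: list[str]) -> np.ndarray:
    """Deterministic SVD sign: sum of loadings >= 0; tie -> first gene's loading >= 0."""
    s = v.sum()
    if s < 0:
        return -v
    if s == 0:
        order = sorted(range(len(genes)), key=lambda i: genes[i])
        if v[order[0]] < 0:
            return -v
    return v


def build_signature(X: ExpressionMatrix, overlap_degs: list[str], outcome: SurvivalOutcome,
                    cox_p_threshold: float = 0.05, *, training_cohort: str = "training") -> SignatureModel:
    """Univariate-Cox filter the overlap DEGs, then PCA (SVD) on the survivors.

    Genes are z-scored (population sd) before the SVD so the PCA acts on the
    correlation structure; component signs are oriented deterministically.
    """
    sub = X.restrict(overlap_degs, missing="warn")
    out_aligned = outcome.subset(sub.sample_ids)
    cox = surv.cox_fit_univariate_many(out_aligned, sub.values)
    keep = cox.index[(cox["p"] < cox_p_threshold) & (cox["flag"] == "")]
    if len(keep) < 2:
        raise ValueError("no signature genes: fewer than 2 overlap DEGs pass the Cox filter")
    vals = sub.values.loc[keep]
    means = vals.mean(axis=1).to_numpy()
    sds = vals.std(axis=1, ddof=0).to_numpy()
    if (sds == 0).any():
        raise ValueError("constant signature gene cannot be z-scored")
    z = ((vals.to_numpy() - means[:, None]) / sds[:, None]).T  # samples x genes
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    genes = list(keep)
    total_var = float((s**2).sum())
    ve1 = float(s[0] ** 2 / total_var) if total_var > 0 else 0.0
    pc1 = _orient_sign(vt[0], genes)
    tol = s[0] * max(z.shape) * np.finfo(float).eps
    degenerate = bool(len(s) < 2 or s[1] <= tol)
    if degenerate:
        pc2 = np.zeros_like(pc1)
        ve2 = 0.0
        warnings.warn("training matrix has effective rank 1: PC2 degenerate (zero loadings)")
    else:
        pc2 = _orient_sign(vt[1], genes)
        ve2 = float(s[1] ** 2 / total_var)
    return SignatureModel(genes, means, sds, pc1, pc2, (ve1, ve2),
                          training_cohort=training_cohort, degenerate_pc2=degenerate,
                          cox_table=cox)


def m6a_score(model: SignatureModel, X: ExpressionMatrix) -> ScoreTable:
    """Per-sample m6Ascore = PC1 projection + PC2 projection.

    All signature genes must be present in ``X`` (missing genes raise,
    listing them); values are centered/scaled with the stored training
    statistics, so scoring the training cohort gives mean 0.
    """
    missing = [g for g in model.genes if g not in X.values.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    vals = X.values.loc[model.genes].to_numpy(float)
    z = (vals - model.means[:, None]) / model.sds[:, None]
    score = z.T @ model.pc1 + z.T @ model.pc2
    return ScoreTable(pd.Series(score, index=X.values.columns, name="m6Ascore"))


def stratify(scores: ScoreTable, outcome: SurvivalOutcome, minprop: float = 0.1,
             *, n_permutations: int = 0, rng=None) -> tuple[ScoreTable, dict]:
    """Split samples at the survival-optimal cutpoint and summarize both arms.

    Returns the grouped ScoreTable plus a summary dict with the cutpoint,
    per-group KM curves and the high-vs-low log-rank test.
    """
    aligned = outcome.subset(list(scores.scores.index))
    cut = surv.optimal_cutpoint(scores.scores, aligned, minprop=minprop,
                                n_permutations=n_permutations, rng=rng)
    groups = pd.Series(np.where(scores.scores > cut.cutpoint, "high", "low"),
                       index=scores.scores.index, name="group")
    grouped = ScoreTable(scores.scores, cutpoint=cut.cutpoint, groups=groups)
    km = {}
    for g in ("high", "low"):
        ids = list(groups.index[groups == g])
        km[g] = surv.km_estimate(aligned.subset(ids))
    chi2, df, p = surv.logrank_test(aligned, groups.to_numpy())
    summary = {
        "cutpoint": cut.cutpoint,
        "cutpoint_statistic": cut.statistic,
        "permutation_p": cut.permutation_p,
        "km": km,
        "logrank_chi2": chi2,
        "logrank_p": p,
        "n_high": int((groups == "high").sum()),
        "n_low": int((groups == "low").sum()),
        "median_survival_high": km["high"].median(),
        "median_survival_low": km["low"].median(),
    }
    return grouped, summary


def regulator_network(X: ExpressionMatrix, outcome: SurvivalOutcome,
                      catalog: RegulatorCatalog | None = None,
                      *, method: str = "spearman", p_threshold: float = 0.05
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise regulator correlations plus per-regulator prognostic class.

    Returns (pairs table, per-regulator table).  Class is "favorable"
    (HR < 1, p < threshold), "risk" (HR > 1, p < threshold), else "ns".
    """
    catalog = catalog or default_regulator_catalog()
    sub = X.restrict(catalog.symbols, missing="warn")
    if sub.n_samples < 3:
        raise ValueError("regulator network needs >=3 samples")
    arr = sub.values.to_numpy(float)
    genes = sub.gene_ids
    if method == "spearman":
        corr, pmat = stats.spearmanr(arr, axis=1)
        corr = np.atleast_2d(corr)
        pmat = np.atleast_2d(pmat)
    elif method == "pearson":
        n = len(genes)
        corr = np.corrcoef(arr)
        tstat = corr * np.sqrt((sub.n_samples - 2) / np.clip(1 - corr**2, 1e-300, None))
        pmat = 2 * stats.t.sf(np.abs(tstat), sub.n_samples - 2)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            rows.append((genes[i], genes[j], float(corr[i, j]), float(pmat[i, j])))
    pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation", "p"])
    cox = surv.cox_fit_univariate_many(outcome.subset(sub.sample_ids), sub.values)
    cls = np.where((cox["p"] < p_threshold) & (cox["hr"] < 1), "favorable",
                   np.where((cox["p"] < p_threshold) & (cox["hr"] > 1), "risk", "ns"))
    per_reg = cox.assign(
        role=[catalog.entries.get(g, "?") for g in cox.index],
        prognostic_class=cls,
    )
    return pairs, per_reg


def associate_score(scores: ScoreTable | pd.Series, covariate, kind: str = "kruskal"
                    ) -> tuple[float, float]:
    """Association between the m6Ascore and a grouping/continuous covariate.

    kinds: ``kruskal`` / ``anova`` (3+ groups), ``wilcoxon`` (two-group
    rank-sum), ``spearman`` (continuous).  Returns (statistic, two-sided p).
    """
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores)
    cov = pd.Series(list(covariate), index=s.index) if not isinstance(covariate, pd.Series) else covariate
    cov = cov.reindex(s.index)
    if cov.isna().any():
        raise ValueError("covariate does not cover all scored samples")
    if kind == "spearman":
        rho, p = stats.spearmanr(s.to_numpy(float), cov.to_numpy(float))
        return float(rho), float(p)
    groups = [s[cov == g].to_numpy(float) for g in sorted(cov.unique(), key=str)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise ValueError("need >=2 non-empty groups")
    if kind == "kruskal":
        stat, p = stats.kruskal(*groups)
    elif kind == "anova":
        stat, p = stats.f_oneway(*groups)
    elif kind == "wilcoxon":
        if len(groups) != 2:
            raise ValueError("wilcoxon rank-sum needs exactly 2 groups")
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown association kind {kind!r}")
    return float(stat), float(p)
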