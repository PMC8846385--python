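"""Single-sample gene-set enrichment for TME cell abundance and pathway activity.

Two statistics are provided: the ssGSEA rank-weighted running sum (score =
sum of the running-sum deviations along the ranked gene list) and a
GSVA-like variant built on cross-sample ECDF ranks with a max-deviation
score.  Over-representation of DEG lists uses the one-sided hypergeometric
tail with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, GeneSetCollection, canonical_symbol
from .diffexp import moderated_t_fit

__all__ = [
    "EnrichmentMatrix",
    "ssgsea_scores",
    "gsva_like_scores",
    "pathway_differential",
    "ora_enrich",
]


@dataclass
class EnrichmentMatrix:
    """Gene sets x samples matrix of continuous enrichment scores."""

    scores: pd.DataFrame
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(float)).all():
            raise ValueError("non-finite enrichment scores")

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)


def _sample_es_ssgsea(order: np.ndarray, rank_weight: np.ndarray, in_set: np.ndarray,
                      alpha: float) -> float:
    """ssGSEA enrichment score for one sample and one set.

    ``order`` walks genes by descending expression; in-set steps rise by
    rank_weight^alpha (normalized to total 1), out-of-set steps fall
    uniformly.  The score is the sum of the running-sum deviations.
    """
    in_walk = in_set[order]
    w = rank_weight[order] ** alpha
    w = np.where(in_walk, w, 0.0)
    wsum = w.sum()
    n_out = (~in_walk).sum()
    p_in = np.cumsum(w) / wsum
    p_out = np.cumsum(~in_walk) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_scores(X: ExpressionMatrix, sets: GeneSetCollection, alpha: float = 0.25,
                  normalize: bool = True, min_size: int = 2) -> EnrichmentMatrix:
    """ssGSEA enrichment scores, one per (gene set, sample).

    Genes are ranked per sample by descending expression with average ranks
    for ties; in-set running-sum increments are proportional to rank^alpha.
    With ``normalize`` all scores are divided by (max - min) over the whole
    matrix (the originating method's default).  Sets with fewer than
    ``min_size`` members present are dropped with a warning.
    """
    if len(sets) == 0:
        raise ValueError("no gene sets supplied")
    kept = sets.restricted_to(X.values.index, min_size=min_size)
    arr = X.values.to_numpy(float)
    genes = X.values.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes, n_samples = arr.shape
    out = np.empty((len(kept.sets), n_samples))
    for j in range(n_samples):
        col = arr[:, j]
        # descending rank value: highest expression -> rank n_genes (ties averaged)
        rank_weight = stats.rankdata(col, method="average")
        order = np.argsort(-col, kind="mergesort")
        for i, (name, members) in enumerate(kept.sets.items()):
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[[gene_pos[g] for g in members]] = True
            out[i, j] = _sample_es_ssgsea(order, rank_weight, in_set, alpha)
    if normalize:
        spread = out.max() - out.min()
        if spread > 0:
            out = out / spread
    scores = pd.DataFrame(out, index=list(kept.sets), columns=X.values.columns)
    return EnrichmentMatrix(scores, "ssgsea",
                            {"alpha": alpha, "normalize": normalize, "min_size": min_size})


def gsva_like_scores(X: ExpressionMatrix, sets: GeneSetCollection, tau: float = 1.0,
                     min_size: int = 2) -> EnrichmentMatrix:
    """GSVA-like enrichment via cross-sample ECDF ranks.

    Each gene's expression is first transformed to its ECDF rank across
    samples (average ranks for ties), centered so high-in-this-sample genes
    get large positive values; per sample a KS-like running statistic is
    walked over genes ordered by decreasing transformed value, with in-set
    increments proportional to |z|^tau; the score is the maximum positive
    deviation plus the minimum negative deviation (max-deviation variant).
    """
    if X.n_samples < 3:
        raise ValueError("GSVA-like scoring needs >=3 samples for the ECDF")
    kept = sets.restricted_to(X.values.index, min_size=min_size)
    arr = X.values.to_numpy(float)
    n_genes, n_samples = arr.shape
    # ECDF rank across samples, centered to (-0.5, 0.5)
    r = np.apply_along_axis(stats.rankdata, 1, arr) / n_samples - 0.5 * (1 + 1 / n_samples)
    genes = X.values.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    out = np.empty((len(kept.sets), n_samples))
    for j in range(n_samples):
        z = r[:, j]
        order = np.argsort(-z, kind="mergesort")
        zw = np.abs(z) ** tau
        for i, (name, members) in enumerate(kept.sets.items()):
            in_set = np.zeros(n_genes, dtype=bool)
            in_set[[gene_pos[g] for g in members]] = True
            in_walk = in_set[order]
            w = np.where(in_walk, zw[order], 0.0)
            wsum = w.sum()
            if wsum == 0:  # all members at exact ECDF center: flat walk
                out[i, j] = 0.0
                continue
            running = np.cumsum(w) / wsum - np.cumsum(~in_walk) / max((~in_walk).sum(), 1)
            out[i, j] = float(max(running.max(), 0.0) + min(running.min(), 0.0))
    scores = pd.DataFrame(out, index=list(kept.sets), columns=X.values.columns)
    return EnrichmentMatrix(scores, "gsva_like", {"tau": tau, "min_size": min_size})


def pathway_differential(E: EnrichmentMatrix, labels, contrast: tuple[str, str]) -> pd.DataFrame:
    """Moderated-t comparison of enrichment scores between two clusters.

    Returns one row per gene set: score difference, moderated t, p, BH FDR
    and an activated/inhibited direction column (relative to the first
    member of ``contrast``).
    """
    labels = pd.Series(list(labels), index=E.scores.columns)
    a, b = contrast
    keep = labels.isin([a, b])
    if (labels == a).sum() < 2 or (labels == b).sum() < 2:
        raise ValueError(f"contrast {contrast}: each group needs >=2 samples")
    sub = E.scores.loc[:, keep.to_numpy()]
    sub_labels = labels[keep]
    deg = moderated_t_fit(sub, sub_labels, contrast="pairwise")
    name = f"{min(a, b)}_vs_{max(a, b)}"
    t = deg.contrast(name).set_index("gene")
    sign = 1.0 if name.startswith(str(a)) else -1.0
    out = pd.DataFrame({
        "set": t.index,
        "score_diff": sign * t["logfc"].to_numpy(),
        "t": sign * t["t"].to_numpy(),
        "p": t["p"].to_numpy(),
        "fdr": t["fdr"].to_numpy(),
    })
    out["direction"] = np.where(out["score_diff"] > 0, "activated", "inhibited")
    return out.sort_values("p", ignore_index=True)


def ora_enrich(query_genes: list[str], sets: GeneSetCollection,
               universe: list[str]) -> pd.DataFrame:
    """Over-representation analysis: one-sided hypergeometric tail per set.

    Query genes outside the universe are dropped with a warning; results are
    sorted by ascending p with BH FDR attached.
    """
    uni = list(dict.fromkeys(canonical_symbol(g) for g in universe))
    if not uni:
        raise ValueError("empty universe")
    query = list(dict.fromkeys(canonical_symbol(g) for g in query_genes))
    if not query:
        raise ValueError("empty query")
    uni_set = set(uni)
    dropped = [g for g in query if g not in uni_set]
    if dropped:
        warnings.warn(f"{len(dropped)} query genes outside the universe dropped: {dropped[:5]}")
    query = [g for g in query if g in uni_set]
    if not query:
        raise ValueError("no query genes inside the universe")
    M, N = len(uni), len(query)
    rows = []
    qset = set(query)
    for name, members in sets.sets.items():
        m = [g for g in dict.fromkeys(canonical_symbol(x) for x in members) if g in uni_set]
        k = len(qset & set(m))
        # P[X >= k], X ~ Hypergeom(M, |set|, N)
        p = float(stats.hypergeom.sf(k - 1, M, len(m), N))
        rows.append((name, k, len(m), p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "set"], ignore_index=True)
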