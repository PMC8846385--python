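"""Moderated-t differential expression between m6A clusters.

Gene-wise residual variances are shrunk toward an empirical-Bayes prior
(Smyth-style): the prior degrees of freedom d0 and prior variance s0^2 are
estimated by moment matching of log s^2 using digamma/trigamma inversion,
the posterior variance is (d0*s0^2 + d*s^2)/(d0 + d), and the moderated t
is referred to a t distribution with d0 + d degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix

__all__ = ["DEGTable", "moderated_t_fit", "select_degs", "overlap_degs", "squeeze_variances"]


@dataclass
class DEGTable:
    """Per-gene differential-expression statistics for a set of contrasts."""

    table: pd.DataFrame  # columns: contrast, gene, logfc, ave_expr, t, p, fdr
    d0: float            # prior degrees of freedom (inf = full shrinkage)
    s0_sq: float         # prior variance

    def contrast(self, name: str) -> pd.DataFrame:
        return self.table[self.table["contrast"] == name]

    @property
    def contrasts(self) -> list[str]:
        return list(dict.fromkeys(self.table["contrast"]))


def _trigamma_inverse(y: np.ndarray | float, tol: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (Smyth's scheme)."""
    y = np.atleast_1d(np.asarray(y, float))
    x = 0.5 + 1.0 / y  # good starting value for all y > 0
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - dif
        if np.max(np.abs(dif / x)) < tol:
            break
    return x


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Estimate (d0, s0_sq) from gene variances and return posterior variances.

    Moment matching on z = log(s^2): E[z] and Var[z] under the scaled-F model
    identify the prior via digamma/trigamma; Var[z] at or below the sampling
    variance trigamma(df/2) means no excess dispersion -> d0 = inf (complete
    shrinkage to s0_sq).
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("prior variance inestimable: fewer than 2 positive gene variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    else:
        d0 = float(2.0 * _trigamma_inverse(excess)[0])
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return d0, s0_sq, post


def _contrast_pairs(labels: pd.Series, scheme: str) -> list[tuple[str, np.ndarray, np.ndarray]]:
    levels = sorted(labels.unique())
    out = []
    if scheme == "one_vs_rest":
        for lv in levels:
            out.append((f"{lv}_vs_rest", (labels == lv).to_numpy(), (labels != lv).to_numpy()))
    elif scheme == "pairwise":
        for a, b in combinations(levels, 2):
            out.append((f"{a}_vs_{b}", (labels == a).to_numpy(), (labels == b).to_numpy()))
    else:
        raise ValueError(f"unknown contrast scheme {scheme!r}")
    return out


def moderated_t_fit(X: ExpressionMatrix | pd.DataFrame, labels,
                    contrast: str = "one_vs_rest", *, d0_override: float | None = None) -> DEGTable:
    """Fit moderated two-group t-statistics for every gene and contrast.

    ``contrast`` is ``one_vs_rest`` (one contrast per cluster) or
    ``pairwise``.  ``d0_override`` forces the prior degrees of freedom (0 =
    ordinary t, inf = complete shrinkage); otherwise the prior is estimated
    from the data.  BH FDR is computed within each contrast.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else X
    arr = values.to_numpy(float)
    genes = values.index
    labels = pd.Series(list(labels), index=values.columns)
    rows = []
    d0_global, s0_global = np.nan, np.nan
    for name, g1, g2 in _contrast_pairs(labels, contrast):
        n1, n2 = int(g1.sum()), int(g2.sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(f"contrast {name}: each side needs >=2 samples (got {n1} vs {n2})")
        m1 = arr[:, g1].mean(axis=1)
        m2 = arr[:, g2].mean(axis=1)
        logfc = m1 - m2
        ave = arr.mean(axis=1)
        ss1 = ((arr[:, g1] - m1[:, None]) ** 2).sum(axis=1)
        ss2 = ((arr[:, g2] - m2[:, None]) ** 2).sum(axis=1)
        df_resid = n1 + n2 - 2
        s2 = (ss1 + ss2) / df_resid
        c = np.sqrt(1.0 / n1 + 1.0 / n2)
        if d0_override is not None:
            d0 = float(d0_override)
            if d0 == 0:
                post = s2.copy()
                s0 = np.nan
            elif np.isinf(d0):
                _, s0, _ = squeeze_variances(s2, df_resid)
                post = np.full_like(s2, s0)
            else:
                d0e, s0, _ = squeeze_variances(s2, df_resid)
                s0 = s0 if np.isfinite(s0) else float(np.median(s2))
                post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        else:
            if len(genes) < 10:
                warnings.warn("fewer than 10 genes: prior df inestimable, "
                              "falling back to ordinary t")
                d0, s0, post = 0.0, np.nan, s2.copy()
            else:
                try:
                    d0, s0, post = squeeze_variances(s2, df_resid)
                except ValueError:
                    warnings.warn("prior estimation failed, falling back to ordinary t")
                    d0, s0, post = 0.0, np.nan, s2.copy()
        if (post <= 0).any():
            raise ValueError("all-zero-variance genes: prior inestimable")
        t = logfc / (np.sqrt(post) * c)
        df_total = df_resid + (d0 if np.isfinite(d0) else 0.0)
        if np.isfinite(d0):
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        rows.append(pd.DataFrame({
            "contrast": name, "gene": genes, "logfc": logfc, "ave_expr": ave,
            "t": t, "p": p, "fdr": fdr,
        }))
        d0_global, s0_global = d0, s0
    return DEGTable(pd.concat(rows, ignore_index=True), d0=d0_global, s0_sq=s0_global)


def select_degs(deg: DEGTable, lfc_threshold: float = 1.0, p_threshold: float = 0.05,
                use_adjusted: bool = False, contrast: str | None = None) -> list[str]:
    """Genes with |logFC| > lfc_threshold AND p < p_threshold (strict).

    Ordered by descending |t|.  ``contrast=None`` uses the whole table.
    """
    if lfc_threshold < 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    t = deg.table if contrast is None else deg.contrast(contrast)
    pcol = "fdr" if use_adjusted else "p"
    hit = t[(t["logfc"].abs() > lfc_threshold) & (t[pcol] < p_threshold)]
    hit = hit.reindex(hit["t"].abs().sort_values(ascending=False).index)
    return list(dict.fromkeys(hit["gene"]))


def overlap_degs(gene_lists: dict[str, list[str]]) -> tuple[list[str], dict[str, int]]:
    """Intersection of per-contrast DEG lists plus all Venn region counts.

    The returned region dict maps membership patterns like ``"A&B"`` (sorted
    list names joined by '&') to the number of genes exactly in those lists.
    """
    if len(gene_lists) < 2:
        raise ValueError("overlap needs >=2 DEG lists")
    names = sorted(gene_lists)
    sets = {n: set(gene_lists[n]) for n in names}
    union = set().union(*sets.values())
    regions: dict[str, int] = {}
    for g in union:
        key = "&".join(n for n in names if g in sets[n])
        regions[key] = regions.get(key, 0) + 1
    core = set.intersection(*sets.values())
    ordered = [g for g in dict.fromkeys(g for n in names for g in gene_lists[n]) if g in core]
    return ordered, regions
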