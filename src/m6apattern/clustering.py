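"""Resampling-based consensus clustering of samples (Monti-style).

For each candidate k the samples are repeatedly subsampled without
replacement, an inner clustering is run on each resample, and the consensus
matrix entry (i, j) is the number of times i and j co-clustered divided by
the number of times they were co-sampled.  k is selected by PAC (proportion
of ambiguous clustering) or the Monti delta-area criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .data_model import ExpressionMatrix

__all__ = ["ConsensusResult", "consensus_cluster", "select_k", "cluster_labels"]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels and k-selection diagnostics."""

    sample_ids: list[str]
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]          # values in 1..k, renumbered by size
    pac: dict[int, float]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    reps: int
    subsample_fraction: float
    inner_algorithm: str
    seed: int | None = None
    dendrogram_order: dict[int, np.ndarray] = field(default_factory=dict)


def _pearson_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; zero-variance rows -> distance 1."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def _inner_cluster(data: np.ndarray, k: int, algorithm: str,
                   rng: np.random.Generator) -> np.ndarray:
    """Cluster rows of ``data`` into k groups; returns labels 0..k-1."""
    n = data.shape[0]
    if k >= n:
        return np.arange(n)
    if algorithm == "hclust_pearson":
        d = _pearson_distance(data)
        z = linkage(squareform(d, checks=False), method="average")
        return fcluster(z, t=k, criterion="maxclust") - 1
    if algorithm == "kmeans":
        zd = (data - data.mean(axis=0)) / np.where(data.std(axis=0) == 0, 1, data.std(axis=0))
        km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31 - 1)))
        return km.fit_predict(zd)
    raise ValueError(f"unknown inner algorithm {algorithm!r}")


def _renumber_by_size(labels: np.ndarray, sample_ids: list[str]) -> np.ndarray:
    """Renumber labels 1..k by descending cluster size, ties by first member id."""
    groups: dict[int, list[str]] = {}
    for lab, sid in zip(labels, sample_ids):
        groups.setdefault(int(lab), []).append(sid)
    order = sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels])


def _cdf_area_and_pac(M: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> tuple[float, float]:
    iu = np.triu_indices_from(M, k=1)
    vals = np.sort(M[iu])
    n = len(vals)
    if n == 0:
        return 0.0, 0.0
    # area under the empirical CDF over [0, 1]
    cdf_at = lambda x: np.searchsorted(vals, x, side="right") / n
    grid = np.concatenate(([0.0], vals, [1.0]))
    heights = np.array([cdf_at(x) for x in grid[:-1]])
    area = float(np.sum(heights * np.diff(grid)))
    pac = float(cdf_at(upper) - cdf_at(lower))
    return area, pac


def consensus_cluster(X: ExpressionMatrix, features: list[str] | None = None,
                      k_range=range(2, 7), reps: int = 1000,
                      subsample_fraction: float = 0.8, seed: int | None = None,
                      inner_algorithm: str = "hclust_pearson",
                      select_method: str = "delta_area",
                      return_assignments: bool = False):
    """Consensus-cluster the samples of ``X`` on the given feature genes.

    Items are samples; features are never subsampled.  Final per-k labels
    come from average-linkage clustering of (1 - consensus) as a distance,
    renumbered by descending cluster size.  Fully deterministic given
    ``seed``.  ``return_assignments`` additionally returns every rep's
    (sampled indices, labels) for oracle checking.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if features is not None:
        X = X.restrict(features)
    if X.n_genes < 2:
        raise ValueError("consensus clustering needs >=2 features")
    data = X.values.to_numpy(float).T  # samples x features
    n = data.shape[0]
    if max(k_range) > n:
        raise ValueError(f"k={max(k_range)} > n_samples={n}")
    if reps < 1 or not 0 < subsample_fraction <= 1:
        raise ValueError("reps must be >=1 and subsample_fraction in (0, 1]")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_fraction * n)))
    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in k_range}
    assignments = {k: [] for k in k_range} if return_assignments else None
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1.0
        sub = data[idx]
        for k in k_range:
            labs = _inner_cluster(sub, k, inner_algorithm, rng)
            same = labs[:, None] == labs[None, :]
            co_clustered[k][np.ix_(idx, idx)] += same
            if return_assignments:
                assignments[k].append((idx.copy(), labs.copy()))
    never = co_sampled == 0
    if never[np.triu_indices(n, k=1)].any():
        warnings.warn("some sample pairs were never co-sampled; their consensus is set to 0")
    consensus, labels, pac, area, dorder = {}, {}, {}, {}, {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(never, 0.0, co_clustered[k] / np.where(never, 1.0, co_sampled))
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        d = 1.0 - M
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        raw = fcluster(z, t=min(k, n), criterion="maxclust")
        labels[k] = _renumber_by_size(raw, X.sample_ids)
        area[k], pac[k] = _cdf_area_and_pac(M)
        dorder[k] = leaves_list(z)
    delta = {}
    ks = k_range
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else area[k]
    result = ConsensusResult(
        sample_ids=X.sample_ids, k_range=list(k_range), consensus=consensus,
        labels=labels, pac=pac, cdf_area=area, delta_area=delta,
        chosen_k=0, reps=reps, subsample_fraction=subsample_fraction,
        inner_algorithm=inner_algorithm, seed=seed, dendrogram_order=dorder,
    )
    result.chosen_k = select_k(result, method=select_method)
    if return_assignments:
        return result, assignments
    return result


def select_k(result: ConsensusResult, method: str = "delta_area") -> int:
    """Choose k: argmin PAC (ties -> smallest k) or the Monti delta-area elbow."""
    ks = result.k_range
    if len(ks) == 1:
        return ks[0]
    if method == "pac":
        best = min(ks, key=lambda k: (round(result.pac[k], 12), k))
        return best
    if method == "delta_area":
        # elbow: largest k whose relative area increase still exceeds 10%
        chosen = ks[0]
        for k in ks[1:]:
            if result.delta_area[k] > 0.1:
                chosen = k
            else:
                break
        return chosen
    raise ValueError(f"unknown k-selection method {method!r}")


def cluster_labels(result: ConsensusResult, k: int | None = None) -> pd.Series:
    """Per-sample labels for the given k (default chosen_k), named by sample id."""
    k = result.chosen_k if k is None else int(k)
    if k not in result.labels:
        raise KeyError(f"k={k} not in computed range {result.k_range}")
    return pd.Series(result.labels[k], index=result.sample_ids, name=f"cluster_k{k}")
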