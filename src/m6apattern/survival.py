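"""Survival statistics: Kaplan-Meier, log-rank, Cox regression, optimal cutpoint.

The maximally selected cutpoint (survminer-style) scans every distinct
marker value inside the minprop quantile window and maximizes the absolute
standardized two-group log-rank statistic.  Multivariate Cox fitting is
delegated to lifelines (Efron ties); the univariate many-gene mode uses an
in-package vectorized Newton solver so thousands of genes can be screened in
one call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import ConvergenceWarning
from scipy import stats

from .data_model import SurvivalOutcome

__all__ = [
    "KMCurve",
    "CoxResult",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "two_group_logrank_z",
    "cox_fit",
    "cox_fit_univariate_many",
    "optimal_cutpoint",
]


@dataclass
class KMCurve:
    """Product-limit survival estimate on the observed event-time grid."""

    time: np.ndarray          # distinct observed times (events and censorings)
    survival: np.ndarray      # S(t) just after each time
    at_risk: np.ndarray       # risk-set size just before each time
    n_events: np.ndarray      # events at each time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.time[below[0]]) if len(below) else float("inf")


def km_estimate(outcome: SurvivalOutcome) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored times reduce the risk set without introducing a step.
    """
    if len(outcome) == 0:
        raise ValueError("empty survival outcome")
    t = outcome.time
    e = outcome.event
    grid = np.unique(t)
    at_risk = np.empty(len(grid), dtype=int)
    n_events = np.empty(len(grid), dtype=int)
    surv = np.empty(len(grid))
    s = 1.0
    for i, ti in enumerate(grid):
        at_risk[i] = int((t >= ti).sum())
        n_events[i] = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - n_events[i] / at_risk[i]
        surv[i] = s
    return KMCurve(grid, surv, at_risk, n_events)


def logrank_test(outcome: SurvivalOutcome, group_labels) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi-square statistic, df, p)."""
    groups = pd.Series(list(group_labels))
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("log-rank test needs >=2 groups")
    if (sizes == 0).any():
        raise ValueError("log-rank test: empty group")
    if len(groups) != len(outcome):
        raise ValueError("group labels do not match outcome length")
    res = multivariate_logrank_test(outcome.time, groups.to_numpy(), outcome.event)
    return float(res.test_statistic), len(sizes) - 1, float(res.p_value)


def two_group_logrank_z(time: np.ndarray, event: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized two-group log-rank statistic z = (O - E) / sqrt(V).

    O, E and the hypergeometric variance V are accumulated over the pooled
    event-time grid for the ``in_group`` arm.  Returns 0 when V is 0 (no
    events, or one arm empty at every event time).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    in_group = np.asarray(in_group, bool)
    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        at_risk = time >= ti
        n = at_risk.sum()
        n1 = (at_risk & in_group).sum()
        d = int(((time == ti) & (event == 1)).sum())
        d1 = int(((time == ti) & (event == 1) & in_group).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e / np.sqrt(var))


@dataclass
class CoxResult:
    """Cox proportional-hazards fit summary (per-covariate rows)."""

    table: pd.DataFrame  # index covariate; columns beta, hr, se, z, p, ci_low, ci_high
    converged: bool = True
    iterations: int = 0
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, covariate: str) -> pd.Series:
        return self.table.loc[covariate]


def cox_fit(outcome: SurvivalOutcome, covariates: pd.DataFrame, *, ties: str = "efron") -> CoxResult:
    """Cox partial-likelihood fit (Newton-Raphson, Efron ties by default).

    Non-convergence / monotone likelihood is flagged on the result, not raised.
    """
    if outcome.event.sum() == 0:
        raise ValueError("no events: Cox model unidentifiable")
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if not np.isfinite(cov.to_numpy(float)).all():
        raise ValueError("non-finite covariate values")
    for col in cov.columns:
        if cov[col].nunique() < 2:
            raise ValueError(f"constant covariate {col!r}")
    df = cov.copy()
    df["_time"] = outcome.time
    df["_event"] = outcome.event
    cph = CoxPHFitter()
    flags: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # monotone likelihood / separation
            return CoxResult(
                pd.DataFrame(
                    np.nan, index=cov.columns,
                    columns=["beta", "hr", "se", "z", "p", "ci_low", "ci_high"],
                ),
                converged=False, flags=[f"fit failed: {exc}"],
            )
        for w in caught:
            if issubclass(w.category, ConvergenceWarning):
                converged = False
                flags.append(str(w.message))
    s = cph.summary
    table = pd.DataFrame({
        "beta": s["coef"],
        "hr": s["exp(coef)"],
        "se": s["se(coef)"],
        "z": s["z"],
        "p": s["p"],
        "ci_low": np.exp(s["coef lower 95%"]),
        "ci_high": np.exp(s["coef upper 95%"]),
    })
    table.index.name = "covariate"
    return CoxResult(table, converged=converged, flags=flags)


def _efron_negloglik_grad_hess(beta: np.ndarray, x: np.ndarray, order_groups, tie_blocks):
    """Log partial likelihood with Efron ties, vectorized across columns of x.

    ``x`` is (n_samples, n_features) with each feature an independent
    univariate model; returns per-feature (loglik, gradient, hessian).
    """
    n, p = x.shape
    eta = x * beta  # (n, p) univariate linear predictor per feature
    w = np.exp(eta)
    wx = w * x
    wxx = w * x * x
    # cumulative risk sums from latest time to earliest
    loglik = np.zeros(p)
    grad = np.zeros(p)
    hess = np.zeros(p)
    S0 = np.zeros(p)
    S1 = np.zeros(p)
    S2 = np.zeros(p)
    for block, death_idx in zip(order_groups, tie_blocks):
        S0 += w[block].sum(axis=0)
        S1 += wx[block].sum(axis=0)
        S2 += wxx[block].sum(axis=0)
        d = len(death_idx)
        if d == 0:
            continue
        T0 = w[death_idx].sum(axis=0)
        T1 = wx[death_idx].sum(axis=0)
        T2 = wxx[death_idx].sum(axis=0)
        loglik += eta[death_idx].sum(axis=0)
        for ell in range(d):
            f = ell / d
            a0 = S0 - f * T0
            a1 = S1 - f * T1
            a2 = S2 - f * T2
            loglik -= np.log(a0)
            grad_term = a1 / a0
            grad -= grad_term
            hess -= a2 / a0 - grad_term**2
        grad += x[death_idx].sum(axis=0)
    return loglik, grad, hess


def cox_fit_univariate_many(outcome: SurvivalOutcome, X: pd.DataFrame,
                            *, max_iter: int = 50, tol: float = 1e-9) -> pd.DataFrame:
    """Univariate Cox screen of many features at once (Efron ties).

    ``X`` is features x samples (one independent univariate Cox model per
    row).  Returns a DataFrame indexed by feature with beta, hr, se, z, p.
    Constant features get NaN with a flag column; non-convergent features are
    flagged, never raised.
    """
    if outcome.event.sum() == 0:
        raise ValueError("no events: Cox screen unidentifiable")
    feat = X.index
    x_all = X.to_numpy(float).T  # (n_samples, n_features)
    n = x_all.shape[0]
    if n != len(outcome):
        raise ValueError("feature matrix and outcome sample counts differ")
    sd = x_all.std(axis=0, ddof=0)
    usable = sd > 0
    # center for numerical stability (partial likelihood is shift-invariant)
    x = x_all[:, usable] - x_all[:, usable].mean(axis=0)
    order = np.argsort(-outcome.time, kind="mergesort")
    t_sorted = outcome.time[order]
    e_sorted = outcome.event[order]
    # group sample indices by distinct time, processed from latest to earliest
    order_groups, tie_blocks = [], []
    i = 0
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        block = order[i:j]
        order_groups.append(block)
        tie_blocks.append(block[e_sorted[i:j] == 1])
        i = j
    p_feat = x.shape[1]
    beta = np.zeros(p_feat)
    prev_ll = np.full(p_feat, -np.inf)
    active = np.ones(p_feat, bool)
    hess = np.full(p_feat, np.nan)
    iters = 0
    for iters in range(1, max_iter + 1):
        ll, grad, hess = _efron_negloglik_grad_hess(beta, x, order_groups, tie_blocks)
        step = np.where(hess < 0, grad / np.clip(-hess, 1e-12, None), 0.0)
        step = np.clip(step, -2.0, 2.0)  # damp monotone-likelihood blowup
        done = np.abs(ll - prev_ll) < tol
        active &= ~done
        if not active.any():
            break
        beta = beta + np.where(active, step, 0.0)
        prev_ll = ll
    se = np.sqrt(1.0 / np.clip(-hess, 1e-12, None))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    out = pd.DataFrame(
        np.nan, index=feat, columns=["beta", "hr", "se", "z", "p"], dtype=float
    )
    out.loc[feat[usable], "beta"] = beta
    out.loc[feat[usable], "hr"] = np.exp(beta)
    out.loc[feat[usable], "se"] = se
    out.loc[feat[usable], "z"] = z
    out.loc[feat[usable], "p"] = pvals
    out["flag"] = np.where(usable, "", "constant")
    out.loc[feat[usable][~np.isfinite(beta) | (np.abs(beta) >= 99)], "flag"] = "non-convergent"
    return out


def _scan_logrank_z(time: np.ndarray, event: np.ndarray, vals: np.ndarray,
                    candidates: np.ndarray) -> np.ndarray:
    """Standardized two-group log-rank z for every candidate cut at once.

    Same statistic as :func:`two_group_logrank_z` with group = vals > cut,
    computed via event-time x candidate matrices.
    """
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return np.zeros(candidates.size)
    at_risk = time[None, :] >= event_times[:, None]              # (m, n)
    deaths = (time[None, :] == event_times[:, None]) & (event[None, :] == 1)
    grp = vals[:, None] > candidates[None, :]                    # (n, C)
    n_tot = at_risk.sum(axis=1).astype(float)                    # (m,)
    d_tot = deaths.sum(axis=1).astype(float)
    n1 = at_risk.astype(float) @ grp                             # (m, C)
    d1 = deaths.astype(float) @ grp
    frac = n1 / n_tot[:, None]
    o_minus_e = (d1 - d_tot[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = d_tot * (n_tot - d_tot) / np.maximum(n_tot - 1.0, 1.0)
    var = (vterm[:, None] * frac * (1.0 - frac)).sum(axis=0)
    z = np.zeros(candidates.size)
    ok = var > 0
    z[ok] = o_minus_e[ok] / np.sqrt(var[ok])
    return z


@dataclass
class CutpointResult:
    """Maximally selected log-rank cutpoint on a continuous marker."""

    cutpoint: float
    statistic: float            # standardized log-rank z at the cutpoint
    scan: pd.DataFrame          # candidate -> statistic
    minprop: float
    permutation_p: float | None = None


def optimal_cutpoint(score: pd.Series, outcome: SurvivalOutcome, minprop: float = 0.1,
                     *, n_permutations: int = 0, rng: np.random.Generator | None = None) -> CutpointResult:
    """Scan candidate cutpoints, maximizing |standardized log-rank statistic|.

    Candidates are the distinct score values inside the
    [minprop, 1-minprop] quantile window; "high" means score strictly greater
    than the cutpoint.  Ties in |z| resolve to the smaller cutpoint.  An
    optional permutation p-value (score permuted against outcome) accounts
    for the multiple looks of the scan.
    """
    score = pd.Series(score)
    vals = score.to_numpy(float)
    if np.unique(vals).size < 2:
        raise ValueError("constant score: no cutpoint exists")
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must be in (0, 0.5)")
    lo, hi = np.quantile(vals, [minprop, 1.0 - minprop])
    candidates = np.unique(vals)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    # a candidate equal to the max leaves the "high" side empty
    candidates = candidates[candidates < vals.max()]
    if candidates.size == 0:
        raise ValueError("no admissible cutpoint inside the minprop window")

    def scan_stats(v: np.ndarray) -> np.ndarray:
        return _scan_logrank_z(outcome.time, outcome.event, v, candidates)

    zs = scan_stats(vals)
    best = int(np.lexsort((candidates, -np.abs(zs)))[0])
    scan = pd.DataFrame({"cutpoint": candidates, "statistic": zs})
    perm_p = None
    if n_permutations > 0:
        rng = np.random.default_rng() if rng is None else rng
        observed = abs(zs[best])
        hits = 0
        for _ in range(n_permutations):
            zperm = scan_stats(rng.permutation(vals))
            if np.max(np.abs(zperm)) >= observed:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)
    return CutpointResult(float(candidates[best]), float(zs[best]), scan, minprop, perm_p)
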