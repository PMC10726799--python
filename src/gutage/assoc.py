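"""Association statistics used throughout the analyses.

Spearman correlation (average ranks), age-adjusted partial Spearman via the
precision matrix of rank correlations, Benjamini-Hochberg FDR, and the
nonparametric group tests (Wilcoxon rank-sum, Kruskal-Wallis, Fisher exact).

P-values for Spearman's rho use the t approximation with n-2 degrees of
freedom for n >= 10 and exact permutation enumeration below that.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman",
    "partial_spearman",
    "bh_fdr",
    "group_tests",
]

_EXACT_N = 10  # below this, Spearman p by exhaustive permutation


def _check_pair(x, y, min_n=4):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined rank correlation")
    return x, y


def _rank_pearson(rx, ry):
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _t_pvalue(rho: float, df: int) -> float:
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def spearman(x, y) -> tuple[float, float]:
    """Average-rank Spearman rho with two-sided p-value.

    Exact permutation p for n < 10, t approximation otherwise.
    """
    x, y = _check_pair(x, y)
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_pearson(rx, ry)
    if n < _EXACT_N:
        perms = np.array(list(permutations(ry)))
        cx = rx - rx.mean()
        cp = perms - perms.mean(axis=1, keepdims=True)
        num = cp @ cx
        den = np.sqrt((cp * cp).sum(axis=1) * (cx @ cx))
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = _t_pvalue(rho, n - 2)
    return rho, p


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Rank partial correlation of x and y given covariates.

    Computed from the precision matrix of the Spearman correlation matrix of
    (x, y, covariates); p from the t statistic on n-2-k df. With an empty
    covariate list this is exactly :func:`spearman`. A covariate collinear
    with x or y is guarded via the pseudo-inverse; an outright singular
    system (e.g. duplicated covariates) raises ValueError.
    """
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return spearman(x, y)
    x, y = _check_pair(x, y)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] == len(x) and Z.shape[1] != len(x):
        Z = Z.T  # accept columns-as-covariates
    k = Z.shape[0]
    n = len(x)
    if n <= k + 3:
        raise ValueError("too few observations for the number of covariates")
    ranks = np.vstack(
        [stats.rankdata(x), stats.rankdata(y)] + [stats.rankdata(z) for z in Z]
    )
    C = np.corrcoef(ranks)
    if not np.isfinite(C).all():
        raise ValueError("constant covariate has undefined rank correlation")
    # x or y identical (in ranks) to a covariate: the conditional
    # association is zero by definition; guard rather than invert a
    # singular matrix
    if (np.abs(C[:2, 2:]) > 1 - 1e-12).any():
        return 0.0, 1.0
    cond = np.linalg.cond(C)
    if cond > 1e10:
        P = np.linalg.pinv(C, rcond=1e-12)
    else:
        P = np.linalg.inv(C)
    denom = P[0, 0] * P[1, 1]
    if denom <= 0:
        raise ValueError("singular rank-correlation matrix")
    rho = float(-P[0, 1] / np.sqrt(denom))
    rho = min(max(rho, -1.0), 1.0)
    p = _t_pvalue(rho, n - 2 - k)
    return rho, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a nonempty 1-d array")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def group_tests(
    values: Sequence[float] | None,
    groups: Sequence | None = None,
    mode: str = "kruskal-wallis",
    *,
    table: np.ndarray | None = None,
) -> pd.DataFrame:
    """Nonparametric group comparisons.

    ``wilcoxon-pairwise``: two-sided rank-sum (Mann-Whitney) test for every
    pair of groups, exact when sample sizes permit and there are no ties.
    ``kruskal-wallis``: one overall test. ``fisher-exact``: two-sided Fisher
    test on a 2x2 contingency ``table``.
    Returns a long-format DataFrame with one row per comparison.
    """
    if mode == "fisher-exact":
        if table is None:
            raise ValueError("fisher-exact requires a contingency table")
        _, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
        return pd.DataFrame([{"comparison": "2x2", "statistic": np.nan, "p": p}])

    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    by = {lab: v[g == lab] for lab in labels}

    if mode == "kruskal-wallis":
        stat, p = stats.kruskal(*by.values())
        return pd.DataFrame(
            [{"comparison": "overall", "statistic": stat, "p": p}]
        )
    if mode == "wilcoxon-pairwise":
        rows = []
        for a, b in combinations(labels, 2):
            xa, xb = by[a], by[b]
            pooled = np.concatenate([xa, xb])
            no_ties = len(np.unique(pooled)) == len(pooled)
            method = "exact" if (no_ties and max(len(xa), len(xb)) <= 25) else "asymptotic"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            rows.append(
                {"comparison": f"{a} vs {b}", "statistic": res.statistic, "p": res.pvalue}
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown mode {mode!r}")
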