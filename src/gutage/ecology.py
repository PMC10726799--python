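"""Community ecology statistics.

Shannon entropy, Bray-Curtis dissimilarity, intragroup beta-diversity
comparisons, enterotyping (square-root Jensen-Shannon distance + PAM
medoid clustering + Calinski-Harabasz model selection), and PERMANOVA
with an effect-size (R^2) decomposition over covariates.

PERMANOVA follows the Gower-centered distance decomposition: with
G = -1/2 C D^2 C (C the centering matrix) and hat matrix H of the design,
R^2 = tr(HGH)/tr(G) and the pseudo-F is compared against label
permutations; p-values use the add-one convention so they are never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

__all__ = [
    "shannon",
    "bray_curtis",
    "intragroup_beta",
    "enterotype",
    "EnterotypeResult",
    "permanova_r2",
    "effect_size_decomposition",
]


def shannon(profile) -> float:
    """Shannon entropy H' = -sum a_i ln a_i (nats), renormalized internally."""
    a = np.asarray(profile, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero profile has undefined entropy")
    a = a[a > 0] / total
    return float(-(a * np.log(a)).sum())


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    X = matrix.to_numpy(dtype=float).T
    if (X < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = X.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined between two all-zero samples")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.columns, columns=matrix.columns)


def intragroup_beta(dist: pd.DataFrame, groups) -> tuple[dict, pd.DataFrame]:
    """Within-group pairwise distances plus pairwise rank-sum comparisons.

    Groups with a single sample carry no within-group distance and are
    excluded with a warning. Returns ``(per_group_distances, tests)``.
    """
    g = pd.Series(np.asarray(groups), index=dist.index)
    per_group: dict = {}
    for lab, idx in g.groupby(g).groups.items():
        if len(idx) < 2:
            warnings.warn(f"group {lab!r} has a single sample; excluded", stacklevel=2)
            continue
        sub = dist.loc[idx, idx].to_numpy()
        per_group[lab] = sub[np.triu_indices(len(idx), k=1)]
    rows = []
    for a, b in combinations(per_group, 2):
        res = mannwhitneyu(per_group[a], per_group[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "p": res.pvalue})
    return per_group, pd.DataFrame(rows)


# ---------------------------------------------------------------- enterotypes


def _pam(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic PAM (BUILD + SWAP) on a precomputed distance matrix.

    Returns the medoid indices. No randomness: BUILD picks greedy cost
    minimizers, ties by lowest index.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        # gain of adding candidate c = total reduction in assignment cost
        gains = np.maximum(current[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1 :])
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
        if not improved:
            break
    return np.asarray(medoids)


def _ch_index(D: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Calinski-Harabasz pseudo-F from squared distances (distance-based SS)."""
    n = len(labels)
    D2 = D**2
    total = D2[np.triu_indices(n, k=1)].sum() / n
    within = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    between = total - within
    if within <= 0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


@dataclass
class EnterotypeResult:
    labels: pd.Series          # cluster id per sample
    k_opt: int
    drivers: dict              # cluster id -> genus with highest mean abundance
    ch_by_k: dict              # Calinski-Harabasz index per candidate k
    medoids: list


def enterotype(genus_matrix: pd.DataFrame, k_range=(2, 3, 4, 5, 6)) -> EnterotypeResult:
    """Cluster samples into enterotypes.

    Distance is the square root of the Jensen-Shannon divergence between
    per-sample genus profiles; clustering is PAM around medoids; the number
    of clusters maximizes the Calinski-Harabasz index over ``k_range``
    (a single-element range skips the index search). The driver taxon of a
    cluster is the genus with the highest mean relative abundance in it.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k must be at least 2")
    P = genus_matrix.to_numpy(dtype=float).T
    if (P < 0).any():
        raise ValueError("abundances must be nonnegative")
    sums = P.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("all-zero sample profile")
    P = P / sums
    n = P.shape[0]
    if n < 3 * max(k_range):
        raise ValueError("need at least 3*max(k) samples")
    D = squareform(pdist(P, metric="jensenshannon"))  # sqrt of JSD, base e
    if np.allclose(D, 0):
        raise ValueError("all profiles identical: no cluster structure")

    ch_by_k, results = {}, {}
    for k in k_range:
        medoids = _pam(D, k)
        labels = np.argmin(D[:, medoids], axis=1)
        results[k] = (medoids, labels)
        if len(k_range) > 1:
            ch_by_k[k] = _ch_index(D, labels, k)
    k_opt = max(ch_by_k, key=ch_by_k.get) if len(k_range) > 1 else k_range[0]
    medoids, labels = results[k_opt]

    drivers = {}
    for c in np.unique(labels):
        mean_prof = P[labels == c].mean(axis=0)
        drivers[int(c)] = genus_matrix.index[int(np.argmax(mean_prof))]
    return EnterotypeResult(
        labels=pd.Series(labels, index=genus_matrix.columns, name="enterotype"),
        k_opt=int(k_opt),
        drivers=drivers,
        ch_by_k=ch_by_k,
        medoids=[int(m) for m in medoids],
    )


# ----------------------------------------------------------------- PERMANOVA


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D**2
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ A @ C


def _design(variable, n: int) -> np.ndarray:
    v = pd.Series(np.asarray(variable))
    if len(v) != n:
        raise ValueError("variable length must match number of samples")
    if v.nunique() <= 1:
        raise ValueError("constant variable has no explanatory power")
    if v.dtype.kind in "fiu":
        X = np.column_stack([np.ones(n), v.to_numpy(dtype=float)])
    else:
        dummies = pd.get_dummies(v, drop_first=True).to_numpy(dtype=float)
        X = np.column_stack([np.ones(n), dummies])
    return X


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _r2_f(G: np.ndarray, H: np.ndarray, m: int) -> tuple[float, float]:
    n = G.shape[0]
    ss_total = np.trace(G)
    ss_model = np.trace(H @ G)
    r2 = ss_model / ss_total
    f = (ss_model / (m - 1)) / ((ss_total - ss_model) / (n - m))
    return float(r2), float(f)


def permanova_r2(
    dist: pd.DataFrame | np.ndarray,
    variable,
    n_perm: int = 999,
    seed: int | None = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Single-variable PERMANOVA: returns (R^2, permutation p-value).

    The variable may be numeric (regression design) or categorical (one-hot).
    Sampled permutations give p = (1 + #{F_perm >= F_obs}) / (1 + n_perm);
    with ``exact=True`` all n! permutations are enumerated (small n only)
    and p = #{F_perm >= F_obs} / n! (the identity permutation always
    counts, so p is never 0).
    """
    D = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    G = _gower_center(D)
    X = _design(variable, n)
    m = np.linalg.matrix_rank(X)
    H = _hat(X)
    r2, f_obs = _r2_f(G, H, m)
    if exact:
        from itertools import permutations as _perms
        from math import factorial
        if factorial(n) > 50_000:
            raise ValueError("exact enumeration is limited to small n")
        exceed = total = 0
        for perm in _perms(range(n)):
            Gp = G[np.ix_(perm, perm)]
            _, f_perm = _r2_f(Gp, H, m)
            total += 1
            if f_perm >= f_obs - 1e-12:
                exceed += 1
        return r2, exceed / total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        _, f_perm = _r2_f(Gp, H, m)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return r2, float(p)


def effect_size_decomposition(
    dist: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    redundancy_r: float = 0.5,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """PERMANOVA effect-size table with significance + redundancy filtering.

    1. Marginal PERMANOVA R^2 and p per covariate; keep p < alpha.
    2. Among kept covariates, greedy pass in descending R^2: drop any
       variable whose |Pearson r| with an already-retained variable exceeds
       ``redundancy_r`` (categoricals compared via integer codes).
    3. Combined R^2 = total-model R^2 of all retained covariates jointly.

    Returns one row per covariate with columns
    (variable, r2, p, kept, redundant_with, combined_r2).
    """
    if covariates.shape[1] < 2:
        raise ValueError("need at least two covariates")
    D = dist.to_numpy(dtype=float)
    G = _gower_center(D)
    n = D.shape[0]

    rows = {}
    name_order = sorted(map(str, covariates.columns))
    for name in covariates.columns:
        # sub-seed keyed to the covariate name so results are invariant to
        # the input column order
        sub = None if seed is None else seed + name_order.index(str(name))
        r2, p = permanova_r2(dist, covariates[name], n_perm=n_perm, seed=sub)
        rows[name] = {"variable": name, "r2": r2, "p": p,
                      "kept": p < alpha, "redundant_with": None}

    kept = sorted((name for name in rows if rows[name]["kept"]),
                  key=lambda v: (-rows[v]["r2"], v))
    numeric = {}
    for name in covariates.columns:
        col = covariates[name]
        numeric[name] = (col.astype("category").cat.codes.to_numpy(dtype=float)
                         if col.dtype.kind not in "fiu" else col.to_numpy(dtype=float))

    retained: list[str] = []
    for v in kept:
        partner = None
        for r in retained:
            r_pear = np.corrcoef(numeric[v], numeric[r])[0, 1]
            if abs(r_pear) > redundancy_r:
                partner = r
                break
        if partner is None:
            retained.append(v)
        else:
            rows[v]["kept"] = False
            rows[v]["redundant_with"] = partner

    if retained:
        X = np.ones((n, 1))
        for v in retained:
            Xv = _design(covariates[v], n)[:, 1:]
            X = np.column_stack([X, Xv])
        H = _hat(X)
        combined = float(np.trace(H @ G) / np.trace(G))
    else:
        combined = 0.0

    out = pd.DataFrame([rows[name] for name in covariates.columns])
    out["combined_r2"] = combined
    return out
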