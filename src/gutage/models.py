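"""Random-forest forward selection with Q2 / leave-one-out cross-validation.

Q2 = 1 - sum((y - yhat)^2) / sum((y - ybar)^2), computed on held-out
predictions; it is bounded above by 1 and may be negative.

Variable selection: a forest on all candidates picks the first variable by
permutation importance (increase in MSE); thereafter each unselected
variable is tried jointly with the selected set and the variable with the
largest LOOCV Q2 is added, stopping when Q2 no longer increases (strict
improvement beyond ``tol``; ties count as no increase), so the Q2
trajectory is strictly increasing by construction.

Forest defaults follow the regression lineage of the classic
implementation: 500 trees, mtry = floor(p/3) features per split.

Also includes the power of the two-sided test of zero correlation via the
Fisher z approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

__all__ = [
    "q2_score",
    "loocv_predict",
    "forward_select_rf",
    "RFSelectionResult",
    "correlation_power",
]


def q2_score(y, yhat) -> float:
    """Predictive coefficient Q2 = 1 - RSS/TSS (TSS about the mean of y)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and yhat must be 1-d arrays of equal length >= 2")
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("constant y has undefined Q2")
    rss = ((y - yhat) ** 2).sum()
    return float(1.0 - rss / tss)


def _forest(n_trees: int, n_features: int, seed: int | None) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, n_features // 3),
        random_state=seed,
        n_jobs=1,
    )


def loocv_predict(
    X: pd.DataFrame,
    y,
    variables: list[str],
    n_trees: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-out forest predictions restricted to ``variables``.

    Each fold trains on all samples but one with a deterministic per-fold
    seed (``seed + fold index``) and predicts the held-out sample.
    """
    if len(variables) < 1:
        raise ValueError("need at least one variable")
    missing = [v for v in variables if v not in X.columns]
    if missing:
        raise ValueError(f"variables not in feature matrix: {missing}")
    Xv = X[list(variables)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples for LOOCV")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        rf = _forest(n_trees, Xv.shape[1], seed + i)
        rf.fit(Xv[mask], y[mask])
        preds[i] = rf.predict(Xv[i : i + 1])[0]
    return preds


@dataclass
class RFSelectionResult:
    selected: list[str]
    q2_trajectory: list[float]
    importances: pd.Series
    final_q2: float = field(init=False)

    def __post_init__(self):
        self.final_q2 = self.q2_trajectory[-1] if self.q2_trajectory else float("nan")

    @property
    def variance_explained_pct(self) -> float:
        """Final LOOCV Q2 expressed as a percentage."""
        return 100.0 * self.final_q2


def forward_select_rf(
    X: pd.DataFrame,
    y,
    n_trees: int = 500,
    seed: int = 0,
    tol: float = 1e-6,
    first_by: str = "importance",
    importance_repeats: int = 10,
    max_vars: int | None = None,
) -> RFSelectionResult:
    """Iterative forward selection of forest predictors driven by LOOCV Q2.

    ``first_by='importance'`` (default) picks the first variable as the one
    with maximal permutation importance (increase in MSE) of a forest on
    all candidates; ``first_by='q2'`` instead screens single-variable
    LOOCV Q2. ``max_vars`` optionally caps the selected-set size (the
    stopping rule still applies first).
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two candidate variables")
    y = np.asarray(y, dtype=float)
    cols = list(X.columns)

    rf = _forest(n_trees, len(cols), seed)
    rf.fit(X.to_numpy(dtype=float), y)
    imp = permutation_importance(
        rf, X.to_numpy(dtype=float), y,
        scoring="neg_mean_squared_error",
        n_repeats=importance_repeats,
        random_state=seed,
    )
    importances = pd.Series(imp.importances_mean, index=cols, name="inc_mse")

    if first_by == "importance":
        first = importances.sort_values(ascending=False).index[0]
    elif first_by == "q2":
        scores = {
            v: q2_score(y, loocv_predict(X, y, [v], n_trees=n_trees, seed=seed))
            for v in cols
        }
        first = max(sorted(scores), key=scores.get)
    else:
        raise ValueError("first_by must be 'importance' or 'q2'")

    selected = [first]
    best_q2 = q2_score(y, loocv_predict(X, y, selected, n_trees=n_trees, seed=seed))
    trajectory = [best_q2]

    while True:
        if max_vars is not None and len(selected) >= max_vars:
            break
        remaining = [v for v in cols if v not in selected]
        if not remaining:
            break
        scores = {
            v: q2_score(
                y, loocv_predict(X, y, selected + [v], n_trees=n_trees, seed=seed)
            )
            for v in remaining
        }
        cand = max(sorted(scores), key=scores.get)
        if scores[cand] > best_q2 + tol:
            selected.append(cand)
            best_q2 = scores[cand]
            trajectory.append(best_q2)
        else:
            break
    return RFSelectionResult(selected=selected, q2_trajectory=trajectory,
                             importances=importances)


def correlation_power(r: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided test of rho = 0 at effect |r| and sample size n.

    Fisher z approximation:
    power = Phi(sqrt(n-3)*atanh|r| - z_{1-a/2}) + Phi(-sqrt(n-3)*atanh|r| - z_{1-a/2}).
    """
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("n must be >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z = np.sqrt(n - 3) * np.arctanh(abs(r))
    zcrit = norm.ppf(1 - alpha / 2)
    return float(norm.cdf(z - zcrit) + norm.cdf(-z - zcrit))
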