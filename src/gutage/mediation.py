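"""Bidirectional mediation analysis with treatment-mediator interaction.

The mediator model is m ~ x (least squares) and the outcome model is
y ~ x + m + x*m. Average causal mediation effect (ACME) and average direct
effect (ADE) are estimated by the quasi-Bayesian simulation approach:
parameter vectors are drawn from the fitted models' asymptotic normal
distributions and potential outcomes are contrasted at a treated versus a
control exposure value. For a continuous exposure the default contrast is
mean versus mean + 1 SD. With an interaction the ACME (and ADE) are
averaged over the two treatment arms; the point estimates then satisfy
total = ACME + ADE exactly.

The *bidirectional screen* runs, for every (microbe, metabolite) pair that
passes a Spearman prefilter, a forward analysis
(x = microbe, m = metabolite, y = age) and an inverse analysis with the
roles of exposure and mediator swapped
(x = metabolite, m = microbe, y = age); a linkage passes iff
p_forward < 0.05 and p_inverse > 0.05.

Why this inverse: in a linear chain microbe -> metabolite -> age, the
residual mediator noise that reaches the outcome makes the
mediator/outcome-swapped analysis (microbe -> age -> metabolite)
stochastically *more* significant than the forward one
(z_inv = z_fwd / sqrt(1 - rho^2) with rho the partial mediator-outcome
correlation), so that swap cannot separate direction at all. Swapping
exposure and mediator instead tests whether the microbe carries any
effect on age beyond the metabolite, which is exactly null for a true
chain with no direct effect and clearly non-null when the true chain runs
microbe -> age -> metabolite. The mediator/outcome swap remains available
via ``inverse_mode="mediator_outcome"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import spearman, bh_fdr

__all__ = ["MediationResult", "mediate_interaction", "bidirectional_screen"]


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    p_mediation: float
    ci: tuple[float, float]
    n_sims: int
    direction: str = "forward"


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares fit; returns (beta, covariance of beta)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov


def _effects(alpha, beta, t, c):
    """ACME/ADE/total from mediator params alpha=(a0,a1) and outcome params
    beta=(b0,bx,bm,bxm), arm-averaged. Vectorized over leading sim axis."""
    a0, a1 = alpha[..., 0], alpha[..., 1]
    bx, bm, bxm = beta[..., 1], beta[..., 2], beta[..., 3]
    dm = a1 * (t - c)
    acme = 0.5 * ((bm + bxm * t) + (bm + bxm * c)) * dm
    ade = 0.5 * ((bx + bxm * (a0 + a1 * c)) + (bx + bxm * (a0 + a1 * t))) * (t - c)
    return acme, ade, acme + ade


def mediate_interaction(
    x,
    m,
    y,
    n_sims: int = 1000,
    seed: int = 0,
    treat_value: float | None = None,
    control_value: float | None = None,
    names: tuple[str, str, str] = ("x", "m", "y"),
    direction: str = "forward",
) -> MediationResult:
    """Quasi-Bayesian mediation with exposure-mediator interaction."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[ok], m[ok], y[ok]
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 complete cases")
    if np.ptp(x) == 0 or np.ptp(m) == 0:
        raise ValueError("constant exposure or mediator")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 0.999:
        raise ValueError("exposure and mediator are collinear (|r| > 0.999)")

    c = float(np.mean(x)) if control_value is None else float(control_value)
    t = c + float(np.std(x, ddof=1)) if treat_value is None else float(treat_value)

    Xm = np.column_stack([np.ones(n), x])
    alpha_hat, cov_a = _ols(Xm, m)
    Xy = np.column_stack([np.ones(n), x, m, x * m])
    beta_hat, cov_b = _ols(Xy, y)

    acme, ade, total = _effects(alpha_hat, beta_hat, t, c)
    prop = acme / total if abs(total) > 1e-12 else np.nan

    rng = np.random.default_rng(seed)
    La = np.linalg.cholesky(cov_a + 1e-14 * np.eye(2))
    Lb = np.linalg.cholesky(cov_b + 1e-14 * np.eye(4))
    alpha_sims = alpha_hat + rng.standard_normal((n_sims, 2)) @ La.T
    beta_sims = beta_hat + rng.standard_normal((n_sims, 4)) @ Lb.T
    acme_s, ade_s, _ = _effects(alpha_sims, beta_sims, t, c)

    ci = (float(np.percentile(acme_s, 2.5)), float(np.percentile(acme_s, 97.5)))
    neg = int(np.sum(acme_s < 0))
    pos = int(np.sum(acme_s > 0))
    p = 2.0 * (1 + min(neg, pos)) / (1 + n_sims)  # add-one: never exactly 0
    p = min(p, 1.0)
    return MediationResult(
        exposure=names[0], mediator=names[1], outcome=names[2],
        acme=float(acme), ade=float(ade), total=float(total),
        prop_mediated=float(prop), p_mediation=float(p), ci=ci,
        n_sims=n_sims, direction=direction,
    )


def bidirectional_screen(
    microbes: pd.DataFrame,
    metabolites: pd.DataFrame,
    age,
    prefilter_alpha: float = 0.05,
    prefilter_mode: str = "p",
    n_sims: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    inverse_mode: str = "exposure_mediator",
) -> pd.DataFrame:
    """Screen microbe -> metabolite -> age mediation linkages.

    ``microbes`` and ``metabolites`` are features x samples with aligned
    columns; ``age`` aligns with the samples. The Spearman prefilter keeps
    pairs with p < ``prefilter_alpha`` (``prefilter_mode='q'`` applies it
    to BH q-values across all pairs instead). For each survivor, a forward
    and an inverse mediation run are performed; ``passes`` is True iff
    p_forward < alpha and p_inverse > alpha. ``inverse_mode`` selects how
    the inverse run rearranges the triplet (see module docstring).
    """
    if list(microbes.columns) != list(metabolites.columns):
        raise ValueError("microbe and metabolite samples must align")
    age = np.asarray(age, dtype=float)
    if len(age) != microbes.shape[1]:
        raise ValueError("age vector must align with samples")

    pairs, prefilter_p = [], []
    for mi in microbes.index:
        xv = microbes.loc[mi].to_numpy(dtype=float)
        if np.ptp(xv) == 0:
            continue
        for mj in metabolites.index:
            mv = metabolites.loc[mj].to_numpy(dtype=float)
            if np.ptp(mv) == 0:
                continue
            _, p = spearman(xv, mv)
            pairs.append((mi, mj))
            prefilter_p.append(p)

    if not pairs:
        return pd.DataFrame(columns=["microbe", "metabolite", "prefilter_p",
                                     "acme_forward", "p_forward",
                                     "acme_inverse", "p_inverse", "passes"])
    prefilter_p = np.asarray(prefilter_p)
    if prefilter_mode == "q":
        keep = bh_fdr(prefilter_p) < prefilter_alpha
    elif prefilter_mode == "p":
        keep = prefilter_p < prefilter_alpha
    else:
        raise ValueError("prefilter_mode must be 'p' or 'q'")

    rows = []
    for k, ((mi, mj), pf) in enumerate(zip(pairs, prefilter_p)):
        if not keep[k]:
            continue
        xv = microbes.loc[mi].to_numpy(dtype=float)
        mv = metabolites.loc[mj].to_numpy(dtype=float)
        fwd = mediate_interaction(
            xv, mv, age, n_sims=n_sims, seed=seed + 2 * k,
            names=(str(mi), str(mj), "age"), direction="forward")
        if inverse_mode == "exposure_mediator":
            inv = mediate_interaction(
                mv, xv, age, n_sims=n_sims, seed=seed + 2 * k + 1,
                names=(str(mj), str(mi), "age"), direction="inverse")
        elif inverse_mode == "mediator_outcome":
            inv = mediate_interaction(
                xv, age, mv, n_sims=n_sims, seed=seed + 2 * k + 1,
                names=(str(mi), "age", str(mj)), direction="inverse")
        else:
            raise ValueError("inverse_mode must be 'exposure_mediator' or "
                             "'mediator_outcome'")
        rows.append({
            "microbe": mi, "metabolite": mj, "prefilter_p": pf,
            "acme_forward": fwd.acme, "p_forward": fwd.p_mediation,
            "acme_inverse": inv.acme, "p_inverse": inv.p_mediation,
            "passes": (fwd.p_mediation < alpha) and (inv.p_mediation > alpha),
        })
    return pd.DataFrame(rows)
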