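"""Firth-penalized univariate logistic regression.

Maximum-likelihood logistic regression breaks down under separation —
the estimate diverges when a predictor perfectly splits cases from
controls, which happens easily in small subgroups such as a detected
risk area.  Firth's correction maximizes the penalized log-likelihood

    l*(b) = l(b) + (1/2) log det I(b),

where I is the Fisher information; the penalty is the Jeffreys prior
and guarantees a finite estimate whenever both outcome classes are
present.  Confidence intervals come from the profile penalized
likelihood, which respects the asymmetry of the penalized surface.

``compare_inside_outside`` runs one Firth model per exposure index for
the subjects inside a detected elevated-risk area and for the full
sample, the side-by-side comparison used to ask which exposures behave
differently in the risk area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

logger = logging.getLogger(__name__)


@dataclass
class FirthFit:
    coef: float
    intercept: float
    se: float
    ci_lower: float
    ci_upper: float
    converged: bool
    iterations: int
    loglik: float                # penalized log-likelihood at the maximum
    ci_method: str = "profile"


def _penalized_parts(beta: np.ndarray, X: np.ndarray, y: np.ndarray):
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1.0 - p)
    I = (X * W[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(I)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta))) + 0.5 * logdet
    # modified score: X'(y - p + h (1/2 - p)) with h the hat diagonal
    Xw = X * np.sqrt(W)[:, None]
    H = Xw @ np.linalg.solve(I, Xw.T)
    h = np.diag(H)
    score = X.T @ (y - p + h * (0.5 - p))
    return ll, score, I


def _fit_firth(X: np.ndarray, y: np.ndarray, tol: float = 1e-6,
               max_iter: int = 50):
    """Newton iterations with step-halving on the penalized likelihood."""
    beta = np.zeros(X.shape[1])
    ll, score, I = _penalized_parts(beta, X, y)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(I, score)
        # step-halving until the penalized likelihood does not decrease
        factor = 1.0
        for _ in range(25):
            cand = beta + factor * step
            ll_new, score_new, I_new = _penalized_parts(cand, X, y)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, score, I = cand, ll_new, score_new, I_new
        if np.linalg.norm(score) < tol:
            converged = True
            break
    return beta, ll, score, I, converged, it


def firth_logistic(y: np.ndarray, x: np.ndarray, ci_level: float = 0.95,
                   max_iter: int = 50, allow_single_class: bool = False) -> FirthFit:
    """Firth-penalized logistic regression of a binary outcome on one
    predictor (plus intercept), with a profile-penalized-likelihood CI.

    The estimate is finite for any data with both outcome classes
    present, including complete separation.  A Wald interval is used
    (and flagged) if the profile bounds cannot be bracketed.  With
    ``allow_single_class=True`` a one-class outcome is tolerated (the
    Jeffreys penalty still yields a finite maximum), which
    :func:`compare_inside_outside` uses for degenerate cluster subsets.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if classes != {0.0, 1.0} and not allow_single_class:
        raise ValueError("outcome must contain both classes, coded 0/1")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    X = np.column_stack([np.ones_like(x), x])
    beta, ll_max, score, I, converged, it = _fit_firth(X, y, max_iter=max_iter)
    if not converged:
        logger.warning("Firth fit did not converge in %d iterations "
                       "(score norm %.2e)", it, np.linalg.norm(score))
    cov = np.linalg.inv(I)
    se = float(np.sqrt(cov[1, 1]))

    crit = chi2.ppf(ci_level, 1) / 2.0

    def profile_ll(b1: float) -> float:
        # maximize the penalized likelihood over the intercept at fixed slope
        def neg(b0):
            ll, _, _ = _penalized_parts(np.array([b0[0], b1]), X, y)
            return -ll

        res = optimize.minimize(neg, [beta[0]], method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-10})
        return -res.fun

    def bound(direction: int) -> float | None:
        f = lambda b: profile_ll(b) - (ll_max - crit)
        step = max(se, 0.5)
        lo = beta[1]
        hi = beta[1] + direction * step
        for _ in range(40):
            if f(hi) < 0:
                break
            lo, hi = hi, hi + direction * step
            step *= 1.5
        else:
            return None
        a, b = sorted([lo, hi])
        try:
            return float(optimize.brentq(f, a, b, xtol=1e-6))
        except ValueError:
            return None

    lower, upper = bound(-1), bound(+1)
    method = "profile"
    if lower is None or upper is None:
        z = chi2.ppf(ci_level, 1) ** 0.5
        lower = beta[1] - z * se if lower is None else lower
        upper = beta[1] + z * se if upper is None else upper
        method = "wald"
        logger.warning("profile CI bracketing failed; Wald fallback used")

    return FirthFit(
        coef=float(beta[1]),
        intercept=float(beta[0]),
        se=se,
        ci_lower=lower,
        ci_upper=upper,
        converged=converged,
        iterations=it,
        loglik=float(ll_max),
        ci_method=method,
    )


def compare_inside_outside(y: np.ndarray, exposures: pd.DataFrame,
                           cluster_members: np.ndarray) -> pd.DataFrame:
    """Per-exposure Firth coefficients inside an elevated-risk area and
    in the full sample.

    ``cluster_members`` indexes rows of ``exposures``/``y`` belonging to
    the area.  Each exposure is fit univariately (intercept + exposure).
    Returns one row per exposure with inside and overall estimates and
    95% CIs; an empty exposure frame yields an empty table.
    """
    y = np.asarray(y, float)
    members = np.asarray(cluster_members, int)
    rows = []
    single_class = len(np.unique(y[members])) < 2
    if single_class:
        logger.warning("cluster subset has a single outcome class; "
                       "estimates remain finite through the penalty")
    for col in exposures.columns:
        x = exposures[col].to_numpy(float)
        overall = firth_logistic(y, x)
        inside = firth_logistic(y[members], x[members], allow_single_class=True)
        rows.append({
            "exposure": col,
            "inside_coef": inside.coef,
            "inside_ci_lower": inside.ci_lower,
            "inside_ci_upper": inside.ci_upper,
            "overall_coef": overall.coef,
            "overall_ci_lower": overall.ci_lower,
            "overall_ci_upper": overall.ci_upper,
        })
    return pd.DataFrame(rows, columns=[
        "exposure", "inside_coef", "inside_ci_lower", "inside_ci_upper",
        "overall_coef", "overall_ci_lower", "overall_ci_upper",
    ])
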