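"""Restricted maximum likelihood for a linear mixed model with two crossed
random intercepts.

The model is

    y = X beta + Z1 u1 + Z2 u2 + e,
    u1 ~ N(0, s1^2 I),  u2 ~ N(0, s2^2 I),  e ~ N(0, se^2 I),

with Z1, Z2 one-hot membership matrices of two crossed grouping factors
(here: surgical procedure and participant).  beta and se^2 are profiled
out analytically; the REML criterion is minimised over the two log
variance ratios log(s_k^2 / se^2).  All linear algebra runs on the
q x q inner matrix (q = number of random-effect levels) via the Woodbury
identity, so a fit on a few thousand observations takes milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


@dataclass(frozen=True)
class CrossedLMMResult:
    """REML fit of the two-factor crossed random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray           # Wald covariance of beta
    sigma2_factor1: float
    sigma2_factor2: float
    sigma2_residual: float
    reml_criterion: float
    converged: bool
    n_obs: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _one_hot(codes: np.ndarray) -> np.ndarray:
    q = int(codes.max()) + 1
    Z = np.zeros((codes.shape[0], q))
    Z[np.arange(codes.shape[0]), codes] = 1.0
    return Z


def fit_crossed_intercepts(y: np.ndarray, X: np.ndarray,
                           codes1: np.ndarray, codes2: np.ndarray,
                           ) -> CrossedLMMResult:
    """Fit the crossed random-intercept model by profiled REML.

    Parameters
    ----------
    y : (n,) response vector.
    X : (n, p) fixed-effects design, full column rank.
    codes1, codes2 : (n,) integer level codes of the two crossed factors
        (0..q1-1 and 0..q2-1).

    Notes
    -----
    The optimiser works on rho = log(lambda) with lambda the variance
    ratios; Nelder–Mead is reliable here because the profiled surface is
    smooth and two-dimensional.  A variance component collapsing to the
    boundary (lambda -> 0) is a valid fit, not a failure.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed-effect columns than observations")

    Z1 = _one_hot(np.asarray(codes1))
    Z2 = _one_hot(np.asarray(codes2))
    q1, q2 = Z1.shape[1], Z2.shape[1]
    Z = np.hstack([Z1, Z2])

    # All sufficient statistics are precomputable; the objective touches
    # only (q1+q2)-dimensional quantities.
    ZtZ = Z.T @ Z
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    scale = np.empty(q1 + q2)

    def profile(rho: np.ndarray):
        lam1, lam2 = np.exp(np.clip(rho, -30.0, 30.0))
        scale[:q1] = np.sqrt(lam1)
        scale[q1:] = np.sqrt(lam2)
        M = ZtZ * np.outer(scale, scale)
        M[np.diag_indices_from(M)] += 1.0
        c, low = linalg.cho_factor(M, lower=True, check_finite=False)
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
        ZtX_s = ZtX * scale[:, None]
        Zty_s = Zty * scale
        MinvZtX = linalg.cho_solve((c, low), ZtX_s, check_finite=False)
        MinvZty = linalg.cho_solve((c, low), Zty_s, check_finite=False)
        XtVinvX = XtX - ZtX_s.T @ MinvZtX
        XtVinvy = Xty - ZtX_s.T @ MinvZty
        ytVinvy = yty - Zty_s @ MinvZty
        beta = np.linalg.solve(XtVinvX, XtVinvy)
        rss = max(ytVinvy - XtVinvy @ beta, 1e-300)
        sigma2 = rss / (n - p)
        sign, logdet_XtVinvX = np.linalg.slogdet(XtVinvX)
        crit = (n - p) * np.log(sigma2) + logdet_V + logdet_XtVinvX
        return crit, beta, sigma2, XtVinvX

    def objective(rho: np.ndarray) -> float:
        return profile(rho)[0]

    res = optimize.minimize(objective, x0=np.array([-1.0, -1.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 500})
    crit, beta, sigma2, XtVinvX = profile(res.x)
    lam1, lam2 = np.exp(np.clip(res.x, -30.0, 30.0))
    cov_beta = sigma2 * np.linalg.inv(XtVinvX)
    return CrossedLMMResult(
        beta=beta, cov_beta=cov_beta,
        sigma2_factor1=float(lam1 * sigma2),
        sigma2_factor2=float(lam2 * sigma2),
        sigma2_residual=float(sigma2),
        reml_criterion=float(crit),
        converged=bool(res.success and np.isfinite(crit)),
        n_obs=n)
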