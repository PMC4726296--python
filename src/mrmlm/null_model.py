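"""REML fit of the pure polygenic null model.

The polygenic-to-residual variance ratio lambda = sigma_g^2 / sigma^2 is
estimated once here and then held fixed throughout the marker scans
("population parameters previously defined").  In the eigen-rotated space the
null covariance is sigma^2 (lambda * diag(D) + I), so the restricted
likelihood is a cheap one-dimensional function of lambda.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import NullPolygenicFit, TransformedData

__all__ = ["fit_null_reml", "reml_loglik_parts", "null_restricted_loglik"]

_LOG2PI = np.log(2.0 * np.pi)


def reml_loglik_parts(n: int, q: int, logdet_sigma: float, logdet_xtx: float, Q: float) -> float:
    """Profiled restricted log-likelihood from its scalar ingredients.

    ``Q`` is the generalised residual sum of squares y' P y on the unit-sigma^2
    scale; sigma^2 is profiled out as Q / (n - q).
    """
    if Q <= 0 or not np.isfinite(Q):
        return -np.inf
    sigma2 = Q / (n - q)
    return -0.5 * (
        (n - q) * (np.log(sigma2) + 1.0 + _LOG2PI) + logdet_sigma + logdet_xtx
    )


def null_restricted_loglik(td: TransformedData, D: np.ndarray, lam: float) -> float:
    """Restricted log-likelihood of the polygenic null model at ratio ``lam``."""
    ys, Xs = td.y_star, td.X_star
    n, qcols = Xs.shape
    r = lam * np.asarray(D, dtype=float) + 1.0
    if np.any(r <= 0):
        return -np.inf
    rinv = 1.0 / r
    A = Xs.T @ (rinv[:, None] * Xs)
    ay = Xs.T @ (rinv * ys)
    sign, logdet_xtx = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("collinear covariates in null design")
    beta = np.linalg.solve(A, ay)
    Q = float(ys @ (rinv * ys) - ay @ beta)
    return reml_loglik_parts(n, qcols, float(np.log(r).sum()), logdet_xtx, Q)


def fit_null_reml(
    td: TransformedData,
    D: np.ndarray,
    bounds: tuple[float, float] = (1e-5, 1e5),
    grid_points: int = 61,
) -> NullPolygenicFit:
    """Maximise the restricted likelihood of the null model over lambda.

    A coarse log10 grid over ``bounds`` (plus the exact boundary lambda = 0)
    brackets the optimum; Brent refinement polishes it.  When the eigenvalues
    are all equal (K proportional to I) lambda is not identifiable and the fit
    returns lambda = 0 with a degeneracy warning.
    """
    D = np.asarray(D, dtype=float)
    n, qcols = td.X_star.shape
    if n <= qcols:
        raise ValueError("need n > q to fit the null model")

    degenerate = bool(np.ptp(D) < 1e-10 * max(1.0, np.abs(D).max()))
    if degenerate:
        warnings.warn(
            "kinship eigenvalues are constant: lambda is not identifiable; "
            "returning lambda_hat = 0",
            stacklevel=2,
        )
        ll0 = null_restricted_loglik(td, D, 0.0)
        sigma2 = _sigma2_at(td, D, 0.0)
        return NullPolygenicFit(0.0, 0.0, sigma2, ll0, degenerate=True)

    lo, hi = bounds
    grid = np.concatenate([[0.0], np.logspace(np.log10(lo), np.log10(hi), grid_points)])
    vals = np.array([null_restricted_loglik(td, D, g) for g in grid])
    if not np.all(np.isfinite(vals[1:])) or not np.isfinite(vals[0]):
        bad = grid[~np.isfinite(vals)]
        raise FloatingPointError(
            f"non-finite restricted likelihood on search grid at lambda={bad[:3]}"
        )
    best = int(np.argmax(vals))
    lam_hat, ll_hat = grid[best], vals[best]

    if 0 < best < len(grid) - 1:
        a = max(grid[best - 1], lo * 1e-3) if best >= 1 else lo
        b = grid[best + 1]
        res = minimize_scalar(
            lambda t: -null_restricted_loglik(td, D, 10.0**t),
            bounds=(np.log10(max(a, 1e-300)), np.log10(b)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > ll_hat:
            lam_hat, ll_hat = 10.0**res.x, -res.fun
        # the boundary lambda = 0 can still dominate a shallow interior optimum
        if vals[0] >= ll_hat:
            lam_hat, ll_hat = 0.0, vals[0]

    bounds_hit = bool(best == 1 and vals[1] >= vals[0]) or best == len(grid) - 1
    if best == len(grid) - 1:
        warnings.warn("lambda estimate at upper search bound", stacklevel=2)

    sigma2 = _sigma2_at(td, D, lam_hat)
    return NullPolygenicFit(
        lambda_hat=float(lam_hat),
        sigma_g2=float(lam_hat * sigma2),
        sigma2=float(sigma2),
        restricted_loglik=float(ll_hat),
        bounds_hit=bounds_hit,
        degenerate=False,
    )


def _sigma2_at(td: TransformedData, D: np.ndarray, lam: float) -> float:
    ys, Xs = td.y_star, td.X_star
    n, qcols = Xs.shape
    r = lam * D + 1.0
    rinv = 1.0 / r
    A = Xs.T @ (rinv[:, None] * Xs)
    ay = Xs.T @ (rinv * ys)
    Q = float(ys @ (rinv * ys) - ay @ np.linalg.solve(A, ay))
    return Q / (n - qcols)
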