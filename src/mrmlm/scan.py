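"""Single-locus genome scans.

Two scans share the same eigen-rotated, diagonal-plus-rank-one algebra:

* the random-SNP-effect scan, which estimates a per-marker variance ratio
  lambda_k = sigma_k^2 / sigma^2 by profiled REML, predicts the SNP effect by
  BLUP (shrunken towards zero) and tests it with a Wald statistic referred to
  chi-square with one degree of freedom, and
* a fixed-effect baseline scan (EMMA-style) that treats the SNP effect as a
  fixed GLS coefficient with the plain Bonferroni threshold alpha / m.

With R = lambda_hat * diag(D) + I fixed from the null model, the marker
covariance is Sigma = lambda_k z z' + R and every quantity reduces, through
the Woodbury identities, to three scalars per marker:

    t  = z' R^-1 M z,   s = z' R^-1 M y,   Q0 = y' R^-1 M y,

where M projects out the fixed effects in the R^-1 metric.  The profiled
restricted log-likelihood in u = lambda_k t / (1 + lambda_k t) is

    l(u) = -1/2 [ -log(1 - u) + (n - q) log(Q0 - u s^2 / t) ] + const,

whose unique stationary point is u* = [(n-q) S - Q0] / [S (n-q-1)] with
S = s^2 / t, giving a closed-form REML maximiser that the vectorised scan
uses directly; the Newton optimiser below reproduces it iteratively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .containers import (
    GenotypeMatrix,
    NullPolygenicFit,
    ScanThresholds,
    TransformedData,
    build_design,
)
from .kinship import compute_kinship, eigendecompose_kinship, transform_data
from .null_model import fit_null_reml, reml_loglik_parts

__all__ = [
    "woodbury_solve",
    "profiled_restricted_loglik",
    "newton_optimize_lambda_k",
    "estimate_beta_sigma2",
    "blup_gamma",
    "wald_test",
    "effective_marker_number",
    "scan_genome",
    "fixed_effect_scan",
]

_2LN10 = 2.0 * np.log(10.0)


# ---------------------------------------------------------------------------
# Woodbury rank-one algebra
# ---------------------------------------------------------------------------

def woodbury_solve(r: np.ndarray, z_star: np.ndarray, lambda_k: float):
    """O(n) action of Sigma^-1 and log det Sigma for Sigma = lambda_k zz' + R.

    Returns ``(solve, logdet)`` where ``solve(v)`` applies Sigma^-1 to a
    vector (or each column of a matrix).
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z_star, dtype=float).ravel()
    if lambda_k < 0:
        raise ValueError("lambda_k must be nonnegative")
    if np.any(r <= 0):
        raise ValueError("R must be positive diagonal")
    rinv = 1.0 / r
    rz = rinv * z
    denom = 1.0 + lambda_k * float(z @ rz)
    if denom <= 0:
        raise ValueError("1 + lambda_k z'R^-1 z <= 0: corrupted input")
    logdet = float(np.log(r).sum() + np.log(denom))

    def solve(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        rv = rinv[:, None] * v if v.ndim == 2 else rinv * v
        corr = (lambda_k / denom) * np.outer(rz, z @ rv) if v.ndim == 2 else (
            (lambda_k / denom) * rz * float(z @ rv)
        )
        return rv - corr

    return solve, logdet


def _marker_scalars(td: TransformedData, z_star: np.ndarray, r: np.ndarray):
    """Projected scalars (t, s, Q0) plus design pieces for one marker."""
    ys, Xs = td.y_star, td.X_star
    rinv = 1.0 / r
    A0 = Xs.T @ (rinv[:, None] * Xs)
    ay = Xs.T @ (rinv * ys)
    sign, logdet_A0 = np.linalg.slogdet(A0)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular X*' Sigma^-1 X*: collinear covariates")
    A0inv_ay = np.linalg.solve(A0, ay)
    z = np.asarray(z_star, dtype=float).ravel()
    vx = Xs.T @ (rinv * z)
    A0inv_vx = np.linalg.solve(A0, vx)
    czz = float(z @ (rinv * z))
    t = czz - float(vx @ A0inv_vx)
    s = float(z @ (rinv * ys)) - float(vx @ A0inv_ay)
    Q0 = float(ys @ (rinv * ys)) - float(ay @ A0inv_ay)
    return t, s, Q0, czz, logdet_A0


def profiled_restricted_loglik(
    lambda_k: float, td: TransformedData, z_star: np.ndarray, r: np.ndarray
) -> float:
    """Profiled restricted log-likelihood of one marker's variance ratio.

    beta and sigma^2 are profiled out analytically; at lambda_k = 0 this
    equals the null-model restricted log-likelihood for the same R.
    """
    if lambda_k < 0:
        raise ValueError("lambda_k must be nonnegative")
    n, qcols = td.X_star.shape
    t, s, Q0, czz, logdet_A0 = _marker_scalars(td, z_star, r)
    lt = lambda_k * t
    Q = Q0 - (lambda_k * s * s) / (1.0 + lt)
    # log|Sigma| + log|X' Sigma^-1 X| = sum log r + log|A0| + log(1 + lambda t)
    logdet_sigma = float(np.log(r).sum()) + np.log1p(lambda_k * czz)
    logdet_xtx = logdet_A0 + np.log1p(lt) - np.log1p(lambda_k * czz)
    return reml_loglik_parts(n, qcols, logdet_sigma, logdet_xtx, Q)


def _closed_form_u(t, s, Q0, n, q):
    """Exact argmax of the profiled restricted likelihood in u = lt/(1+lt)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(t > 0, s * s / np.where(t > 0, t, 1.0), 0.0)
        u = ((n - q) * S - Q0) / (S * (n - q - 1))
    u = np.where((S > 0) & ((n - q) * S > Q0), u, 0.0)
    return np.clip(u, 0.0, 1.0 - 1e-12), S


def newton_optimize_lambda_k(
    td: TransformedData,
    z_star: np.ndarray,
    r: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[float, bool]:
    """Newton (Fisher-scoring) maximiser of the profiled restricted likelihood.

    The score in lambda is
        l'(lambda) = 1/2 [ (n-q) s^2 / ((1+lt)^2 Q) - t / (1+lt) ]
    and the expected information 1/2 t^2 / (1+lt)^2; steps are halved until
    the likelihood does not decrease and the estimate is projected to the
    boundary 0 when the unconstrained optimum is negative.  Falls back to a
    grid + Brent search on non-convergence.  Returns (lambda_hat, converged).
    """
    n, qcols = td.X_star.shape
    t, s, Q0, _, _ = _marker_scalars(td, z_star, r)
    if t <= 0:
        return 0.0, True
    S = s * s / t
    # boundary check: score at 0 is 1/2 t [ (n-q) S / Q0 - 1 ]
    if (n - qcols) * S <= Q0:
        return 0.0, True

    def nll(lam):
        lt = lam * t
        Q = Q0 - lam * s * s / (1.0 + lt)
        return 0.5 * ((n - qcols) * np.log(Q) + np.log1p(lt))

    lam = 1.0 / t  # scale-aware start
    f = nll(lam)
    converged = False
    for _ in range(max_iter):
        lt = lam * t
        Q = Q0 - lam * s * s / (1.0 + lt)
        score = 0.5 * ((n - qcols) * s * s / ((1.0 + lt) ** 2 * Q) - t / (1.0 + lt))
        info = 0.5 * t * t / (1.0 + lt) ** 2
        step = score / info
        new = lam + step
        if new < 0:
            new = lam / 2.0 if lam > 0 else 0.0
        fnew = nll(new)
        halvings = 0
        while fnew > f + 1e-12 and halvings < 30:
            new = lam + (new - lam) / 2.0
            fnew = nll(new)
            halvings += 1
        if abs(new - lam) < tol * (1.0 + lam):
            lam, f = new, fnew
            converged = True
            break
        lam, f = new, fnew
    if not converged:
        # grid + Brent fallback over log10 lambda
        grid = np.logspace(-6.0, 4.0, 201)
        vals = np.array([nll(g) for g in grid])
        b = int(np.argmin(vals))
        lo = grid[max(b - 1, 0)]
        hi = grid[min(b + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda u: nll(10.0**u),
            bounds=(np.log10(lo), np.log10(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = 10.0**res.x
        if nll(0.0) <= nll(lam):
            lam = 0.0
    return float(max(lam, 0.0)), converged


def estimate_beta_sigma2(
    lambda_k_hat: float, td: TransformedData, z_star: np.ndarray, r: np.ndarray
) -> tuple[np.ndarray, float]:
    """GLS fixed effects and REML residual variance at the fitted ratio."""
    ys, Xs = td.y_star, td.X_star
    n, qcols = Xs.shape
    solve, _ = woodbury_solve(r, z_star, lambda_k_hat)
    SiX = solve(Xs)
    Siy = solve(ys)
    A = Xs.T @ SiX
    if np.linalg.matrix_rank(A) < qcols:
        raise np.linalg.LinAlgError("rank-deficient fixed-effect design")
    beta = np.linalg.solve(A, Xs.T @ Siy)
    Q = float(ys @ Siy - (Xs.T @ Siy) @ beta)
    return beta, Q / (n - qcols)


def blup_gamma(
    lambda_k_hat: float,
    td: TransformedData,
    z_star: np.ndarray,
    r: np.ndarray,
    beta_hat: np.ndarray | None = None,
    sigma2_hat: float | None = None,
) -> tuple[float, float]:
    """BLUP of the marker effect and its conditional variance.

    gamma_hat = lambda_k z' Sigma^-1 (y - X beta_hat); the conditional
    variance sigma^2 (lambda_k - lambda_k^2 z' P z) with P the REML
    projection reduces to sigma^2 u / t with u = lambda t / (1 + lambda t).
    """
    if beta_hat is None or sigma2_hat is None:
        beta_hat, sigma2_hat = estimate_beta_sigma2(lambda_k_hat, td, z_star, r)
    if lambda_k_hat == 0.0:
        return 0.0, 0.0
    z = np.asarray(z_star, dtype=float).ravel()
    solve, _ = woodbury_solve(r, z, lambda_k_hat)
    resid = td.y_star - td.X_star @ beta_hat
    gamma = lambda_k_hat * float(z @ solve(resid))
    t, _, _, _, _ = _marker_scalars(td, z, r)
    u = lambda_k_hat * t / (1.0 + lambda_k_hat * t)
    var_gamma = sigma2_hat * (u / t) if t > 0 else 0.0
    return gamma, max(var_gamma, 0.0)


def wald_test(gamma_hat: float, var_gamma: float) -> tuple[float, float, float]:
    """Wald statistic, chi2(1) upper-tail p-value and LOD score."""
    if var_gamma < 0:
        raise ValueError("var_gamma must be nonnegative")
    if var_gamma == 0.0:
        if gamma_hat != 0.0:
            raise ValueError("inconsistent record: zero variance, nonzero effect")
        return 0.0, 1.0, 0.0
    w = gamma_hat * gamma_hat / var_gamma
    p = float(stats.chi2.sf(w, df=1))
    return float(w), p, float(w / _2LN10)


# ---------------------------------------------------------------------------
# Effective number of markers (Li-Ji style, block-wise)
# ---------------------------------------------------------------------------

def effective_marker_number(
    G: GenotypeMatrix | np.ndarray, block_size: int = 133
) -> float:
    """Effective number of independent markers for the modified Bonferroni.

    Computed from the eigenvalues of the marker correlation matrix with the
    Li-Ji estimator f(x) = I(x >= 1) + (x - floor(x)), summed over
    consecutive blocks of ``block_size`` markers within each chromosome.
    Invariant to marker order permutations within blocks and to allele-
    orientation flips; equals m for mutually uncorrelated markers.
    """
    if isinstance(G, GenotypeMatrix):
        mask = G.polymorphic_mask()
        values = G.values[:, mask]
        chroms = G.snp_map["chrom"].to_numpy()[mask]
    else:
        values = np.asarray(G, dtype=float)
        values = values[:, values.std(axis=0) > 0]
        chroms = np.array(["1"] * values.shape[1])
    m = values.shape[1]
    if m == 0:
        raise ValueError("no polymorphic markers")
    total = 0.0
    for chrom in pd.unique(chroms):
        block = values[:, chroms == chrom]
        for start in range(0, block.shape[1], block_size):
            sub = block[:, start : start + block_size]
            if sub.shape[1] == 1:
                total += 1.0
                continue
            corr = np.corrcoef(sub, rowvar=False)
            ev = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
            total += float(np.sum((ev >= 1.0) + (ev - np.floor(ev))))
    return float(min(max(total, 1.0), m))


# ---------------------------------------------------------------------------
# Vectorised whole-genome scans
# ---------------------------------------------------------------------------

def _prepare(G, y, X, null_fit, kinship, maf_min):
    """Shared set-up: design, kinship spectrum, rotation, null fit."""
    if not isinstance(G, GenotypeMatrix):
        G = GenotypeMatrix(values=np.asarray(G, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != G.n:
        raise ValueError("phenotype length does not match genotype rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if X is None:
        X = build_design(G.n)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.allclose(X[:, 0], 1.0):
            X = build_design(G.n, X)
    if kinship is None:
        spectrum = eigendecompose_kinship(compute_kinship(G))
    elif hasattr(kinship, "U"):
        spectrum = kinship
    else:
        spectrum = eigendecompose_kinship(np.asarray(kinship, dtype=float))
    td = transform_data(y, X, spectrum.U)
    if null_fit is None:
        null_fit = fit_null_reml(td, spectrum.D)
    r = null_fit.lambda_hat * spectrum.D + 1.0
    mask = G.polymorphic_mask(maf_min)
    return G, td, spectrum, null_fit, r, mask


def _projected_scalars_all(td: TransformedData, Zs: np.ndarray, r: np.ndarray):
    """Vectorised (t, s, Q0) for every marker column of Zs."""
    ys, Xs = td.y_star, td.X_star
    rinv = 1.0 / r
    A0 = Xs.T @ (rinv[:, None] * Xs)
    ay = Xs.T @ (rinv * ys)
    A0inv_ay = np.linalg.solve(A0, ay)
    Vx = Xs.T @ (rinv[:, None] * Zs)  # q x m
    W = np.linalg.solve(A0, Vx)
    czz = np.einsum("nm,nm->m", Zs, rinv[:, None] * Zs)
    t = czz - np.einsum("qm,qm->m", Vx, W)
    s = Zs.T @ (rinv * ys) - W.T @ ay
    Q0 = float(ys @ (rinv * ys) - ay @ A0inv_ay)
    return t, s, Q0


def _records_frame(G, mask, cols: dict) -> pd.DataFrame:
    df = G.snp_map.copy()
    df["maf"] = G.maf()
    for name, values in cols.items():
        full = np.full(G.m, np.nan)
        full[mask] = values
        df[name] = full
    return df


def scan_genome(
    G,
    y,
    X=None,
    null_fit: NullPolygenicFit | None = None,
    kinship=None,
    alpha: float = 0.05,
    maf_min: float | None = None,
    me_block_size: int = 133,
) -> tuple[pd.DataFrame, ScanThresholds, NullPolygenicFit]:
    """Random-SNP-effect scan of every polymorphic marker.

    Returns one record per marker (monomorphic / low-MAF markers carry NaN
    statistics), the modified-Bonferroni thresholds based on the effective
    marker number, and the null polygenic fit that was used.
    """
    G, td, spectrum, null_fit, r, mask = _prepare(G, y, X, null_fit, kinship, maf_min)
    n, qcols = td.X_star.shape
    Zs = td.U.T @ G.values[:, mask]
    t, s, Q0 = _projected_scalars_all(td, Zs, r)

    u, S = _closed_form_u(t, s, Q0, n, qcols)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where((u > 0) & (t > 0), u / ((1.0 - u) * np.where(t > 0, t, 1.0)), 0.0)
        sigma2 = (Q0 - u * S) / (n - qcols)
        gamma = np.where(t > 0, u * s / np.where(t > 0, t, 1.0), 0.0)
        var_gamma = np.where(t > 0, sigma2 * u / np.where(t > 0, t, 1.0), 0.0)
        wald = np.where(u > 0, u / (1.0 - u), 0.0)
    p = stats.chi2.sf(wald, df=1)
    p = np.where(wald > 0, p, 1.0)
    lod = wald / _2LN10

    m_e = effective_marker_number(G, block_size=me_block_size)
    thresholds = ScanThresholds(m_e=m_e, alpha_genome=alpha, m=int(mask.sum()))
    df = _records_frame(
        G,
        mask,
        {
            "lambda_k": lam,
            "effect": gamma,
            "var_gamma": var_gamma,
            "se": np.sqrt(var_gamma),
            "wald": wald,
            "p": p,
            "lod": lod,
        },
    )
    df["significant"] = df["p"] <= thresholds.p_threshold
    df.loc[~np.asarray(mask), "significant"] = False
    return df, thresholds, null_fit


def fixed_effect_scan(
    G,
    y,
    X=None,
    null_fit: NullPolygenicFit | None = None,
    kinship=None,
    alpha: float = 0.05,
    maf_min: float | None = None,
) -> tuple[pd.DataFrame, ScanThresholds, NullPolygenicFit]:
    """EMMA-style fixed-SNP-effect scan with Bonferroni threshold alpha / m.

    Per-marker GLS Wald test in the eigen-rotated covariance with the
    polygenic ratio fixed from the null fit; p-values use the exact
    F(1, n - q - 1) reference of the per-marker statistic.
    """
    G, td, spectrum, null_fit, r, mask = _prepare(G, y, X, null_fit, kinship, maf_min)
    n, qcols = td.X_star.shape
    Zs = td.U.T @ G.values[:, mask]
    t, s, Q0 = _projected_scalars_all(td, Zs, r)

    dof = n - qcols - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(t > 0, s / np.where(t > 0, t, 1.0), 0.0)
        S = gamma * s  # = s^2 / t
        sigma2 = np.maximum(Q0 - S, 0.0) / dof
        var_gamma = np.where(t > 0, sigma2 / np.where(t > 0, t, 1.0), 0.0)
        wald = np.where((t > 0) & (sigma2 > 0), S / np.where(sigma2 > 0, sigma2, 1.0), 0.0)
    p = stats.f.sf(wald, 1, dof)
    p = np.where(wald > 0, p, 1.0)
    lod = wald / _2LN10

    m = int(mask.sum())
    thresholds = ScanThresholds(m_e=float(m), alpha_genome=alpha, m=m)
    df = _records_frame(
        G,
        mask,
        {
            "effect": gamma,
            "var_gamma": var_gamma,
            "se": np.sqrt(var_gamma),
            "wald": wald,
            "p": p,
            "lod": lod,
        },
    )
    df["significant"] = df["p"] <= thresholds.p_threshold
    df.loc[~np.asarray(mask), "significant"] = False
    return df, thresholds, null_fit
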