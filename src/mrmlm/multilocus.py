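"""Multi-locus second stage.

Markers surviving the lenient single-locus screen (p < 0.01, positionally
pruned) are fitted jointly: those that also pass the genome-wide modified
Bonferroni threshold and show LRT LOD > 1.5 enter the model as fixed effects,
the rest as random effects with marker-specific variances estimated by an EM
empirical Bayes (EMEB) algorithm.  Each marker then gets a likelihood ratio
test; LOD >= 3 (p <= 0.0002 under chi2 with 1 df) declares a QTN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "preselect_markers",
    "classify_fixed_random",
    "emeb_fit",
    "EMEBFit",
    "MultiLocusModel",
    "final_calls",
    "bic_goodness_of_fit",
]

_2LN10 = 2.0 * np.log(10.0)
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Stage-1 output filtering
# ---------------------------------------------------------------------------

def preselect_markers(
    scan: pd.DataFrame, p_select: float = 0.01, window_bp: int = 1000
) -> pd.DataFrame:
    """Greedy preselection of scan records below ``p_select``.

    Records are taken in ascending p order (ties broken by position then
    marker id); any remaining candidate within ``window_bp`` of an already
    selected marker on the same chromosome is eliminated, which keeps the
    selected set free of tight local clusters.  An empty result is valid and
    simply means the pipeline reports no QTN.
    """
    cand = scan[np.isfinite(scan["p"]) & (scan["p"] < p_select)]
    cand = cand.sort_values(["p", "pos", "marker_id"], kind="mergesort")
    kept_rows = []
    kept_pos: dict[str, list[int]] = {}
    for _, row in cand.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if any(abs(pos - kp) <= window_bp for kp in kept_pos.get(chrom, ())):
            continue
        kept_rows.append(row)
        kept_pos.setdefault(chrom, []).append(pos)
    if not kept_rows:
        return scan.iloc[0:0].copy()
    out = pd.DataFrame(kept_rows)
    return out.sort_values(["chrom", "pos"], kind="mergesort")


def classify_fixed_random(
    selected: pd.DataFrame,
    p_threshold: float,
    ys: np.ndarray,
    Xs: np.ndarray,
    Zs_sel: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Partition selected markers into fixed and random model terms.

    Markers whose scan p-value passes the modified Bonferroni threshold get a
    single-marker likelihood ratio test (mixed model with vs without the
    marker as a fixed effect, polygenic ratio held fixed; ML likelihoods,
    since the two models differ in fixed effects); LRT LOD > 1.5 makes the
    marker fixed, anything else stays random.
    """
    treated = np.array(["random"] * len(selected), dtype=object)
    if len(selected) == 0:
        return treated
    rinv = 1.0 / r
    rss0 = _gls_rss(ys, Xs, rinv)
    n = ys.shape[0]
    for j, (_, row) in enumerate(selected.iterrows()):
        if not (row["p"] <= p_threshold):
            continue
        W = np.column_stack([Xs, Zs_sel[:, j]])
        rss1 = _gls_rss(ys, W, rinv)
        lrt = n * np.log(max(rss0, 1e-300) / max(rss1, 1e-300))
        if lrt / _2LN10 > 1.5:
            treated[j] = "fixed"
    return treated


def _gls_rss(y: np.ndarray, W: np.ndarray, rinv: np.ndarray) -> float:
    A = W.T @ (rinv[:, None] * W)
    b = W.T @ (rinv * y)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return float(y @ (rinv * y) - b @ coef)


# ---------------------------------------------------------------------------
# EM empirical Bayes
# ---------------------------------------------------------------------------

@dataclass
class EMEBFit:
    """Converged (or best-iterate) state of the EM empirical Bayes model."""

    beta: np.ndarray            # fixed-effect coefficients (incl. fixed markers)
    gamma: np.ndarray           # posterior means of random marker effects
    gamma_var: np.ndarray       # posterior variances (diagonal of C)
    sigma_k2: np.ndarray        # per-marker effect variances
    sigma2: float               # residual variance
    loglik: float               # marginal log-likelihood at the final state
    loglik_path: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    n_iter: int = 0


def _marginal_loglik(y, X, Z, r, beta, sigma_k2, sigma2) -> float:
    """Marginal log-likelihood of y ~ N(X beta, Z diag(sigma_k2) Z' + sigma2 R)."""
    n = y.shape[0]
    d = y - X @ beta
    rinv = 1.0 / r
    logdet_base = n * np.log(sigma2) + np.log(r).sum()
    if Z.shape[1] == 0:
        quad = float(d @ (rinv * d)) / sigma2
        return -0.5 * (n * _LOG2PI + logdet_base + quad)
    shalf = np.sqrt(sigma_k2)
    B = Z.T @ (rinv[:, None] * Z)
    M0 = np.eye(Z.shape[1]) + (shalf[:, None] * B * shalf[None, :]) / sigma2
    sign, logdet_M0 = np.linalg.slogdet(M0)
    zd = shalf * (Z.T @ (rinv * d))
    quad = float(d @ (rinv * d)) / sigma2 - float(
        zd @ np.linalg.solve(M0, zd)
    ) / sigma2**2
    return -0.5 * (n * _LOG2PI + logdet_base + logdet_M0 + quad)


def emeb_fit(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    r: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    init: dict | None = None,
    track_loglik: bool = False,
) -> EMEBFit:
    """EM empirical Bayes fit of a multi-locus model with per-effect variances.

    Model: y = X beta + Z gamma + e with gamma_k ~ N(0, sigma_k^2)
    independently and e ~ N(0, sigma^2 R), R = diag(r) known.  The
    scaled-inverse-chi-square hyperparameters (tau, omega) = (-2, 0) make the
    M-step sigma_k^2 = E[gamma_k^2 | y]; beta and sigma^2 are updated by their
    conditional maximisers, so the marginal likelihood is non-decreasing
    across iterations.  Effect variances are floored at 1e-8 x sigma^2 to
    keep the posterior precision well conditioned (an effect at the floor is
    fully shrunk).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = y.shape[0]
    if r is None:
        r = np.ones(n)
    r = np.asarray(r, dtype=float)
    k = Z.shape[1]
    rinv = 1.0 / r

    XtRX = X.T @ (rinv[:, None] * X)
    if np.linalg.matrix_rank(XtRX) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient fixed design after augmentation")
    XtR = X.T * rinv[None, :]
    B = Z.T @ (rinv[:, None] * Z) if k else np.zeros((0, 0))

    if init is None:
        beta = np.linalg.solve(XtRX, XtR @ y)
        e0 = y - X @ beta
        sigma2 = float(e0 @ (rinv * e0)) / max(n - X.shape[1], 1)
        if k:
            naive = (Z.T @ (rinv * e0)) / np.maximum(np.diag(B), 1e-12)
            sigma_k2 = np.maximum(naive**2, 1e-4 * sigma2)
        else:
            sigma_k2 = np.zeros(0)
    else:
        beta = np.asarray(init["beta"], dtype=float).copy()
        sigma2 = float(init["sigma2"])
        sigma_k2 = np.asarray(init["sigma_k2"], dtype=float).copy()

    mu = np.zeros(k)
    C = np.zeros((k, k))
    ZtRi = Z.T * rinv[None, :] if k else np.zeros((0, n))
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        floor = 1e-8 * sigma2
        sigma_k2 = np.maximum(sigma_k2, floor)
        if track_loglik:
            path.append(_marginal_loglik(y, X, Z, r, beta, sigma_k2, sigma2))
        # E-step: joint posterior of gamma
        if k:
            A = B / sigma2 + np.diag(1.0 / sigma_k2)
            C = np.linalg.inv(A)
            mu = C @ (ZtRi @ (y - X @ beta)) / sigma2
        # M-step
        beta_new = np.linalg.solve(XtRX, XtR @ (y - Z @ mu)) if k else np.linalg.solve(
            XtRX, XtR @ y
        )
        sigma_k2_new = mu**2 + np.diag(C) if k else sigma_k2
        e = y - X @ beta_new - (Z @ mu if k else 0.0)
        trace_term = float(np.sum(B * C)) if k else 0.0
        sigma2_new = (float(e @ (rinv * e)) + trace_term) / n
        delta = max(
            np.max(np.abs(beta_new - beta), initial=0.0),
            np.max(np.abs(sigma_k2_new - sigma_k2), initial=0.0),
            abs(sigma2_new - sigma2),
        )
        beta, sigma_k2, sigma2 = beta_new, np.maximum(sigma_k2_new, 0.0), sigma2_new
        if delta < tol * (1.0 + abs(sigma2)):
            converged = True
            break
    if not converged:
        warnings.warn("EMEB did not converge; returning best iterate", stacklevel=2)
    # final E-step so reported effects match the final variances
    if k:
        A = B / sigma2 + np.diag(1.0 / np.maximum(sigma_k2, 1e-8 * sigma2))
        C = np.linalg.inv(A)
        mu = C @ (ZtRi @ (y - X @ beta)) / sigma2
    ll = _marginal_loglik(y, X, Z, r, beta, np.maximum(sigma_k2, 1e-12), sigma2)
    path.append(ll)
    return EMEBFit(
        beta=beta,
        gamma=mu,
        gamma_var=np.diag(C).copy() if k else np.zeros(0),
        sigma_k2=sigma_k2,
        sigma2=float(sigma2),
        loglik=float(ll),
        loglik_path=np.asarray(path),
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Full multi-locus model with per-marker tests
# ---------------------------------------------------------------------------

class MultiLocusModel:
    """Joint model over the selected markers with per-marker LRTs.

    Operates in the eigen-rotated space: ``Xs`` is the rotated base design,
    ``Zs`` the rotated selected-marker columns, ``r`` the diagonal residual
    profile (lambda_hat * D + 1 when the polygenic term is retained, ones
    otherwise).  ``treated_as`` routes each marker into the fixed design or
    the random shrinkage set.
    """

    def __init__(self, ys, Xs, Zs, treated_as, r=None, max_iter=200, tol=1e-6):
        self.ys = np.asarray(ys, dtype=float).ravel()
        self.Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        self.Zs = np.asarray(Zs, dtype=float)
        if self.Zs.ndim == 1:
            self.Zs = self.Zs[:, None]
        self.treated_as = np.asarray(treated_as, dtype=object)
        self.r = np.ones(self.ys.shape[0]) if r is None else np.asarray(r, dtype=float)
        self.max_iter = max_iter
        self.tol = tol
        self.fixed_idx = np.where(self.treated_as == "fixed")[0]
        self.random_idx = np.where(self.treated_as == "random")[0]

    def _design(self, drop: int | None = None):
        """Augmented (X, Z) with marker ``drop`` removed (by selected index)."""
        fixed = [j for j in self.fixed_idx if j != drop]
        rand = [j for j in self.random_idx if j != drop]
        X = np.hstack([self.Xs, self.Zs[:, fixed]]) if fixed else self.Xs
        Z = self.Zs[:, rand] if rand else np.zeros((self.ys.shape[0], 0))
        return X, Z, fixed, rand

    def fit(self) -> "MultiLocusModel":
        X, Z, _, _ = self._design()
        self.fit_ = emeb_fit(self.ys, X, Z, self.r, self.max_iter, self.tol)
        self._extract_effects()
        return self

    def _extract_effects(self) -> None:
        _, _, fixed, rand = self._design()
        k_sel = self.Zs.shape[1]
        effects = np.zeros(k_sel)
        variances = np.zeros(k_sel)
        qbase = self.Xs.shape[1]
        for pos, j in enumerate(fixed):
            effects[j] = self.fit_.beta[qbase + pos]
        for pos, j in enumerate(rand):
            effects[j] = self.fit_.gamma[pos]
            variances[j] = self.fit_.sigma_k2[pos]
        self.effects_ = effects
        self.sigma_k2_ = variances

    def loglik_without(self, j: int) -> float:
        """Converged marginal log-likelihood with selected marker j removed.

        The reduced fit warm-starts from the full solution with marker j's
        contribution deleted, which typically converges in a few EM cycles.
        """
        X, Z, fixed, rand = self._design(drop=j)
        full = self.fit_
        qbase = self.Xs.shape[1]
        full_fixed = [f for f in self.fixed_idx]
        full_rand = [g for g in self.random_idx]
        beta = np.zeros(X.shape[1])
        beta[:qbase] = full.beta[:qbase]
        for pos, f in enumerate(fixed):
            beta[qbase + pos] = full.beta[qbase + full_fixed.index(f)]
        sigma_k2 = np.array([full.sigma_k2[full_rand.index(g)] for g in rand])
        red = emeb_fit(
            self.ys, X, Z, self.r, self.max_iter, self.tol,
            init={"beta": beta, "sigma2": full.sigma2, "sigma_k2": sigma_k2},
        )
        self._last_reduced_ = red
        return red.loglik

    def lrt_table(self) -> pd.DataFrame:
        """Per-marker likelihood ratio tests with full refit of the rest.

        LRT_j = 2 (loglik_full - loglik_without_j); p from chi2(1); LOD =
        LRT / (2 ln 10).  If a reduced fit beats the full fit (local optimum
        of the EM), the full model is refit from the reduced solution —
        EM monotonicity then restores LRT >= 0 up to numerical noise; a
        residual deficit beyond 1e-6 is an error.
        """
        k_sel = self.Zs.shape[1]
        lrt = np.zeros(k_sel)
        for j in range(k_sel):
            ll_red = self.loglik_without(j)
            stat = 2.0 * (self.fit_.loglik - ll_red)
            # negative beyond the likelihood resolution of the EM tolerance
            # signals a refit inconsistency; tiny negatives are clipped
            slack = 1e-6 * max(1.0, abs(self.fit_.loglik))
            if stat < -slack:
                self._refit_from_reduced(j)
                stat = 2.0 * (self.fit_.loglik - ll_red)
            if stat < -slack:
                raise RuntimeError(
                    f"negative LRT {stat:.3g} for selected marker {j}: refit inconsistency"
                )
            lrt[j] = max(stat, 0.0)
        p = stats.chi2.sf(lrt, df=1)
        p = np.where(lrt > 0, p, 1.0)
        return pd.DataFrame({"lrt": lrt, "lod": lrt / _2LN10, "p": p})

    def _refit_from_reduced(self, j: int) -> None:
        """Warm-restart the full fit from the reduced solution for marker j."""
        red = self._last_reduced_
        X, Z, fixed, rand = self._design()
        qbase = self.Xs.shape[1]
        beta = np.zeros(X.shape[1])
        sigma_k2 = np.full(len(rand), 1e-8 * red.sigma2)
        # map reduced-model coefficients back into the full layout
        red_fixed = [f for f in fixed if f != j]
        red_rand = [g for g in rand if g != j]
        beta[: qbase] = red.beta[: qbase]
        for pos, f in enumerate(fixed):
            if f in red_fixed:
                beta[qbase + pos] = red.beta[qbase + red_fixed.index(f)]
        for pos, g in enumerate(rand):
            if g in red_rand:
                sigma_k2[pos] = red.sigma_k2[red_rand.index(g)]
        warm = emeb_fit(
            self.ys,
            X,
            Z,
            self.r,
            self.max_iter,
            self.tol,
            init={"beta": beta, "sigma2": red.sigma2, "sigma_k2": sigma_k2},
        )
        if warm.loglik > self.fit_.loglik:
            self.fit_ = warm
            self._extract_effects()


# ---------------------------------------------------------------------------
# Final calls and goodness of fit
# ---------------------------------------------------------------------------

def final_calls(
    marker_table: pd.DataFrame,
    marker_columns: np.ndarray,
    y: np.ndarray,
    lod_threshold: float = 3.0,
) -> pd.DataFrame:
    """Declared QTNs: markers with LOD >= threshold (inclusive).

    Adds the proportion of phenotypic variance explained,
    r^2 = var(z_k * effect) / var(y), computed from the original-scale
    genotype column of each called marker.
    """
    if len(marker_table) == 0:
        out = marker_table.copy()
        out["r2"] = pd.Series(dtype=float)
        return out
    called = marker_table[marker_table["lod"] >= lod_threshold].copy()
    vy = float(np.var(np.asarray(y, dtype=float), ddof=1))
    r2 = []
    for idx, row in called.iterrows():
        z = marker_columns[:, marker_table.index.get_loc(idx)]
        r2.append(float(np.var(z * row["effect"], ddof=1) / vy) if vy > 0 else np.nan)
    called["r2"] = r2
    return called.reset_index(drop=True)


def bic_goodness_of_fit(
    y: np.ndarray, marker_columns: np.ndarray | None = None
) -> tuple[float, float]:
    """Gaussian multiple regression of y on the called markers, with BIC.

    BIC = -2 loglik + k ln n where k counts the regression coefficients
    (intercept included) plus the residual variance.  Collinear called
    columns are dropped with a warning; with no calls the model is
    intercept-only.  A residual-variance floor guards exact-fit degeneracy.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if marker_columns is None or np.size(marker_columns) == 0:
        M = np.empty((n, 0))
    else:
        M = np.atleast_2d(np.asarray(marker_columns, dtype=float))
        if M.shape[0] != n:
            M = M.T
    # drop collinear columns left to right
    keep: list[int] = []
    for j in range(M.shape[1]):
        trial = np.column_stack([np.ones(n)] + [M[:, i] for i in keep] + [M[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
    if len(keep) < M.shape[1]:
        warnings.warn(
            f"dropped {M.shape[1] - len(keep)} collinear marker column(s) from the "
            "goodness-of-fit regression",
            stacklevel=2,
        )
    X = np.column_stack([np.ones(n)] + [M[:, i] for i in keep])
    res = sm.OLS(y, X).fit()
    vy = float(np.var(y)) if np.var(y) > 0 else 1.0
    sigma2_ml = max(res.ssr / n, 1e-12 * vy)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_ml) + 1.0)
    k = X.shape[1] + 1  # coefficients + residual variance
    bic = -2.0 * loglik + k * np.log(n)
    return float(-loglik), float(bic)
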