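"""scikit-learn style estimators wrapping the association pipeline.

All three estimators follow the sklearn contract: constructor parameters are
stored verbatim, ``fit(G, y)`` validates inputs and exposes results through
trailing-underscore attributes, and ``get_params``/``set_params``/``clone``
work as usual so the estimators compose with sklearn model selection.
``G`` may be a :class:`~mrmlm.containers.GenotypeMatrix` or a plain coded
(n x m) array; an array can be accompanied by ``snp_map=`` in ``fit``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .containers import GenotypeMatrix, build_design
from .pipeline import mrmlm_pipeline
from .scan import fixed_effect_scan, scan_genome

__all__ = ["RandomEffectScan", "FixedEffectScan", "MultiLocusGWAS"]


def _coerce_genotypes(G, snp_map=None) -> GenotypeMatrix:
    if isinstance(G, GenotypeMatrix):
        return G
    return GenotypeMatrix(values=np.asarray(G, dtype=float), snp_map=snp_map)


class _ScanBase(BaseEstimator):
    def _validate(self, G, y, snp_map):
        G = _coerce_genotypes(G, snp_map)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != G.n:
            raise ValueError(
                f"phenotype length {y.shape[0]} does not match {G.n} individuals"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotype contains non-finite values")
        self.n_samples_, self.n_features_in_ = G.n, G.m
        return G, y

    def __sklearn_is_fitted__(self):
        return hasattr(self, "results_") or hasattr(self, "calls_")


class RandomEffectScan(_ScanBase):
    """Single-locus random-SNP-effect mixed-model scan.

    Each marker's effect is treated as a draw from N(0, sigma_k^2); the
    ratio lambda_k = sigma_k^2 / sigma^2 is estimated by profiled REML with
    the polygenic-to-residual ratio fixed from a null-model fit, the effect
    is predicted by BLUP and tested with a Wald statistic against chi2(1).
    Genome-wide significance uses the modified Bonferroni threshold
    alpha / m_e with m_e the effective number of markers.

    Parameters
    ----------
    alpha : genome-wide significance level (default 0.05).
    kinship : precomputed kinship matrix / spectrum, or None to infer a
        VanRaden-type kinship from the genotypes.
    maf_min : minimum minor-allele frequency for a marker to be tested
        (default 1/(2n)).
    me_block_size : block length for the effective-marker-number estimator.

    Attributes
    ----------
    results_ : DataFrame with one record per marker (lambda_k, effect, se,
        wald, p, lod, significant); monomorphic markers carry NaN.
    thresholds_ : ScanThresholds (m_e and alpha / m_e).
    null_ : NullPolygenicFit reused by the scan.
    """

    def __init__(self, alpha=0.05, kinship=None, maf_min=None, me_block_size=133):
        self.alpha = alpha
        self.kinship = kinship
        self.maf_min = maf_min
        self.me_block_size = me_block_size

    def fit(self, G, y, X=None, snp_map=None, null_fit=None):
        G, y = self._validate(G, y, snp_map)
        self.results_, self.thresholds_, self.null_ = scan_genome(
            G,
            y,
            X=X,
            null_fit=null_fit,
            kinship=self.kinship,
            alpha=self.alpha,
            maf_min=self.maf_min,
            me_block_size=self.me_block_size,
        )
        self.m_e_ = self.thresholds_.m_e
        return self


class FixedEffectScan(_ScanBase):
    """EMMA-style fixed-SNP-effect baseline scan.

    Per-marker GLS Wald test with the polygenic ratio fixed from the null
    model and the plain Bonferroni threshold alpha / m.
    """

    def __init__(self, alpha=0.05, kinship=None, maf_min=None):
        self.alpha = alpha
        self.kinship = kinship
        self.maf_min = maf_min

    def fit(self, G, y, X=None, snp_map=None, null_fit=None):
        G, y = self._validate(G, y, snp_map)
        self.results_, self.thresholds_, self.null_ = fixed_effect_scan(
            G,
            y,
            X=X,
            null_fit=null_fit,
            kinship=self.kinship,
            alpha=self.alpha,
            maf_min=self.maf_min,
        )
        return self


class MultiLocusGWAS(_ScanBase):
    """Two-stage multi-locus association mapping.

    Stage 1 runs :class:`RandomEffectScan`; markers with scan p < ``p_select``
    (positionally pruned within ``window_bp``) enter a joint model — fixed
    terms when they pass alpha / m_e with LRT LOD > 1.5, random shrinkage
    terms otherwise — fitted by EM empirical Bayes.  Each selected marker
    gets a likelihood ratio test and markers with LOD >= ``lod_threshold``
    (p <= 0.0002 at the default 3.0) are declared QTNs; no multiple-test
    correction is applied to the multi-locus tests.

    Attributes
    ----------
    scan_results_, thresholds_, null_ : stage-1 products.
    selected_ : preselected marker records.
    marker_tests_ : per-selected-marker effects and LRT/LOD/p.
    calls_ : declared QTNs with variance explained r^2.
    neg_loglik_, bic_ : goodness of fit of the called set.
    """

    def __init__(
        self,
        alpha=0.05,
        p_select=0.01,
        window_bp=1000,
        lod_threshold=3.0,
        include_polygene=True,
        kinship=None,
        maf_min=None,
        me_block_size=133,
        em_max_iter=200,
        em_tol=1e-6,
    ):
        self.alpha = alpha
        self.p_select = p_select
        self.window_bp = window_bp
        self.lod_threshold = lod_threshold
        self.include_polygene = include_polygene
        self.kinship = kinship
        self.maf_min = maf_min
        self.me_block_size = me_block_size
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol

    def fit(self, G, y, X=None, snp_map=None, null_fit=None):
        G, y = self._validate(G, y, snp_map)
        res = mrmlm_pipeline(
            G,
            y,
            X=X,
            kinship=self.kinship,
            null_fit=null_fit,
            alpha=self.alpha,
            p_select=self.p_select,
            window_bp=self.window_bp,
            lod_threshold=self.lod_threshold,
            include_polygene=self.include_polygene,
            em_max_iter=self.em_max_iter,
            em_tol=self.em_tol,
            maf_min=self.maf_min,
            me_block_size=self.me_block_size,
        )
        self.scan_results_ = res.scan
        self.thresholds_ = res.thresholds
        self.null_ = res.null_fit
        self.selected_ = res.selected
        self.marker_tests_ = res.marker_tests
        self.calls_ = res.calls
        self.neg_loglik_ = res.neg_loglik
        self.bic_ = res.bic
        self._G_columns = {m: j for j, m in enumerate(G.snp_map["marker_id"])}
        self._train_mean = float(np.mean(y))
        return self

    def predict(self, G, snp_map=None):
        """Phenotype prediction from the called markers' effects.

        y_hat = train mean + sum over called markers of effect * z; a crude
        genomic-prediction summary of the fitted multi-locus model.
        """
        if not hasattr(self, "calls_"):
            raise RuntimeError("estimator is not fitted")
        G = _coerce_genotypes(G, snp_map)
        yhat = np.full(G.n, self._train_mean)
        cols = {m: j for j, m in enumerate(G.snp_map["marker_id"])}
        for _, row in self.calls_.iterrows():
            j = cols.get(row["marker_id"])
            if j is not None:
                yhat += row["effect"] * G.values[:, j]
        return yhat
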