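"""End-to-end two-stage association pipeline (scan -> multi-locus -> calls)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NullPolygenicFit, ScanThresholds
from .multilocus import (
    MultiLocusModel,
    bic_goodness_of_fit,
    classify_fixed_random,
    final_calls,
    preselect_markers,
)
from .scan import _prepare, scan_genome

__all__ = ["PipelineResult", "mrmlm_pipeline"]


@dataclass
class PipelineResult:
    scan: pd.DataFrame
    thresholds: ScanThresholds
    null_fit: NullPolygenicFit
    selected: pd.DataFrame
    marker_tests: pd.DataFrame
    calls: pd.DataFrame
    neg_loglik: float
    bic: float
    em: object | None = None


_CALL_COLS = ["marker_id", "chrom", "pos", "treated_as", "effect", "sigma_k2", "lrt", "lod", "p"]


def mrmlm_pipeline(
    G,
    y,
    X=None,
    kinship=None,
    null_fit=None,
    alpha: float = 0.05,
    p_select: float = 0.01,
    window_bp: int = 1000,
    lod_threshold: float = 3.0,
    include_polygene: bool = True,
    em_max_iter: int = 200,
    em_tol: float = 1e-6,
    maf_min: float | None = None,
    me_block_size: int = 133,
) -> PipelineResult:
    """Run the full two-stage analysis and return every intermediate product.

    Stage 1 is the random-SNP-effect scan; markers with p < ``p_select``
    survive (positionally pruned within ``window_bp``), are split into fixed
    and random terms, jointly fitted by EM empirical Bayes with the polygenic
    background retained (ratio fixed at the null estimate) unless
    ``include_polygene`` is False, and tested marker by marker; LOD >=
    ``lod_threshold`` declares a QTN.  A multiple-regression BIC of the
    called set measures goodness of fit.
    """
    G, td, spectrum, null_fit, r_scan, mask = _prepare(G, y, X, null_fit, kinship, maf_min)
    scan, thresholds, null_fit = scan_genome(
        G,
        y,
        X=X,
        null_fit=null_fit,
        kinship=spectrum,
        alpha=alpha,
        maf_min=maf_min,
        me_block_size=me_block_size,
    )
    selected = preselect_markers(scan, p_select=p_select, window_bp=window_bp)

    empty_tests = pd.DataFrame(columns=_CALL_COLS)
    if len(selected) == 0:
        nll, bic = bic_goodness_of_fit(np.asarray(y, dtype=float))
        return PipelineResult(
            scan, thresholds, null_fit, selected, empty_tests,
            final_calls(empty_tests, np.empty((G.n, 0)), y, lod_threshold),
            nll, bic,
        )

    col_of = {mid: j for j, mid in enumerate(G.snp_map["marker_id"])}
    sel_idx = [col_of[mid] for mid in selected["marker_id"]]
    Z_orig = G.values[:, sel_idx]
    Zs_sel = td.U.T @ Z_orig
    r = r_scan if include_polygene else np.ones(G.n)

    treated = classify_fixed_random(
        selected, thresholds.p_threshold, td.y_star, td.X_star, Zs_sel, r
    )
    model = MultiLocusModel(
        td.y_star, td.X_star, Zs_sel, treated, r, max_iter=em_max_iter, tol=em_tol
    ).fit()
    tests = model.lrt_table()

    marker_tests = selected[["marker_id", "chrom", "pos"]].reset_index(drop=True).copy()
    marker_tests["treated_as"] = treated
    marker_tests["effect"] = model.effects_
    marker_tests["sigma_k2"] = model.sigma_k2_
    marker_tests[["lrt", "lod", "p"]] = tests[["lrt", "lod", "p"]].to_numpy()

    calls = final_calls(marker_tests, Z_orig, y, lod_threshold)
    called_cols = (
        Z_orig[:, [marker_tests.index[marker_tests["marker_id"] == mid][0] for mid in calls["marker_id"]]]
        if len(calls)
        else None
    )
    nll, bic = bic_goodness_of_fit(np.asarray(y, dtype=float), called_cols)
    return PipelineResult(
        scan, thresholds, null_fit, selected, marker_tests, calls, nll, bic, em=model.fit_
    )
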