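"""Multi-locus stage: preselection, fixed/random split, EMEB, tests, BIC."""

import numpy as np
import pandas as pd
import pytest

from mrmlm import bic_goodness_of_fit, final_calls, preselect_markers
from mrmlm.multilocus import MultiLocusModel, classify_fixed_random, emeb_fit


def _scan_table(rows):
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "p", "effect"])


# -- preselection ------------------------------------------------------------

def test_preselect_prunes_within_window():
    scan = _scan_table([("a", "1", 100, 1e-5, 1.0), ("b", "1", 500, 1e-3, 0.5)])
    sel = preselect_markers(scan, p_select=0.01, window_bp=1000)
    assert list(sel["marker_id"]) == ["a"]


def test_preselect_keeps_distant_markers():
    scan = _scan_table([("a", "1", 1000, 1e-3, 1.0), ("b", "1", 4000, 5e-3, 0.5)])
    sel = preselect_markers(scan, p_select=0.01, window_bp=1000)
    assert sorted(sel["marker_id"]) == ["a", "b"]


def test_preselect_empty_when_nothing_passes():
    scan = _scan_table([("a", "1", 100, 0.02, 1.0), ("b", "1", 500, 0.5, 0.5)])
    assert len(preselect_markers(scan, p_select=0.01, window_bp=1000)) == 0


def test_preselect_chromosome_boundaries_respected():
    scan = _scan_table([("a", "1", 100, 1e-5, 1.0), ("b", "2", 400, 1e-3, 0.5)])
    sel = preselect_markers(scan, p_select=0.01, window_bp=1000)
    assert sorted(sel["marker_id"]) == ["a", "b"]  # different chromosomes


# -- fixed/random classification ---------------------------------------------

def _classification_data(rng, strong=3.0, weak=0.0):
    n = 120
    z1 = rng.binomial(2, 0.3, n) - 1.0
    z2 = rng.binomial(2, 0.3, n) - 1.0
    y = 10 + strong * z1 + weak * z2 + rng.normal(0, 1, n)
    Xs = np.ones((n, 1))
    Zs = np.column_stack([z1, z2])
    return y, Xs, Zs


def test_classify_gate_not_passed_stays_random(rng):
    y, Xs, Zs = _classification_data(rng)
    selected = _scan_table([("a", "1", 100, 1e-9, 1.0), ("b", "1", 5000, 5e-3, 0.1)])
    treated = classify_fixed_random(selected, 1e-4, y, Xs, Zs, np.ones(len(y)))
    assert treated[1] == "random"  # p = 5e-3 fails the 1e-4 gate


def test_classify_strong_marker_becomes_fixed(rng):
    y, Xs, Zs = _classification_data(rng, strong=3.0)
    selected = _scan_table([("a", "1", 100, 1e-9, 1.0), ("b", "1", 5000, 5e-3, 0.1)])
    treated = classify_fixed_random(selected, 1e-4, y, Xs, Zs, np.ones(len(y)))
    assert treated[0] == "fixed"  # huge effect -> LRT LOD far above 1.5


def test_classify_null_marker_stays_random_despite_gate(rng):
    y, Xs, Zs = _classification_data(rng, strong=3.0, weak=0.0)
    # the strong QTN sits in the base design, so the null marker's LRT is
    # pure noise: LOD stays below 1.5 -> random even though it passed the gate
    Xaug = np.column_stack([Xs, Zs[:, 0]])
    selected = _scan_table([("b", "1", 5000, 1e-9, 0.1)])
    treated = classify_fixed_random(selected, 1e-4, y, Xaug, Zs[:, [1]], np.ones(len(y)))
    assert treated[0] == "random"


# -- EM empirical Bayes ------------------------------------------------------

def test_emeb_single_strong_marker_near_ols(rng):
    n = 150
    z = rng.binomial(2, 0.3, n) - 1.0
    y = 10 + 2.0 * z + rng.normal(0, 1, n)
    fit = emeb_fit(y, np.ones((n, 1)), z[:, None])
    ols = np.polyfit(z, y, 1)[0]
    assert fit.gamma[0] == pytest.approx(ols, rel=0.10)


def test_emeb_null_marker_shrinks_to_zero(rng):
    """A zero-effect marker among 20 gets its variance and effect collapsed."""
    n = 150
    effects_null = []
    for _ in range(200):
        Z = rng.binomial(2, 0.3, (n, 20)) - 1.0
        eff = np.zeros(20)
        eff[:5] = 1.5
        y = 10 + Z @ eff + rng.normal(0, 1, n)
        fit = emeb_fit(y, np.ones((n, 1)), Z)
        effects_null.append(abs(fit.gamma[10]))
    assert np.median(effects_null) < 0.05


def test_emeb_no_random_markers_reduces_to_gls(rng):
    n = 40
    z = rng.binomial(2, 0.4, n) - 1.0
    y = 5 + 1.2 * z + rng.normal(0, 1, n)
    X = np.column_stack([np.ones(n), z])
    fit = emeb_fit(y, X, np.zeros((n, 0)))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(fit.beta, coef, atol=1e-8)


def test_emeb_marginal_likelihood_monotone(rng):
    n = 100
    Z = rng.binomial(2, 0.3, (n, 8)) - 1.0
    y = 10 + Z @ np.array([1.5, 0, 0, 1.0, 0, 0, 0, 0.5]) + rng.normal(0, 1, n)
    fit = emeb_fit(y, np.ones((n, 1)), Z, track_loglik=True)
    diffs = np.diff(fit.loglik_path)
    assert np.all(diffs > -1e-8)


# -- per-marker LRT ----------------------------------------------------------

def test_lrt_shrunk_marker_near_zero_and_lod3_conversion(rng):
    n = 150
    Z = rng.binomial(2, 0.3, (n, 3)) - 1.0
    y = 10 + 2.0 * Z[:, 0] + rng.normal(0, 1, n)
    model = MultiLocusModel(
        y, np.ones((n, 1)), Z, ["random", "random", "random"], np.ones(n)
    ).fit()
    tab = model.lrt_table()
    # null markers carry at most noise-level evidence; a fully shrunk one
    # (variance at the floor) contributes nothing at all
    assert tab.loc[1, "lrt"] < 2.0 and tab.loc[2, "lrt"] < 2.0
    assert tab.loc[1, "p"] > 0.1
    if model.sigma_k2_[1] < 1e-6:
        assert tab.loc[1, "lrt"] == pytest.approx(0.0, abs=1e-3)
    assert tab.loc[0, "lod"] > 3.0
    # LOD / p conversion identity on the returned table
    from scipy import stats

    lod3_lrt = 3.0 * 2.0 * np.log(10.0)
    assert stats.chi2.sf(lod3_lrt, 1) == pytest.approx(0.0002, abs=2.5e-6)
    assert np.allclose(tab["lod"], tab["lrt"] / (2 * np.log(10)))


def test_lrt_fixed_marker_tested_by_refit(rng):
    n = 150
    Z = rng.binomial(2, 0.3, (n, 2)) - 1.0
    y = 10 + 2.5 * Z[:, 0] + rng.normal(0, 1, n)
    model = MultiLocusModel(
        y, np.ones((n, 1)), Z, ["fixed", "random"], np.ones(n)
    ).fit()
    tab = model.lrt_table()
    assert tab.loc[0, "lod"] > 3.0
    assert tab.loc[1, "lod"] < 1.0


# -- final calls -------------------------------------------------------------

def _tests_frame():
    return pd.DataFrame(
        {
            "marker_id": ["a", "b", "c"],
            "chrom": ["1"] * 3,
            "pos": [100, 2000, 9000],
            "treated_as": ["fixed", "random", "random"],
            "effect": [2.0, 1.0, 0.5],
            "sigma_k2": [0.0, 0.5, 0.2],
            "lrt": [50.0, 3.01 * 2 * np.log(10), 2.99 * 2 * np.log(10)],
            "lod": [50.0 / (2 * np.log(10)), 3.01, 2.99],
            "p": [1e-10, 1.9e-4, 2.1e-4],
        }
    )


def test_final_calls_lod3_boundary(rng):
    cols = (rng.binomial(2, 0.3, (60, 3)) - 1.0).astype(float)
    y = rng.normal(10, 2, 60)
    calls = final_calls(_tests_frame(), cols, y, lod_threshold=3.0)
    assert sorted(calls["marker_id"]) == ["a", "b"]  # 2.99 excluded, 3.01 kept


def test_final_calls_r2_hand_computation(rng):
    cols = (rng.binomial(2, 0.3, (60, 3)) - 1.0).astype(float)
    y = rng.normal(10, 2, 60)
    calls = final_calls(_tests_frame(), cols, y, lod_threshold=3.0)
    row = calls[calls["marker_id"] == "a"].iloc[0]
    expected = np.var(cols[:, 0] * 2.0, ddof=1) / np.var(y, ddof=1)
    assert row["r2"] == pytest.approx(expected)


def test_final_calls_empty():
    empty = _tests_frame().iloc[0:0]
    calls = final_calls(empty, np.empty((10, 0)), np.zeros(10))
    assert len(calls) == 0


# -- BIC goodness of fit -----------------------------------------------------

def test_bic_intercept_only_closed_form(rng):
    y = rng.normal(3.0, 1.5, 80)
    neg_ll, bic = bic_goodness_of_fit(y)
    s2 = np.var(y)  # ML variance
    ll = -0.5 * 80 * (np.log(2 * np.pi * s2) + 1)
    assert neg_ll == pytest.approx(-ll, abs=1e-8)
    assert bic == pytest.approx(-2 * ll + 2 * np.log(80), abs=1e-8)


def test_bic_noise_column_usually_increases(rng):
    worse = 0
    for _ in range(200):
        y = rng.normal(0, 1, 60)
        _, bic0 = bic_goodness_of_fit(y)
        _, bic1 = bic_goodness_of_fit(y, rng.normal(0, 1, 60))
        worse += bic1 > bic0
    assert worse >= 0.9 * 200  # chi2(1) quantile of ln(60) ~ 0.957


def test_bic_perfect_fit_floored(rng):
    z = rng.normal(0, 1, (30, 2))
    y = 1.0 + z @ np.array([2.0, -1.0])  # exact linear fit, zero residual
    neg_ll, bic = bic_goodness_of_fit(y, z)
    assert np.isfinite(neg_ll) and np.isfinite(bic)


def test_bic_collinear_columns_dropped(rng):
    y = rng.normal(0, 1, 50)
    z = rng.normal(0, 1, 50)
    with pytest.warns(UserWarning, match="collinear"):
        neg_ll, bic = bic_goodness_of_fit(y, np.column_stack([z, z]))
    assert np.isfinite(bic)
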