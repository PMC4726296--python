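"""Single-locus scans: Woodbury algebra, optimisers, tests and thresholds."""

import numpy as np
import pytest
from scipy import stats

from mrmlm import (
    GenotypeMatrix,
    effective_marker_number,
    estimate_beta_sigma2,
    fixed_effect_scan,
    newton_optimize_lambda_k,
    profiled_restricted_loglik,
    scan_genome,
    wald_test,
    woodbury_solve,
)
from mrmlm.null_model import null_restricted_loglik
from mrmlm.scan import blup_gamma

from conftest import dense_reml, random_instance


# -- Woodbury ---------------------------------------------------------------

def test_woodbury_matches_dense(rng):
    r = rng.uniform(0.5, 2.0, 4)
    z = rng.standard_normal(4)
    v = rng.standard_normal(4)
    for lam in (0.0, 0.7, 5.0):
        solve, logdet = woodbury_solve(r, z, lam)
        Sig = lam * np.outer(z, z) + np.diag(r)
        assert np.allclose(solve(v), np.linalg.solve(Sig, v), atol=1e-10)
        assert logdet == pytest.approx(np.linalg.slogdet(Sig)[1], abs=1e-10)


def test_woodbury_zero_lambda_and_zero_marker(rng):
    r = rng.uniform(0.5, 2.0, 5)
    v = rng.standard_normal(5)
    solve0, ld0 = woodbury_solve(r, rng.standard_normal(5), 0.0)
    assert np.allclose(solve0(v), v / r)
    assert ld0 == pytest.approx(np.log(r).sum())
    solvez, ldz = woodbury_solve(r, np.zeros(5), 3.0)
    assert np.allclose(solvez(v), v / r)
    assert ldz == pytest.approx(np.log(r).sum())


def test_woodbury_rejects_nonpositive_diagonal(rng):
    with pytest.raises(ValueError):
        woodbury_solve(np.array([1.0, -0.1]), np.ones(2), 1.0)


# -- profiled restricted likelihood ----------------------------------------

def test_profiled_loglik_matches_dense_oracle(rng):
    for _ in range(20):
        y, X, z, r, td = random_instance(rng, n=6, q=1)
        for lam in (0.0, 0.4, 2.5):
            ll = profiled_restricted_loglik(lam, td, z, r)
            ll_dense, _, _ = dense_reml(lam, y, X, z, r)
            assert ll == pytest.approx(ll_dense, abs=1e-8)


def test_loglik_at_zero_equals_null_model(rng):
    y, X, z, r, td = random_instance(rng, n=10, q=2)
    # same R expressed through its eigenvalue profile: r = lam*D + 1 with lam=1
    D = r - 1.0
    assert profiled_restricted_loglik(0.0, td, z, r) == pytest.approx(
        null_restricted_loglik(td, D, 1.0), abs=1e-10
    )


def test_strong_marker_raises_loglik(rng):
    n = 60
    z = rng.standard_normal(n)
    y = 3.0 + 2.0 * z + rng.standard_normal(n)
    from mrmlm import transform_data

    td = transform_data(y, np.ones((n, 1)), np.eye(n))
    r = np.ones(n)
    assert profiled_restricted_loglik(1.0, td, z, r) > profiled_restricted_loglik(
        0.0, td, z, r
    )


# -- Newton optimiser -------------------------------------------------------

def test_newton_matches_grid_search(rng):
    for _ in range(10):
        y, X, z, r, td = random_instance(rng, n=15, q=2)
        lam_hat, _ = newton_optimize_lambda_k(td, z, r)
        grid = np.concatenate([[0.0], np.logspace(-6, 4, 2001)])
        vals = [profiled_restricted_loglik(g, td, z, r) for g in grid]
        lam_grid = grid[int(np.argmax(vals))]
        ll_hat = profiled_restricted_loglik(lam_hat, td, z, r)
        assert ll_hat >= max(vals) - 1e-7
        if lam_hat > 0 and lam_grid > 0:
            assert abs(np.log10(lam_hat) - np.log10(lam_grid)) < 1e-2


def test_null_marker_majority_at_boundary(rng):
    n, zero = 80, 0
    for _ in range(60):
        y, X, z, r, td = random_instance(rng, n=n, q=1)
        lam_hat, _ = newton_optimize_lambda_k(td, z, r)
        zero += lam_hat == 0.0
    assert zero > 30  # boundary MLE mass under the null


def test_strong_marker_detected_consistently(rng):
    """A marker explaining 15% of variance at n = 199 gets lambda_k > 0."""
    from mrmlm import transform_data

    n, hits = 199, 0
    for _ in range(200):
        z = rng.binomial(2, 0.3, n) - 1.0
        a = np.sqrt(0.15 / 0.85 / 0.42)  # 15% of total variance, unit residual
        y = 10 + a * z + rng.standard_normal(n)
        td = transform_data(y, np.ones((n, 1)), np.eye(n))
        lam_hat, _ = newton_optimize_lambda_k(td, z, np.ones(n))
        hits += lam_hat > 0
    assert hits >= 190


# -- GLS estimates and BLUP -------------------------------------------------

def test_beta_sigma2_ols_limit(rng):
    y, X, z, r, td = random_instance(rng, n=12, q=2)
    td.X_star[:] = X
    r1 = np.ones(12)
    beta, s2 = estimate_beta_sigma2(0.0, td, z, r1)
    beta_ols, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(beta, beta_ols, atol=1e-10)
    assert s2 == pytest.approx(float(res[0]) / (12 - 2), abs=1e-10)


def test_beta_sigma2_dense_and_scaling(rng):
    y, X, z, r, td = random_instance(rng, n=6, q=1)
    beta, s2 = estimate_beta_sigma2(0.8, td, z, r)
    _, beta_d, s2_d = dense_reml(0.8, y, X, z, r)
    assert np.allclose(beta, beta_d, atol=1e-8)
    assert s2 == pytest.approx(s2_d, abs=1e-8)
    from mrmlm import transform_data

    td2 = transform_data(2.0 * y, X, np.eye(6))
    beta2, s22 = estimate_beta_sigma2(0.8, td2, z, r)
    assert np.allclose(beta2, 2.0 * beta, atol=1e-8)
    assert s22 == pytest.approx(4.0 * s2, rel=1e-8)


def test_blup_zero_lambda_full_shrinkage(rng):
    _, _, z, r, td = random_instance(rng)
    gamma, var = blup_gamma(0.0, td, z, r)
    assert gamma == 0.0 and var == 0.0


def test_blup_large_lambda_approaches_fixed_estimate(rng):
    y, X, z, r, td = random_instance(rng, n=10, q=1)
    gamma_inf, _ = blup_gamma(1e6, td, z, r)
    from mrmlm.scan import _marker_scalars

    t, s, *_ = _marker_scalars(td, z, r)
    assert gamma_inf == pytest.approx(s / t, rel=1e-4)


def test_blup_matches_dense_conditional_expectation(rng):
    y, X, z, r, td = random_instance(rng, n=8, q=1)
    lam = 0.9
    gamma, var = blup_gamma(lam, td, z, r)
    _, beta_d, s2_d = dense_reml(lam, y, X, z, r)
    Si = np.linalg.inv(lam * np.outer(z, z) + np.diag(r))
    gamma_d = lam * z @ Si @ (y - X @ beta_d)
    assert gamma == pytest.approx(gamma_d, abs=1e-8)
    assert var >= 0


# -- Wald test --------------------------------------------------------------

def test_wald_zero_gives_p_one():
    assert wald_test(0.0, 0.0) == (0.0, 1.0, 0.0)


def test_lod3_is_p_00002():
    w = 6.0 * np.log(10.0)
    _, p, lod = wald_test(np.sqrt(w), 1.0)
    assert lod == pytest.approx(3.0)
    assert p == pytest.approx(0.0002, abs=2.5e-6)  # prints as 0.0002


def test_wald_chi2_quantile():
    _, p, _ = wald_test(np.sqrt(3.841459), 1.0)
    assert p == pytest.approx(0.05, abs=1e-6)


def test_wald_inconsistent_record_rejected():
    with pytest.raises(ValueError):
        wald_test(1.0, 0.0)


# -- effective number of markers -------------------------------------------

def test_me_independent_markers(rng):
    values = rng.binomial(2, 0.4, size=(500, 50)) - 1.0
    G = GenotypeMatrix(values=values.astype(float))
    m_e = effective_marker_number(G)
    assert abs(m_e / 50 - 1.0) < 0.10


def test_me_duplicated_marker_counts_once(rng):
    z = (rng.binomial(2, 0.4, 60) - 1.0).astype(float)
    w = (rng.binomial(2, 0.4, 60) - 1.0).astype(float)
    values = np.column_stack([z, z, z, w])
    m_e = effective_marker_number(GenotypeMatrix(values=values))
    # eigenvalues of the correlation matrix: ~{3, 1, 0, 0} -> ~2 effective
    assert m_e == pytest.approx(2.0, abs=0.2)


def test_me_single_marker(rng):
    values = (rng.binomial(2, 0.4, 30) - 1.0).astype(float)[:, None]
    assert effective_marker_number(GenotypeMatrix(values=values)) == 1.0


def test_me_invariances(rng):
    values = (rng.binomial(2, 0.4, size=(80, 20)) - 1.0).astype(float)
    base = effective_marker_number(values)
    flipped = values.copy()
    flipped[:, 3] *= -1.0
    assert effective_marker_number(flipped) == pytest.approx(base, abs=1e-8)
    perm = rng.permutation(20)
    assert effective_marker_number(values[:, perm]) == pytest.approx(base, abs=1e-8)


# -- whole-genome scans ------------------------------------------------------

def _sim_scan_data(rng, n=120, m=300, effect=None, qtn=150):
    import mrmlm

    cfg = mrmlm.SimulationConfig(n=n, m=m, qtn_h2=())
    G, _ = mrmlm.simulate_genotypes(cfg, rng)
    y = 10.0 + rng.normal(0, 1.0, n)
    if effect:
        y = y + effect * G.values[:, qtn]
    return G, y


def test_strong_qtn_has_smallest_p(rng):
    G, y = _sim_scan_data(rng, effect=1.5)
    df, thr, _ = scan_genome(G, y)
    assert int(np.nanargmin(df["p"].to_numpy())) == 150


def test_scan_deterministic(rng):
    G, y = _sim_scan_data(rng, effect=0.5)
    df1, _, _ = scan_genome(G, y)
    df2, _, _ = scan_genome(G, y)
    assert df1.equals(df2)


def test_permuted_phenotype_rarely_significant(rng):
    G, y = _sim_scan_data(rng, effect=1.0)
    clean = 0
    for _ in range(40):
        df, thr, _ = scan_genome(G, rng.permutation(y))
        clean += not df["significant"].any()
    assert clean >= 38


def test_monomorphic_markers_get_nan(rng):
    G, y = _sim_scan_data(rng)
    G.values[:, 7] = 1.0
    G.monomorphic[7] = True
    df, _, _ = scan_genome(G, y)
    assert np.isnan(df.loc[7, "p"])
    assert not df.loc[7, "significant"]


def test_phenotype_length_mismatch(rng):
    G, y = _sim_scan_data(rng)
    with pytest.raises(ValueError):
        scan_genome(G, y[:-1])


def test_fixed_scan_matches_dense_gls(rng):
    """Fixed-effect per-marker estimate equals the dense GLS solution."""
    G, y = _sim_scan_data(rng, n=30, m=60, effect=0.8, qtn=30)
    df, thr, null = fixed_effect_scan(G, y)
    from mrmlm import compute_kinship, eigendecompose_kinship

    spec = eigendecompose_kinship(compute_kinship(G))
    V = null.lambda_hat * spec.K + np.eye(30)
    Vi = np.linalg.inv(V)
    for j in (5, 30, 51):
        W = np.column_stack([np.ones(30), G.values[:, j]])
        coef = np.linalg.solve(W.T @ Vi @ W, W.T @ Vi @ y)
        assert df.loc[j, "effect"] == pytest.approx(coef[1], abs=1e-8)


def test_fixed_scan_bonferroni_threshold(rng):
    G, y = _sim_scan_data(rng)
    _, thr, _ = fixed_effect_scan(G, y, alpha=0.05)
    assert thr.p_threshold == pytest.approx(0.05 / thr.m)


def test_bonferroni_five_e_minus_eight():
    from mrmlm import ScanThresholds

    thr = ScanThresholds(m_e=1_000_000.0, alpha_genome=0.05, m=1_000_000)
    assert thr.p_threshold == pytest.approx(5e-8)


def test_random_scan_shrinks_relative_to_fixed(rng):
    """|BLUP| <= |fixed GLS estimate| marker by marker on identical data."""
    G, y = _sim_scan_data(rng, effect=1.0)
    dfr, _, null = scan_genome(G, y)
    dff, _, _ = fixed_effect_scan(G, y, null_fit=null)
    ok = np.isfinite(dfr["effect"]) & np.isfinite(dff["effect"])
    assert np.all(np.abs(dfr.loc[ok, "effect"]) <= np.abs(dff.loc[ok, "effect"]) + 1e-10)


def test_modified_bonferroni_supersedes_plain(rng):
    """Anything significant at 0.05/m is significant at 0.05/m_e (m_e <= m)."""
    G, y = _sim_scan_data(rng, effect=1.2)
    df, thr, _ = scan_genome(G, y)
    assert thr.m_e <= thr.m
    plain = df["p"] <= 0.05 / thr.m
    assert np.all(df.loc[plain, "significant"])
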