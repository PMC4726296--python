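"""Shared fixtures and dense-matrix oracles for the test suite."""

import numpy as np
import pytest

from mrmlm.kinship import transform_data


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def dense_reml(lam_k, y, X, z, r):
    """Brute-force restricted likelihood with explicit n x n inverses.

    Independent of the Woodbury/profiled implementation: builds
    Sigma = lam_k zz' + diag(r) densely and profiles beta, sigma^2.
    """
    n, q = X.shape
    Sig = lam_k * np.outer(z, z) + np.diag(r)
    Si = np.linalg.inv(Sig)
    A = X.T @ Si @ X
    beta = np.linalg.solve(A, X.T @ Si @ y)
    resid = y - X @ beta
    Q = float(resid @ Si @ resid)
    s2 = Q / (n - q)
    _, ld_S = np.linalg.slogdet(Sig)
    _, ld_A = np.linalg.slogdet(A)
    ll = -0.5 * ((n - q) * (np.log(s2) + 1 + np.log(2 * np.pi)) + ld_S + ld_A)
    return ll, beta, s2


def random_instance(rng, n=12, q=2, r_scale=(0.5, 3.0)):
    """A small random marker-test instance in already-rotated coordinates."""
    X = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))]) if q > 1 else np.ones((n, 1))
    y = 1.0 + 2.0 * rng.standard_normal(n)
    z = rng.standard_normal(n)
    r = rng.uniform(*r_scale, n)
    td = transform_data(y, X, np.eye(n))
    return y, X, z, r, td


@pytest.fixture
def toy_instance(rng):
    return random_instance(rng, n=6, q=1)
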