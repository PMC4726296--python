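"""Marker-inferred kinship, its spectral decomposition, and the whitening rotation."""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix, KinshipSpectrum, TransformedData

__all__ = ["compute_kinship", "eigendecompose_kinship", "transform_data"]


def vanraden_kinship(values: np.ndarray) -> np.ndarray:
    """VanRaden-type kinship: centred cross-product scaled to mean diagonal 1.

    K = Z_c Z_c' / c with Z_c the column-centred coded genotypes and
    c = trace(Z_c Z_c') / n.  K is PSD by construction and K @ 1 = 0.
    """
    Zc = values - values.mean(axis=0, keepdims=True)
    G = Zc @ Zc.T
    c = np.trace(G) / G.shape[0]
    if c <= 0:
        raise ValueError("no genotypic variation: cannot build kinship")
    return G / c


def compute_kinship(G: GenotypeMatrix | np.ndarray, method="vanraden") -> np.ndarray:
    """Kinship matrix from the polymorphic markers of a genotype matrix.

    ``method`` may be ``"vanraden"`` or a callable mapping an n x m coded
    matrix to an n x n PSD matrix (pluggable strategy).
    """
    if isinstance(G, GenotypeMatrix):
        mask = ~G.monomorphic
        if not mask.any():
            raise ValueError("zero polymorphic markers: cannot build kinship")
        values = G.values[:, mask]
    else:
        values = np.asarray(G, dtype=float)
        if values.std(axis=0).max() == 0:
            raise ValueError("zero polymorphic markers: cannot build kinship")
    if callable(method):
        return np.asarray(method(values), dtype=float)
    if method == "vanraden":
        return vanraden_kinship(values)
    raise ValueError(f"unknown kinship method {method!r}")


def eigendecompose_kinship(K: np.ndarray, tol: float = 1e-8) -> KinshipSpectrum:
    """Eigen decomposition K = U diag(D) U' with PSD repair.

    Asymmetry beyond ``tol`` (relative to ||K||) is an error, as are negative
    eigenvalues below ``-tol * max|eigenvalue|``; tiny negatives are clipped
    to zero.  Eigenvalues are returned in descending order.
    """
    K = np.asarray(K, dtype=float)
    scale = max(1.0, np.abs(K).max())
    if np.abs(K - K.T).max() > tol * scale:
        raise ValueError("kinship matrix is not symmetric")
    K = (K + K.T) / 2.0
    D, U = np.linalg.eigh(K)
    if D.min() < -tol * max(1.0, np.abs(D).max()):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {D.min():.3g})")
    D = np.clip(D, 0.0, None)
    order = np.argsort(D)[::-1]
    return KinshipSpectrum(K=K, U=U[:, order], D=D[order])


def transform_data(y: np.ndarray, X: np.ndarray, U: np.ndarray) -> TransformedData:
    """Rotate phenotype and design by the kinship eigenvectors.

    The rotation is orthogonal (norms are preserved) and diagonalises the
    polygenic covariance: Var(U'u) = sigma_g^2 diag(D).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match phenotype length")
    if U.shape != (y.shape[0], y.shape[0]):
        raise ValueError("U must be n x n with n matching the phenotype")
    return TransformedData(y_star=U.T @ y, X_star=U.T @ X, U=U)
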