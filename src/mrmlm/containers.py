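"""Core data containers shared by every stage of the association pipeline.

The pipeline works on a coded biallelic genotype matrix (entries 1, 0, -1 for
the two homozygotes and the heterozygote), a phenotype vector, an optional
fixed-effect design with a mandatory intercept, and the spectral decomposition
of a marker-inferred kinship matrix.  The eigen rotation by the kinship
eigenvectors turns the polygenic covariance into a diagonal matrix, which is
what makes the per-marker restricted likelihoods cheap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipSpectrum",
    "TransformedData",
    "NullPolygenicFit",
    "ScanThresholds",
    "build_design",
]


def _as_snp_map(snp_map, m: int) -> pd.DataFrame:
    """Normalise a SNP map to a DataFrame with marker_id, chrom, pos columns."""
    if snp_map is None:
        snp_map = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(m)],
                "chrom": ["1"] * m,
                "pos": np.arange(1, m + 1, dtype=np.int64),
            }
        )
    snp_map = pd.DataFrame(snp_map).reset_index(drop=True)
    required = {"marker_id", "chrom", "pos"}
    if not required.issubset(snp_map.columns):
        raise ValueError(f"snp_map must have columns {sorted(required)}")
    if len(snp_map) != m:
        raise ValueError(f"snp_map has {len(snp_map)} rows for {m} markers")
    if snp_map["marker_id"].duplicated().any():
        dup = snp_map["marker_id"][snp_map["marker_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate marker id {dup!r}")
    snp_map["chrom"] = snp_map["chrom"].astype(str)
    snp_map["pos"] = snp_map["pos"].astype(np.int64)
    return snp_map


@dataclass
class GenotypeMatrix:
    """An n x m coded marker matrix with its SNP map.

    ``values`` holds the coded (and, if needed, imputed) genotypes; raw coded
    entries are in {1, 0, -1}, imputed entries may be fractional.  Positions
    are 1-based and must be strictly increasing within a chromosome.
    """

    values: np.ndarray
    snp_map: pd.DataFrame = None
    sample_ids: Sequence[str] = None
    monomorphic: np.ndarray = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x markers)")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 individuals and 1 marker")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("genotype matrix contains non-finite entries")
        self.snp_map = _as_snp_map(self.snp_map, m)
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]
        self.sample_ids = list(map(str, self.sample_ids))
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match genotype rows")
        for chrom, grp in self.snp_map.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing within chromosome {chrom}"
                )
        if self.monomorphic is None:
            self.monomorphic = np.asarray(self.values.std(axis=0) == 0.0)
        self.monomorphic = np.asarray(self.monomorphic, dtype=bool)
        if self.monomorphic.shape != (m,):
            raise ValueError("monomorphic flag vector has wrong length")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker from the {1,0,-1} coding."""
        p = (self.values.mean(axis=0) + 1.0) / 2.0
        return np.minimum(p, 1.0 - p)

    def polymorphic_mask(self, maf_min: float | None = None) -> np.ndarray:
        """Markers retained for testing: not monomorphic and MAF >= maf_min."""
        if maf_min is None:
            maf_min = 1.0 / (2.0 * self.n)
        return (~self.monomorphic) & (self.maf() >= maf_min)


@dataclass
class KinshipSpectrum:
    """A kinship matrix together with its eigenvectors and eigenvalues.

    ``U @ diag(D) @ U.T`` reconstructs ``K``; eigenvalues are nonnegative
    (tiny negatives are clipped during decomposition) and sorted descending.
    """

    K: np.ndarray
    U: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n) or self.U.shape != (n, n) or self.D.shape != (n,):
            raise ValueError("inconsistent kinship spectrum shapes")

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class TransformedData:
    """Phenotype and design rotated by the kinship eigenvectors.

    After rotation the polygenic covariance is lambda * diag(D) + I, so every
    downstream covariance is diagonal plus a rank-one marker term.  Marker
    columns are rotated on demand with :meth:`transform_markers`.
    """

    y_star: np.ndarray
    X_star: np.ndarray
    U: np.ndarray

    def __post_init__(self):
        self.y_star = np.asarray(self.y_star, dtype=float).ravel()
        self.X_star = np.asarray(self.X_star, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        n = self.y_star.shape[0]
        if self.X_star.ndim != 2 or self.X_star.shape[0] != n:
            raise ValueError("X_star must be n x q")
        if self.U.shape != (n, n):
            raise ValueError("U must be n x n")

    @property
    def n(self) -> int:
        return self.y_star.shape[0]

    @property
    def q(self) -> int:
        return int(np.linalg.matrix_rank(self.X_star))

    def transform_markers(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] != self.n:
            if Z.shape[1] == self.n:  # allow a single marker given as a row
                Z = Z.T
            else:
                raise ValueError("marker matrix rows must match sample size")
        return self.U.T @ Z


@dataclass
class NullPolygenicFit:
    """REML fit of the pure polygenic null model.

    ``lambda_hat`` is the polygenic-to-residual variance ratio held fixed for
    every subsequent marker scan (population parameters previously defined).
    """

    lambda_hat: float
    sigma_g2: float
    sigma2: float
    restricted_loglik: float
    bounds_hit: bool = False
    degenerate: bool = False

    def __post_init__(self):
        if self.lambda_hat < 0:
            raise ValueError("lambda_hat must be nonnegative")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not np.isfinite(self.restricted_loglik):
            raise ValueError("restricted log-likelihood must be finite")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "lambda_hat": self.lambda_hat,
                    "sigma_g2": self.sigma_g2,
                    "sigma2": self.sigma2,
                    "restricted_loglik": self.restricted_loglik,
                    "bounds_hit": self.bounds_hit,
                    "degenerate": self.degenerate,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "NullPolygenicFit":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ScanThresholds:
    """Genome-wide significance thresholds for a single-locus scan."""

    m_e: float
    alpha_genome: float = 0.05
    m: int | None = None

    def __post_init__(self):
        if not (self.m_e >= 1.0):
            raise ValueError("effective marker number must be >= 1")
        if self.m is not None and self.m_e > self.m + 1e-9:
            raise ValueError("effective marker number cannot exceed marker count")
        if not (0 < self.alpha_genome < 1):
            raise ValueError("alpha_genome must be in (0, 1)")

    @property
    def p_threshold(self) -> float:
        return self.alpha_genome / self.m_e


def build_design(n: int, covariates: np.ndarray | None = None) -> np.ndarray:
    """Fixed-effect design with a mandatory intercept column.

    ``covariates`` (e.g. population-structure axes) are appended after the
    intercept.  A rank-deficient design raises unless the deficiency is an
    accidental duplicate of the intercept, which is dropped with a warning.
    """
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            if C.shape[1] == n:
                C = C.T
            else:
                raise ValueError("covariate rows must match sample size")
        X = np.hstack([X, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear covariates in fixed-effect design", stacklevel=2)
    return X
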