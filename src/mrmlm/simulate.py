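"""Synthetic genotype/phenotype generator and method-evaluation harness.

The generator emulates the Monte Carlo designs used to benchmark the
single-locus and multi-locus scans:

* experiment 1 — six additive QTNs at allele frequency 0.30 with variance
  fractions (0.10, 0.05, 0.05, 0.15, 0.05, 0.05), trait mean 10.0 and
  residual variance 10.0;
* experiment 2 — experiment 1 plus an additive polygenic component explaining
  0.092 of the phenotypic variance, drawn from MVN(0, sigma_pg^2 K) with K
  the marker-inferred kinship of the simulated genotypes;
* experiment 3 — experiment 1 plus three epistatic (product-coded) pairs,
  each explaining 0.05 of the phenotypic variance (0.15 collectively);
* experiment 4 — the polygenic design analysed at sample sizes 199/149/99.

Genotypes are Gaussian-copula haplotypes with latent AR(1) correlation along
the chromosome (default rho = 0.7, 500 bp spacing), which stands in for the
local linkage disequilibrium of a real inbred panel.  QTN effect sizes are
back-solved from their variance fractions: with total variance
V_p = resid_var / (1 - sum fractions), a_i = sqrt(f_i V_p / (2 p q)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lfilter

from .containers import GenotypeMatrix
from .kinship import compute_kinship, eigendecompose_kinship

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "experiment_config",
    "simulate_genotypes",
    "derive_qtn_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "evaluate_power",
    "evaluate_type1",
    "evaluate_mse",
    "roc_curves",
    "credit_calls",
]

#: fractional marker positions of the additive QTNs and of the members of the
#: three epistatic pairs (pairs are (e0,e3), (e1,e4), (e2,e5)) -- far enough
#: apart that the 1 kb pruning/crediting windows never overlap
_QTN_FRAC = (0.08, 0.22, 0.36, 0.50, 0.64, 0.78)
_EPI_FRAC = (0.15, 0.29, 0.43, 0.57, 0.71, 0.85)


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated dataset."""

    n: int = 199
    m: int = 2000
    maf: float = 0.30
    qtn_h2: tuple = (0.10, 0.05, 0.05, 0.15, 0.05, 0.05)
    mean: float = 10.0
    resid_var: float = 10.0
    polygenic_h2: float = 0.0
    epistasis_h2: tuple = ()
    ld_rho: float = 0.7
    spacing_bp: int = 500
    background_maf: tuple = (0.05, 0.5)

    def __post_init__(self):
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 and m >= 1")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if any(h < 0 for h in self.qtn_h2) or self.polygenic_h2 < 0:
            raise ValueError("variance fractions must be nonnegative")
        if self.total_fraction >= 1.0:
            raise ValueError("variance fractions must sum to < 1")
        if self.qtn_h2 and self.m < 50:
            raise ValueError("QTN placement needs m >= 50")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")

    @property
    def total_fraction(self) -> float:
        return sum(self.qtn_h2) + self.polygenic_h2 + sum(self.epistasis_h2)

    @property
    def phenotypic_variance(self) -> float:
        """Total variance implied by the residual variance and the fractions."""
        return self.resid_var / (1.0 - self.total_fraction)

    def qtn_indices(self) -> np.ndarray:
        return np.array([int(f * self.m) for f in _QTN_FRAC[: len(self.qtn_h2)]])

    def epistasis_indices(self) -> np.ndarray:
        k = len(self.epistasis_h2)
        idx = np.array([int(f * self.m) for f in _EPI_FRAC])
        return np.column_stack([idx[:k], idx[3 : 3 + k]])


def experiment_config(which: int, n: int = 199, m: int = 2000) -> SimulationConfig:
    """Presets for the four benchmark designs (4 = polygenic design, any n)."""
    if which == 1:
        return SimulationConfig(n=n, m=m)
    if which in (2, 4):
        return SimulationConfig(n=n, m=m, polygenic_h2=0.092)
    if which == 3:
        return SimulationConfig(n=n, m=m, epistasis_h2=(0.05, 0.05, 0.05))
    raise ValueError("experiment must be 1..4")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset (for power/MSE/Type-1 scoring)."""

    qtn_indices: np.ndarray
    qtn_positions: np.ndarray
    qtn_effects: np.ndarray
    epi_pairs: np.ndarray
    epi_effects: np.ndarray = None
    components: dict = field(default_factory=dict)

    def effect_marker_indices(self) -> np.ndarray:
        """All marker indices carrying a simulated effect (additive or pair member)."""
        idx = list(self.qtn_indices)
        if self.epi_pairs is not None and np.size(self.epi_pairs):
            idx.extend(np.asarray(self.epi_pairs).ravel())
        return np.unique(np.asarray(idx, dtype=int))


def simulate_genotypes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw an n x m coded genotype matrix with local LD and HWE margins.

    Two haplotypes per individual share nothing; within a haplotype the
    latent Gaussian is AR(1) with coefficient ``ld_rho``, thresholded at the
    per-marker allele-frequency quantile.  QTN (and epistatic-member) columns
    have their allele frequency pinned at ``cfg.maf`` inside the copula, so
    they keep LD with their neighbours.
    """
    n, m, rho = cfg.n, cfg.m, cfg.ld_rho
    freqs = rng.uniform(*cfg.background_maf, size=m)
    qtn_idx = cfg.qtn_indices() if cfg.qtn_h2 else np.array([], dtype=int)
    epi_pairs = cfg.epistasis_indices() if cfg.epistasis_h2 else np.array([], dtype=int).reshape(0, 2)
    special = np.unique(np.concatenate([qtn_idx, epi_pairs.ravel()]).astype(int)) if (
        qtn_idx.size or epi_pairs.size
    ) else np.array([], dtype=int)
    freqs[special] = cfg.maf

    eps = rng.standard_normal((2, n, m))
    if rho > 0:
        w = eps * np.sqrt(1.0 - rho * rho)
        w[..., 0] = eps[..., 0]
        latent = lfilter([1.0], [1.0, -rho], w, axis=-1)
    else:
        latent = eps
    thresh = stats.norm.ppf(freqs)
    alleles = (latent < thresh[None, None, :]).astype(float)
    values = alleles[0] + alleles[1] - 1.0  # {0,1,2} counts coded to {-1,0,1}

    # a monomorphic special column cannot carry its variance fraction: redraw it
    for j in special:
        tries = 0
        while np.std(values[:, j]) == 0 and tries < 20:
            col = rng.binomial(2, cfg.maf, size=n).astype(float) - 1.0
            values[:, j] = col
            tries += 1

    pos = 1 + cfg.spacing_bp * np.arange(m, dtype=np.int64)
    snp_map = pd.DataFrame(
        {"marker_id": [f"snp{j}" for j in range(m)], "chrom": ["1"] * m, "pos": pos}
    )
    G = GenotypeMatrix(values=values, snp_map=snp_map)
    truth = SimulationTruth(
        qtn_indices=qtn_idx,
        qtn_positions=pos[qtn_idx] if qtn_idx.size else np.array([], dtype=int),
        qtn_effects=derive_qtn_effects(cfg),
        epi_pairs=epi_pairs,
    )
    return G, truth


def derive_qtn_effects(cfg: SimulationConfig) -> np.ndarray:
    """Additive QTN effects back-solved from their variance fractions.

    Under the {1, 0, -1} coding a QTN at allele frequency p contributes
    variance a^2 * 2 p q, so a_i = sqrt(f_i * V_p / (2 p q)).
    """
    if not cfg.qtn_h2:
        return np.zeros(0)
    two_pq = 2.0 * cfg.maf * (1.0 - cfg.maf)
    vp = cfg.phenotypic_variance
    return np.sqrt(np.asarray(cfg.qtn_h2) * vp / two_pq)


def simulate_phenotypes(
    G: GenotypeMatrix,
    truth: SimulationTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    spectrum=None,
) -> np.ndarray:
    """Phenotypes y = mean + sum a_i z_i + sum e_j (z_j1 * z_j2) + u + eps.

    The epistatic effect of each pair is scaled per replicate so the product
    column contributes exactly its variance fraction of V_p; the polygenic
    variance is f_pg * V_p * (n-1)/n so the *expected sample variance* of the
    drawn polygenic vector hits its fraction (the kinship has unit mean
    diagonal and rows summing to zero).  Component vectors are stored on
    ``truth.components`` for generator-faithfulness checks.
    """
    n = G.n
    vp = cfg.phenotypic_variance
    additive = np.zeros(n)
    add_parts = np.zeros((n, len(truth.qtn_indices)))
    for i, (j, a) in enumerate(zip(truth.qtn_indices, truth.qtn_effects)):
        add_parts[:, i] = a * G.values[:, j]
    if add_parts.size:
        additive = add_parts.sum(axis=1)

    epistatic = np.zeros(n)
    epi_effects = np.zeros(len(cfg.epistasis_h2))
    for j, (f, (i1, i2)) in enumerate(zip(cfg.epistasis_h2, truth.epi_pairs)):
        w = G.values[:, i1] * G.values[:, i2]
        vw = np.var(w, ddof=1)
        if vw <= 0:
            raise RuntimeError("degenerate epistatic product column")
        epi_effects[j] = np.sqrt(f * vp / vw)
        epistatic += epi_effects[j] * w
    truth.epi_effects = epi_effects

    polygenic = np.zeros(n)
    if cfg.polygenic_h2 > 0:
        if spectrum is None:
            spectrum = eigendecompose_kinship(compute_kinship(G))
        sigma_pg2 = cfg.polygenic_h2 * vp * (n - 1) / n
        polygenic = spectrum.U @ (
            np.sqrt(sigma_pg2 * spectrum.D) * rng.standard_normal(n)
        )

    residual = rng.normal(0.0, np.sqrt(cfg.resid_var), size=n)
    y = cfg.mean + additive + epistatic + polygenic + residual
    truth.components = {
        "additive": add_parts,
        "epistasis": epistatic,
        "polygenic": polygenic,
        "residual": residual,
    }
    return y


def simulate_dataset(cfg: SimulationConfig, rng: np.random.Generator, spectrum_out=None):
    """Convenience wrapper: genotypes, phenotypes and truth in one call."""
    G, truth = simulate_genotypes(cfg, rng)
    spectrum = None
    if cfg.polygenic_h2 > 0:
        spectrum = eigendecompose_kinship(compute_kinship(G))
        if spectrum_out is not None:
            spectrum_out.append(spectrum)
    y = simulate_phenotypes(G, truth, cfg, rng, spectrum=spectrum)
    return G, y, truth


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def credit_calls(
    call_positions, call_effects, qtn_positions, window_bp: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Match declared markers to true QTNs within ``window_bp``.

    Each call is credited to at most its nearest QTN; a QTN hit by several
    calls keeps the nearest one's effect estimate.  Returns (hit flags,
    credited effect per QTN, 0 when undetected).
    """
    qtn_positions = np.asarray(qtn_positions, dtype=float)
    k = qtn_positions.size
    hits = np.zeros(k, dtype=bool)
    effects = np.zeros(k)
    best_dist = np.full(k, np.inf)
    for pos, eff in zip(np.asarray(call_positions, dtype=float), np.asarray(call_effects, dtype=float)):
        if k == 0:
            break
        d = np.abs(qtn_positions - pos)
        i = int(np.argmin(d))
        if d[i] <= window_bp and d[i] < best_dist[i]:
            hits[i] = True
            effects[i] = eff
            best_dist[i] = d[i]
    return hits, effects


def evaluate_power(
    calls_per_rep, qtn_positions, window_bp: int = 1000
) -> np.ndarray:
    """Per-QTN detection frequency over replicates.

    ``calls_per_rep`` is a sequence of (positions, effects) pairs or call
    DataFrames with ``pos``/``effect`` columns, one per replicate; a QTN
    counts as detected in a replicate when some call lies within
    ``window_bp`` of it.
    """
    k = len(qtn_positions)
    hit_count = np.zeros(k)
    nrep = 0
    for calls in calls_per_rep:
        pos, eff = _calls_arrays(calls)
        hits, _ = credit_calls(pos, eff, qtn_positions, window_bp)
        hit_count += hits
        nrep += 1
    if nrep == 0:
        raise ValueError("no replicates supplied")
    return hit_count / nrep


def _calls_arrays(calls):
    if isinstance(calls, pd.DataFrame):
        return calls["pos"].to_numpy(), calls["effect"].to_numpy()
    pos, eff = calls
    return np.asarray(pos), np.asarray(eff)


def evaluate_type1(significant_per_rep, null_mask) -> float:
    """Empirical Type 1 error pooled over replicates.

    Proportion of significant tests among markers with zero simulated effect
    (``null_mask`` selects those markers).
    """
    null_mask = np.asarray(null_mask, dtype=bool)
    hits = 0
    total = 0
    for flags in significant_per_rep:
        flags = np.asarray(flags, dtype=bool)
        hits += int(flags[null_mask].sum())
        total += int(null_mask.sum())
    if total == 0:
        raise ValueError("no null-marker tests")
    return hits / total


def evaluate_mse(estimates: np.ndarray, true_effects: np.ndarray) -> np.ndarray:
    """Per-QTN mean squared error of the effect estimates across replicates.

    ``estimates`` is replicates x QTNs with 0 for an undetected QTN (the
    shrinkage-consistent convention).
    """
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    true_effects = np.asarray(true_effects, dtype=float)
    return ((estimates - true_effects[None, :]) ** 2).mean(axis=0)


def roc_curves(
    pvalues_per_rep,
    positions,
    qtn_positions,
    null_mask,
    window_bp: int = 1000,
    alphas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Power and Type 1 error swept over 61 significance levels 1e-8..1e-2.

    For each level alpha, a marker is declared when its p-value is <= alpha;
    power and Type 1 error follow the same definitions as above.  Both
    curves are monotone non-decreasing in alpha.
    """
    if alphas is None:
        alphas = np.logspace(-8.0, -2.0, 61)
    positions = np.asarray(positions, dtype=float)
    null_mask = np.asarray(null_mask, dtype=bool)
    qtn_positions = np.asarray(qtn_positions, dtype=float)
    k = qtn_positions.size
    nrep = len(pvalues_per_rep)
    power = np.zeros((len(alphas), k))
    fp = np.zeros(len(alphas))
    for pvals in pvalues_per_rep:
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        for a_i, alpha in enumerate(alphas):
            sig = pvals <= alpha
            fp[a_i] += sig[null_mask].sum()
            if k:
                sig_pos = positions[sig]
                for q_i, qp in enumerate(qtn_positions):
                    if np.any(np.abs(sig_pos - qp) <= window_bp):
                        power[a_i, q_i] += 1
    out = pd.DataFrame({"alpha": alphas, "type1": fp / (nrep * null_mask.sum())})
    for q_i in range(k):
        out[f"power_{q_i + 1}"] = power[:, q_i] / nrep
    if k:
        out["mean_power"] = power.mean(axis=1) / nrep
    return out
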