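# Methods

## Model

For n individuals, phenotype **y**, fixed-effect design **X** (intercept
mandatory, optional population-structure covariates) and coded biallelic
genotypes z<sub>k</sub> ∈ {1, 0, −1}ⁿ (homozygote / heterozygote / other
homozygote; the lexicographically first allele's homozygote is +1), the
single-marker model is

    y = X β + z_k γ_k + u + ε,
    γ_k ~ N(0, σ_k²),   u ~ N(0, σ_g² K),   ε ~ N(0, σ² I).

**K** is a marker-inferred kinship; the default is the VanRaden-type
K = Z<sub>c</sub>Z<sub>c</sub>ᵀ/c with column-centred genotypes and c fixed
so mean(diag K) = 1 (this also gives K·1 = 0, used below).  The kinship
builder is pluggable — any callable producing an n×n PSD matrix can be
substituted.

Writing λ = σ_g²/σ² and λ_k = σ_k²/σ², Var(y) = σ²(λ_k z_k z_kᵀ + λK + I).
λ is estimated once by REML under the pure polygenic null and then held
fixed for the whole scan (the P3D device), so after rotating everything by
the eigenvectors U of K = U D Uᵀ the per-marker covariance is diagonal plus
rank one: Σ_k = λ_k z*z*ᵀ + R with R = λ̂D + I and z* = Uᵀz_k.

## Single-locus scan (random SNP effect)

With the Woodbury identities, every REML quantity for marker k reduces to
three projected scalars (M is the R⁻¹-metric projection removing X*):

    t = z*ᵀR⁻¹Mz*,   s = z*ᵀR⁻¹My*,   Q0 = y*ᵀR⁻¹My*.

In u = λ_k t/(1 + λ_k t) the profiled restricted log-likelihood is

    ℓ(u) = −½[ −log(1−u) + (n−q) log(Q0 − u s²/t) ] + const,

with a unique interior stationary point u* = [(n−q)S − Q0]/[S(n−q−1)],
S = s²/t, whenever the score at zero is positive, else the boundary
λ̂_k = 0.  The vectorised scan uses this closed form directly — it is the
exact argmax the Newton iteration converges to, costs O(1) per marker after
O(nm) preprocessing, and removes any iteration-failure mode from the hot
loop.  A conventional Newton optimiser (Fisher scoring with step halving,
boundary projection, grid+Brent fallback) is kept as a public operation and
is cross-checked against a 2001-point grid and the closed form in the tests.

Given λ̂_k: β̂ and σ̂² are the GLS/REML plug-ins; the BLUP of the marker
effect is γ̂_k = λ̂_k z*ᵀΣ⁻¹(y* − X*β̂) = u·(s/t), with conditional variance
σ̂²·u/t.  The Wald statistic W = γ̂_k²/Var(γ̂_k) then simplifies to
W = λ̂_k t, with p from the χ²₁ upper tail and LOD = W/(2 ln 10), so LOD 3
corresponds to p ≈ 0.0002.  Because γ̂_k/γ̂_fixed = t/(t + 1/λ̂_k) ∈ [0, 1),
the BLUP never exceeds the fixed-effect GLS estimate in magnitude —
shrinkage holds marker by marker, exactly.

**Exact null law and calibration.**  Substituting the stationary condition
into W gives W = max(F − 1, 0) with F ~ F(1, n−q−1) under a Gaussian null —
the scan's Wald statistic is a shifted F.  Per-marker p-values from χ²₁ are
therefore *conservative* (empirically ≈0.6α at α = 0.01 for n = 199, which
the test suite verifies against the shifted-F law).  This deliberate
conservatism is what licenses the lenient m_e-based threshold: the
family-wise error stays controlled even though 0.05/m_e ≫ 0.05/m.

**Thresholds.**  The effective marker number m_e is the Li–Ji eigenvalue
estimator Σ f(λ_i), f(x) = 1(x ≥ 1) + (x − ⌊x⌋), applied to the marker
correlation matrix in consecutive blocks of 133 markers per chromosome
(block evaluation keeps the eigenproblem tractable and local LD dominates
the correction; the estimator is exposed as a strategy).  The scan declares
markers at p ≤ 0.05/m_e; the fixed-effect baseline at p ≤ 0.05/m.  Markers
with MAF < 1/(2n) are treated as monomorphic and reported with NA.

**Fixed-effect baseline.**  The EMMA-style scan uses the same rotation and
fixed λ̂, tests the GLS coefficient per marker, and refers the statistic to
its exact F(1, n−q−1) distribution (χ²₁ would be slightly anticonservative
at these n).

## Multi-locus stage

Markers with scan p < 0.01 survive, pruned greedily in ascending-p order so
that no two selected markers lie within the window (±1 kb simulated / ±20 kb
real; positions are 1-based, windows closed).  Selected markers that also
pass 0.05/m_e receive a single-marker LRT (the marker as a fixed effect vs
not, λ fixed at λ̂; ML likelihoods, since REML values are not comparable
across different fixed-effect designs): LOD > 1.5 ⇒ fixed effect, else
random.  The polygenic term is retained in the stage-2 model with λ fixed
at λ̂ (`include_polygene=False` switches to an i.i.d. residual).

The joint model y* = X*β + Σ_k z*_k γ_k + e, γ_k ~ N(0, σ_k²),
e ~ N(0, σ²R), is fitted by EM empirical Bayes.  With the scaled-inverse-χ²
hyperparameters (τ, ω) = (−2, 0) the M-step for each effect variance is
σ_k² = E[γ_k² | y] = μ_k² + C_kk, where (μ, C) is the joint posterior from
the E-step; β and σ² are updated by their conditional maximisers, so the
marginal likelihood is non-decreasing across cycles (asserted to 1e−8 in
tests).  Convergence: max parameter change < 1e−6 (relative to σ²), cap 200
cycles; effect variances are floored at 1e−8·σ² (an effect at the floor is
fully shrunk).  Each marker's LRT removes it and re-converges everything
else (full-refit policy), warm-started from the full solution; if a local
optimum makes the LRT negative, the full model is refit from the reduced
solution, which by EM monotonicity restores LRT ≥ 0 up to likelihood
resolution (~1e−6·|ℓ|, the error threshold).  LOD ≥ 3 (inclusive) declares
a QTN; declared markers report r² = var(z_k γ̂_k)/var(y).  Goodness of fit
of the called set is an ordinary multiple regression with
BIC = −2ℓ + k ln n, k counting all coefficients plus the residual variance,
with collinear columns dropped and a residual floor of 1e−12·var(y) against
exact fits.

## Synthetic data generator

The generator emulates the benchmark designs on which the two-stage method
is scored; defaults are the design values: n = 199; six additive QTNs at
allele frequency 0.30 with variance fractions (0.10, 0.05, 0.05, 0.15,
0.05, 0.05); trait mean 10.0; residual variance 10.0; optionally a
polygenic component at fraction 0.092 and/or three epistatic (product-coded)
pairs at 0.05 each.  Total variance is V_p = σ²/(1 − Σ fractions) and
additive effects are back-solved as a_i = √(f_i V_p / 2pq) (e.g. QTN4:
√(0.15·18.18/0.42) ≈ 2.548).

Genotypes are Gaussian-copula haplotypes: two independent haplotypes per
individual, latent AR(1) correlation ρ = 0.7 along the chromosome, 500 bp
marker spacing, background allele frequencies ~ U(0.05, 0.5); QTN and
epistatic-member columns have their allele frequency pinned at 0.30 inside
the copula, so they keep LD with their neighbours.  m defaults to 2000
markers (≈1 Mb), the scale at which the full Monte Carlo loops stay
desk-sized.  What this emulates: HWE margins, exponentially decaying local
LD, a realistic MAF spectrum.  What it does not: long-range LD and
population structure of real panels, selfing/inbreeding excess
homozygosity, genotyping error and missingness.  Passing the Monte Carlo
suite therefore demonstrates correct behaviour under clean local-LD
genetics, not performance on any particular real panel (real coded
genotypes can be imported through the same interfaces).

Per-replicate calibrations: epistatic effects are rescaled to the empirical
variance of the product column, so each pair contributes exactly its
fraction of V_p; the polygenic variance is σ_pg² = f·V_p·(n−1)/n because,
with mean(diag K) = 1 and K·1 = 0, E[sample var of u] = σ_pg²·n/(n−1) —
this makes the *expected realized* fraction exact.  Additive and residual
components use unbiased sample variances and need no correction.  The mean
realized per-replicate ratio component-variance/var(y) still carries a
small O(1/n) upward ratio bias (≈+0.5% of a 0.15 target at n = 199), a
property of ratio averaging rather than of the generator.

## Evaluation harness

Power per QTN is the fraction of replicates with a declared marker within
±1 kb (each call credited to its nearest QTN only); Type 1 error pools
significant zero-effect markers over all replicates (markers carrying any
simulated effect are excluded); per-QTN MSE averages (γ̂ − γ)², with an
undetected QTN contributing γ̂ = 0 (the shrinkage-consistent convention; a
skip-undetected variant is a one-line change in the caller).  ROC curves
sweep 61 log-spaced significance levels from 1e−8 to 1e−2.  The
sample-size study (199/149/99) analyses nested subsamples of each
replicate — common random numbers that sharpen the monotonicity comparison
without changing the marginal designs.

## Numerical choices and limitations

* Null REML: coarse log-grid (61 points plus the exact boundary λ = 0) with
  Brent refinement over λ ∈ [1e−5, 1e5]; boundary hits warn; constant
  eigenvalue spectra (K ∝ I) are flagged degenerate and return λ = 0.
* Kinship eigenvalues below −1e−8 (relative) are errors; tiny negatives are
  clipped to zero.
* A single variance ratio at n ≈ 100–200 is intrinsically noisy: the REML
  sampling distribution of λ̂ at n = 100 with λ = 1 spans roughly a factor
  of 30 between the 5th and 95th percentiles even under strong family
  structure (verified against a dense-matrix grid oracle); estimates are
  median-centred but individual fits should not be over-interpreted.
* The scan's χ²₁ p-values are conservative by construction (see the exact
  null law above); the package keeps the conventional reference because the
  m_e-corrected threshold is calibrated around exactly this behaviour.
* Multi-trait models, dominance/epistasis terms inside the association
  models, exact per-marker polygenic re-estimation (non-P3D) and VCF/BED
  parsing are out of scope.
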