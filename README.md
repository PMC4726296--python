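# mrmlm — random-SNP-effect and multi-locus mixed linear model GWAS

`mrmlm` is a genome-wide association toolkit for quantitative traits in
structured populations (plant panels, inbred collections, association
panels).  It implements a two-stage strategy:

1. **RMLM** — a single-locus scan that treats each SNP effect γ<sub>k</sub>
   as *random*, γ<sub>k</sub> ~ N(0, σ<sub>k</sub>²), on top of a polygenic
   background **u** ~ N(0, σ<sub>g</sub>²**K**) with marker-inferred kinship
   **K**.  The polygenic-to-residual ratio λ = σ<sub>g</sub>²/σ² is
   estimated once under the null and held fixed (P3D); after rotating by the
   eigenvectors of **K**, each marker costs a one-dimensional profiled-REML
   problem in λ<sub>k</sub> = σ<sub>k</sub>²/σ², solved in closed form via
   Woodbury rank-one algebra.  Effects are predicted by BLUP (shrunken
   towards zero) and tested by a Wald statistic against χ²₁; genome-wide
   significance uses a modified Bonferroni threshold 0.05/m<sub>e</sub>,
   where m<sub>e</sub> is the effective number of markers from the
   eigenvalues of the marker correlation matrix.
2. **MRMLM** — markers with scan p < 0.01 (pruned within ±1 kb for
   simulated maps, ±20 kb for real ones) enter a joint multi-locus model:
   markers that also pass 0.05/m<sub>e</sub> with a single-marker LRT LOD
   > 1.5 become fixed effects, the rest random effects with marker-specific
   variances estimated by EM empirical Bayes.  Each selected marker gets a
   likelihood ratio test; LOD ≥ 3 (p ≤ 0.0002 under χ²₁) declares a QTN —
   no multiple-test correction is needed in the multi-locus model.

An EMMA-style fixed-SNP-effect scan (threshold 0.05/m, i.e. 5×10⁻⁸ at one
million markers) is included as the baseline, together with a Monte Carlo
harness that scores statistical power, per-QTN MSE, Type 1 error and ROC
curves under four benchmark designs (plain six-QTN, +polygenic background,
+epistatic pairs, and varying sample size).

## Worked example

```python
import numpy as np
import mrmlm

rng = np.random.default_rng(1)
cfg = mrmlm.experiment_config(2, n=199, m=2000)   # six QTNs + polygene
G, y, truth = mrmlm.simulate_dataset(cfg, rng)

est = mrmlm.MultiLocusGWAS(window_bp=1000).fit(G, y)
print(est.calls_[["marker_id", "pos", "treated_as", "effect", "lod", "r2"]])
print("true QTN positions:", truth.qtn_positions)
print("true effects:      ", np.round(truth.qtn_effects, 3))
```

prints (numbers from this exact seed):

```
  marker_id     pos treated_as    effect       lod        r2
0    snp160   80001     random  1.754423  3.949694  0.050677
1    snp440  220001     random  1.832347  3.853182  0.054772
2   snp1000  500001      fixed  2.546477  8.137350  0.099209
3   snp1280  640001      fixed  1.560241  3.521855  0.041519
4   snp1560  780001     random  1.868288  3.950920  0.053786
true QTN positions: [ 80001 220001 360001 500001 640001 780001]
true effects:       [2.28  1.612 1.612 2.792 1.612 1.612]
```

Five of the six simulated QTNs are recovered at their exact marker
positions; the largest (h² = 0.15 at 500 001 bp, true effect 2.79) is
declared a fixed effect with estimated effect 2.55 explaining ~10% of the
phenotypic variance, while the weaker QTNs enter as shrunken random effects.
The h² = 0.05 QTN at 360 001 bp is missed in this replicate — expected at
this sample size.  `est.scan_results_` holds the per-marker scan
(λ<sub>k</sub>, BLUP effect, Wald, p, LOD), `est.thresholds_` the
m<sub>e</sub>-based threshold, and `est.bic_` the goodness-of-fit BIC of the
called set.

The same pipeline runs from the shell:

```bash
mrmlm scan  --geno geno.csv --pheno pheno.tsv --out scan_out/
mrmlm mrmlm --geno geno.csv --pheno pheno.tsv --window-kb 20 --out mrmlm_out/
mrmlm simulate --experiment 1 --replicates 100 --methods mrmlm,rmlm,emma --out sim_out/
```

Genotypes are accepted as coded CSV (`marker_id,chrom,pos,<samples…>` with
1/0/−1 codes) or a hapmap-like layout with two-letter calls; every run
writes a JSON manifest (input hashes, thresholds, seeds) sufficient to
reproduce it.

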