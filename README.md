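# introgmap

Analysis of landrace-introgression early-testcross trials: spatially
adjusted yield means, a drought-tolerance index, and mixed-model GWAS for
backcross populations derived from maize landraces.

## Who this is for

Breeders and quantitative geneticists running *introgression* programmes:
a set of landrace donor populations is crossed and backcrossed to an
elite recurrent parent, partially inbred (BC1S1, BC1S2), testcrossed to
an elite tester, and the testcrosses evaluated for grain yield at several
sites under contrasting irrigation treatments (well-watered, WW, and
managed drought, DR). The package covers the full statistical path from
plot-level yields to candidate loci, and ships a simulator that generates
genotypes and field trials with the same structure so every estimator can
be checked against known truth.

## The models

**Stage 1 — spatial adjustment per trial.** Each site x treatment trial is
fitted with the fixed-effects model `y = Xτ + e` where τ holds genotype
effects and optional row/column/replicate factors (retained by Wald
tests), and the residual is separable autoregressive over the field grid
plus an independent nugget:

    R = σ²_ζ · [AR1(ρ_col) ⊗ AR1(ρ_row)] + σ²_η · I

The restricted likelihood is maximised over (ρ_row, ρ_col, σ²_η/σ²_ζ)
with σ²_ζ profiled out; genotype BLUEs and standard errors come from GLS
at the optimum. WW trials are unreplicated augmented designs with
knight-move check plots; DR trials are RCBDs with two replicates.

**Drought-tolerance index.** Per genotype *i* and site *j*, the Harmonic
Mean of Relative Performance combines the two treatments:

    HMRP_ij = 2 / [ (GYww_ij / ȳww_j)⁻¹ + (GYdr_ij / ȳdr_j)⁻¹ ]

Values sit near 1; a genotype must do well in *both* treatments to score
high, and failure in either drags the harmonic mean down.

**Stage 2 — weighted joint model.** `y = Xβ + Zg + Wi + e` with site
fixed, genotype (g) and genotype x site (i) random, and per-record
residual variance proportional to the stage-1 squared standard errors
(for HMRP, the mean of the WW and DR squared SEs). Reported alongside the
REML components: broad-sense heritability
`h² = σ²_g / (σ²_g + σ²_gs/l + σ²_e/(l·r))` for `l` sites and `r`
replicates, BLUP-accuracy from prediction-error variance, CVg/CVe, a Wald
test for site and boundary-corrected LRTs for the random terms.

**GWAS.** Single-marker mixed linear model
`g = Xβ + Zu + e, u ~ N(0, σ²_u G)` with the intercept, three genomic
principal components and one SNP at a time as fixed effects and
VanRaden's genomic relationship matrix `G = WW′ / 2Σp(1−p)`. The variance
ratio is estimated once under the no-SNP null and held fixed across
markers; genome-wide significance comes from the empirical quantile of
minimum p-values over seeded phenotype permutations.

**Post-GWAS.** LD decay per chromosome (Hill–Weir drift expectation of r²
fitted by nonlinear least squares), allele-origin tracing against the
genotyped recurrent parent (the landrace allele is the one the recurrent
parent lacks), family rankings by superior-allele frequency rank-sums,
gene lookups in a ±100 kb window from a local GFF3, and cross-generation
validation `ŷ₂ = Xα₁` scored by Pearson correlation against
next-generation BLUPs.

## Worked example

Simulate a small introgression panel (8 landrace families, 200 BC1S1
lines, 100 SNPs, two planted drought QTL), run the two-stage analysis and
the GWAS:

```python
import numpy as np, pandas as pd
import introgmap as ig

sc = ig.BreedingScenario(n_families=8, lines_per_family=25, n_chromosomes=5,
                         markers_per_chromosome=20, seed=7,
                         qtl=[(12, 1.0, "DR"), (57, 0.8, "both")])
ms, truth = ig.simulate_backcross_genotypes(sc)
ts = ig.TrialScenario(allocation=(40, 40, 40, 80), seed=8)
plots, _ = ig.simulate_trials(ms, ts, sc)

fits = {}
for (site, trt), sub in plots.groupby(["site", "treatment"]):
    spec = ig.select_spatial_factors(sub, alpha=0.05)
    fits[(site, trt)] = ig.fit_spatial_reml(sub, factors=spec.factors)

rows = [(e, site, trt, f.blues[e], f.se[e])
        for (site, trt), f in fits.items() for e in f.blues.index]
blues = pd.DataFrame(rows, columns=["entry", "site", "treatment", "blue", "se"])
dr = blues[(blues.treatment == "DR") & ~blues.entry.isin(ts.check_names)].copy()
dr["weight"] = dr.se ** 2
joint = ig.fit_joint_reml(dr, trait="GYDR", reps=2, value_col="blue")

geno = ig.impute_wright(ms.take_samples(
    [i for i, s in enumerate(ms.samples) if s in joint.blups.index]))
y = joint.blups.loc[geno.samples].to_numpy()
st = ig.StructureModel(pcs=ig.pca_structure(geno, 3).pcs,
                       variance_explained=np.empty(0), grm=ig.grm_vanraden(geno))
scan = ig.mlm_scan(y, geno, st, trait="GYDR")
thr = ig.permutation_threshold(y, geno, st, n_perm=100, seed=9)
print(ig.summarize_scan(scan, geno, thr))
```

Output (abridged):

```
BC1S1 lines: 200, markers: 100, mean donor fraction: 0.253
TL/DR spatial fit: rho_row=0.55 rho_col=0.40 sigma2_spatial=0.30 sigma2_nugget=0.64
GYDR joint fit: sigma_g2=0.1732 h2=0.45 LRT genotype p=4.4e-05
GYDR scan: 100 SNPs, permutation threshold p=1.74e-03, 1 significant
trait snp  chrom      pos  maf   effect  marker_h2  partial_r2
 GYDR M13      1 94736854  0.1 0.159885   0.077594     0.07409
snp superior_origin   effect
M13        landrace 0.159885
```

Reading the numbers: the simulated backcross-selfing scheme leaves the
lines with ~25% donor genome as expected. The TL drought trial shows
strong row-wise autocorrelation (ρ_row = 0.55), which the stage-1 REML
absorbs before computing entry means. In the joint model the genotypes
differ significantly (LRT p ≈ 4e-5) with a genotype-mean heritability of
0.45. The scan flags M13 — the marker carrying the planted drought QTL —
at p below the permutation threshold; its positive substitution effect
(+0.16 Mg·ha⁻¹ per alternative-allele copy) traces to the landrace
donors, because the recurrent parent is homozygous reference there.

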