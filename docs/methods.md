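# Methods

This note documents the statistical models, the simulator, the numerical
choices, and the limitations of `introgmap`.

## Study system and data model

The package targets introgression breeding programmes in maize: landrace
donor populations crossed to a homozygous elite recurrent parent,
backcrossed once, selfed (BC1S1, BC1S2), and evaluated as testcrosses in
multi-site yield trials under well-watered (WW) and drought (DR)
irrigation. Genotypes are stored as alternative-allele dosages in
`MarkerSet` (samples x markers, with a physical map sorted by chromosome
and position; markers named `M1..Mk` in genome order). Quality control
removes markers with minor allele frequency below 5% and call rate below
95% — the MAF test is applied first, so a marker failing both is counted
once, under MAF. Missing calls are imputed from per-marker allele
frequencies, either deterministically (expectation `2p`) or by seeded
Hardy–Weinberg sampling; the deterministic default keeps every downstream
stage reproducible.

## Stage 1: spatial REML per trial

Model: `y = Xτ + e`, `e ~ N(0, R)` with
`R = σ²_ζ [AR1(ρ_col) ⊗ AR1(ρ_row)] + σ²_η I`. Plots are ordered
column-major (row index fastest), which makes the Kronecker order
`AR1(ρ_col) ⊗ AR1(ρ_row)`; the element-wise form
`cor(a,b) = ρ_row^|Δrow| ρ_col^|Δcol|` is ordering-free and the tests
verify both constructions agree.

Numerical strategy:

* σ²_ζ is profiled out analytically; the optimizer works on
  (ρ_row, ρ_col, log λ) with λ = σ²_η/σ²_ζ, bounded to |ρ| < 0.95 and
  |log λ| ≤ 14. Estimates at these bounds are flagged
  (`boundary_flags_`).
* A fixed 3x3x3 grid of starts is evaluated; bounded L-BFGS-B
  (ftol 1e-12) runs from the best three. Fits are therefore
  deterministic given the data.
* On a complete grid the likelihood is evaluated through the
  eigendecompositions of the two AR1 factors (O(R³ + C³) per step);
  trials with missing plots fall back to a dense Cholesky of the observed
  submatrix — observations are dropped and the covariance subsetted
  (conditioning), never imputed. Dense construction refuses grids above
  10⁴ plots.
* Genotype adjusted means use the estimable function
  intercept + genotype effect, averaged over the levels of any other
  fixed factor; SEs come from the REML-scaled GLS covariance.

Row/column fixed factors are chosen by Wald tests at α = 0.05 in the
richest estimable candidate fit ({row+col}, then singles); ties resolve
toward the simpler model, and a retained pair that is jointly
inestimable backs off to the more significant single factor. On small
trials the asymptotic χ² reference for these Wald tests is mildly
anti-conservative; the test suite bounds the null retention rate loosely
rather than asserting exact calibration. Checks are treated as ordinary
fixed entries.

The residual-grid sample variogram (half mean squared difference at each
row/column displacement) is provided as the standard diagnostic for
unmodelled trends.

## The HMRP index and stage 2

`HMRP_ij = 2 / [(GYww_ij/ȳww_j)⁻¹ + (GYdr_ij/ȳdr_j)⁻¹]` with site means
taken over test entries (checks excluded, configurable). Genotypes
missing one treatment at a site, or with a non-positive relative
performance (harmonic mean undefined), are excluded at that site with a
warning rather than imputed.

The joint model `y = Xβ + Zg + Wi + e` has site fixed, genotype and
genotype x site random, and `Var(e_ij) = w_ij σ²_e` with `w_ij` the
stage-1 squared SE (for HMRP, the mean of the WW and DR squared SEs) —
the standard two-stage weighting. Because no random term links records
of different genotypes, the marginal covariance is block-diagonal by
genotype; REML reduces to batched small-matrix solves and runs in
milliseconds for hundreds of genotypes. The optimizer profiles σ²_e and
searches (log θ_g, log θ_gs), θ = variance ratios, from a 3x3 start
grid.

Identifiability: with exactly one record per genotype x site and equal
weights, σ²_gs and σ²_e are confounded (only their sum is identified);
weight variation across records separates them. The recovery study uses
weights log-uniform on [0.25, 4], reflecting the several-fold spread of
squared SEs between unreplicated WW entries and replicated DR entries
across trials with different error variance.

Reported statistics:

* `h² = σ²_g / (σ²_g + σ²_gs/l + σ²_e/(l·r))`, genotype-mean basis;
  `r` is always explicit (2 for the RCBD drought trials, 1 for the
  unreplicated WW trials; no value is assumed for HMRP).
* Accuracy = `100·sqrt(1 − mean(PEV)/σ²_g)` from the BLUP
  prediction-error variance, defined as 0 when σ²_g = 0. The PEV-based
  definition is this package's documented choice; on balanced one-way
  data it matches the closed form `sqrt(n h²_p/(1+(n−1)h²_p))`.
* CVg/CVe = 100·σ/mean.
* LRTs for the random terms use the 50:50 χ²₀/χ²₁ boundary mixture
  (statistic 2.706 gives p = 0.05); the Wald statistic for site tests
  equality of the site means.

## GWAS

Scan model: `g = Xβ + Zu + e` with X = [intercept, k genomic PCs, one
SNP], `u ~ N(0, σ²_u G)`, G the VanRaden GRM from 2p-centred dosages
normalised by `2Σp(1−p)`. PCs come from the 2p-centred dosage matrix
without scaling; k defaults to 3. The variance ratio δ = σ²_e/σ²_u is
REML-estimated once under the no-SNP null and reused for every marker
(population parameters previously determined); a `per_snp_reml` flag
re-estimates it per marker. After rotation by the eigenvectors of G and
whitening by `1/sqrt(s_i + δ)` the per-SNP test is an exact OLS t-test
(n − k − 2 df) computed in one vectorized pass via Frisch–Waugh
partialling; with G = I and no PCs it reduces exactly to the simple
regression t-test, and it matches a dense explicit-V⁻¹ GLS oracle to
1e-14 in the tests. SNPs collinear with the covariates get p = 1,
effect 0, and a flag.

Per-SNP summaries follow the conventional definitions: the
marker-variance share ("marker h²") is `2p(1−p)α̂²/σ̂²_P` and "r²" is the
squared partial correlation `t²/(t²+df)`; both labels are stated in the
output because different toolchains define them differently.

The genome-wide threshold is the empirical α-quantile (lower order
statistic) of minimum scan p-values over `n_perm` seeded phenotype
permutations (default 100, with a warning below 20). Under an
exchangeable null the resulting genome-wide error is `⌈αn⌉/(n+1)` ≈ α by
construction, which the calibration study confirms empirically.

## Post-GWAS

* LD: r² is the squared Pearson correlation of dosage columns, distance
  the physical-map difference; pair subsampling is seeded. The decay
  curve is the Hill–Weir drift expectation
  `E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]`
  with C = β·distance, fitted by nonlinear least squares with β ≥ 0; the
  exact functional form is this package's documented choice. β ≈ 0 data
  report an infinite half-decay distance.
* Allele origin: defined only where the recurrent parent is homozygous
  (heterozygous SNPs are flagged); the landrace allele is the allele the
  recurrent parent lacks, the superior allele follows the sign of the
  substitution effect under alt-dosage coding. The whole construction is
  invariant to re-polarizing a SNP (flipping dosage and effect sign
  jointly).
* Family rankings: per SNP, families are ranked by superior-allele
  frequency (rank 1 = highest, average ranks for ties); families are
  ordered by ascending rank-sum. The `landrace_origin` mode restricts to
  SNPs whose superior allele is landrace-derived.
* Validation: `ŷ₂ = Xα₁` with no intercept or re-centring, since the
  Pearson correlation against next-generation BLUPs is location/scale
  invariant.
* Gene annotation queries a local GFF3 (`gene` features only) in a
  closed ±100 kb window, 1-based inclusive coordinates.

## The simulator

`synthpop` emulates the statistical structure the estimators assume:

* **Genotypes.** Landraces are allele-frequency pools, not fixed lines —
  landrace accessions are heterogeneous open-pollinated populations —
  with per-marker founder frequencies drawn from U(0.1, 0.9). A landrace
  gamete is produced by meiosis between two haplotypes drawn from those
  frequencies; meiosis is a Markov walk along the genetic map with
  Haldane recombination fractions. The default map is 10 chromosomes x
  150 cM with a uniform 1 cM = 1 Mb physical scaling — adequate for
  desk-scale testing, not for fine-scale recombination realism. The
  crossing scheme (F1, backcross, selfing) gives BC1S1 lines an expected
  25% donor genome and 25% heterozygosity at donor-segregating loci,
  which the tests verify against the realized, origin-tracked values.
* **Default scheme.** 20 families x 74 BC1F1 lines; a sparse three-site
  allocation (266/266/265/529) covering 1326 test genotypes; selection
  of 64 fertile lines advanced at 174/64 ears per line to 174 BC1S2
  lines.
* **Trials.** Plot yield = site/treatment mean + testcross genetic value
  (Σ α·dosage/2 per QTL — the line transmits one gamete to the
  testcross — plus a seeded polygenic term) + genotype x site deviation
  + AR1⊗AR1 spatial error + nugget. WW trials are unreplicated with
  knight-move check placements (successive (+1 row, +2 col) steps
  wrapping over the grid — the named pattern, with the arithmetic fixed
  here); DR trials are RCBDs whose blocks are contiguous field spans.
  The tester effect is absorbed into the trial mean (with a single
  tester the tester x genotype interaction is confounded with the
  genotypic value, as in real single-tester first-stage trials).
* Everything is deterministic under a fixed seed, and a truth record
  (genetic values, variance components, true HMRP) accompanies each
  simulation.

What the simulator does **not** emulate: dominance and epistasis,
pedigree-accurate recreation of specific accessions, selection during
seed increase, non-separable or trend-like field effects, and
genotyping-error processes. Passing recovery tests therefore show the
estimators are correct under the stated model, not that the model
captures every feature of real field data.

## Problem sizes used by the recovery studies

Chosen as the smallest sizes at which the targeted parameters are well
identified: a 6x6 trial against a 21³ brute-force likelihood grid; 50
replicates of a 40x30-plot trial (100 genotypes) for autocorrelation
recovery; 30 replicates of 500 genotypes x 3 sites for stage-2 component
recovery; 3 null scans of 300 samples x 400 markers for per-marker
type-I error; 200 null replicates (100 samples x 200 markers, 100
permutations each) for genome-wide calibration; 200 BC1S1 / 174 BC1S2
lines with three planted QTL for the closed-loop validation; 20
replicates of 400 synthetic r²-distance pairs for LD-decay recovery.

## Known limitations

* The stage-1 Wald factor selection is anti-conservative on very small
  trials (asymptotic reference).
* Stage-2 σ²_gs/σ²_e separation relies on weight heterogeneity; with
  near-equal weights only their sum is meaningful and single-replicate
  estimates of the split are noisy.
* The scan is single-marker: nearby markers in LD with a causal locus
  share its signal, so "the QTL or a neighbour within the LD window" is
  the right unit of detection.
* Permutation thresholds assume exchangeability of samples under the
  null; strong unmodelled structure violates this (the PCs + GRM are the
  mitigation).
* The accuracy statistic is PEV-based and not comparable across packages
  that define accuracy differently.
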