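# Methods

## Problem and model

Single-SNP genome-wide association scans miss risk that is spread across
many weakly associated variants. A competitive gene-set analysis asks
whether the genes in a pathway are, as a group, more associated with the
phenotype than the genes outside it. Working from SNP-level p-values raises
two problems that this package addresses parametrically, without
permutation:

1. **Gene-size bias.** If a gene's SNP p-values were independent uniforms,
   the m-th order statistic p_(m) of n p-values is Beta(m, n−m+1) with mean
   m/(n+1): genes with more SNPs have systematically smaller minimum
   p-values, so any summary based on p_(m) (such as the PAGE-style −log
   p_(m)) drifts with gene size and large-gene sets masquerade as enriched.
2. **Linkage disequilibrium.** SNP p-values within a gene are correlated
   through LD, so the SNP count n overstates the number of effectively
   independent tests.

The corrected gene-level measure is

    g_j = (ñ_j + 1) · mean of the m smallest p-values in gene j,

where ñ_j is the *effective gene size* described below. Under independence
(ñ = n) the expectation of g is (m+1)/2 regardless of gene size; m defaults
to 1 and averaging the top m ≤ 5 p-values trades a little size-robustness
for power when several associated SNPs share a gene.

### Effective gene size

Each gene's SNPs (position-sorted) are partitioned into LD blocks by a
greedy sequential rule: a SNP joins the current block iff its squared
dosage correlation r² with *any* SNP already in the block exceeds 0.05,
otherwise it starts a new block. The rule enforces near-independence only
between adjacent blocks; all-pairs cross-block violations are logged, not
repaired. Within blocks the correlation is modelled as exchangeable
(compound symmetry). Three candidate structures are fitted to the
standardized dosages by Gaussian maximum likelihood and compared by
AIC = 2k − 2ℓ:

* IND — identity correlation (0 parameters);
* CS — one exchangeable ρ across the whole gene (1 parameter);
* LD-CS — exchangeable ρ_k per block, zero across blocks (one parameter per
  block of size ≥ 2).

For standardized columns the ML estimate of an exchangeable ρ is the
average pairwise sample correlation clipped to [0, 0.999]; the package uses
this closed form and keeps a bounded 1-d numerical optimizer as a reference
implementation for testing. The [0, 0.999] box also keeps every candidate
positive definite.

The selected structure's blocks yield the effective size
ñ = Σ_k e(b_k, ρ̂_k) over blocks of size b_k. Two per-block forms are
provided:

* `vif` — b/(1 + (b−1)ρ), the effective sample size of a *mean* of b
  exchangeable variables;
* `galwey` (default) — (Σ√λ)²/Σλ over the eigenvalues
  λ = {1+(b−1)ρ, (1−ρ)×(b−1)} of the block's correlation matrix, an
  effective number of *tests*.

Both give ñ = n at ρ = 0 and collapse each block toward one effective SNP
as ρ → 1. The default is the eigenvalue form: in simulations from the
block-exchangeable model itself, the VIF form (which corrects the variance
of a mean, not the behaviour of a minimum) leaves a residual gene-size
trend in the mean of −log g (≈0.27 between 10-SNP and 42-SNP genes) that
makes the set test visibly conservative for small-gene sets (type-I error
~0.005 at nominal 0.05); the eigenvalue form halves the trend and restores
near-nominal error for all gene sizes. The per-block formula is pluggable
(`effective_gene_size(blocks, block_size_fn=...)`).

### Set-level test

For set i with N_i measured genes and the complement C (all other
summarized genes), the statistic is Welch's two-sample t with set-specific
variances,

    t_i = (x̄_i − x̄_c) / sqrt(s_i²/N_i + s_c²/N_c),

with Satterthwaite degrees of freedom

    df_i = (s_i²/N_i + s_c²/N_c)² / [(s_i²/N_i)²/(N_i−1) + (s_c²/N_c)²/(N_c−1)].

The heterogeneous-variance form matters because the measure's variance
depends on gene size and LD, hence differs across sets, most strongly for
small sets. By default the test operates on x = −log g (enrichment = upper
tail, one-sided): the raw measure is bounded below by zero, which caps the
achievable |t| near 1.5 for a 20-gene set and with it the test's power,
whereas the log scale is unbounded in the significant direction and is also
the scale of the Z baseline that the statistic modifies. `scale="natural"`
restores the untransformed version (lower tail). The comparison group
excludes the tested set by default; `comparison="global"` includes it.

Sets with fewer than 10 measured genes are flagged and excluded from
multiple-testing correction: the central limit theorem that justifies the
Student-t reference is unreliable there (see the normality diagnostic,
which draws random null subsets, maps each Welch statistic through its
claimed t reference to a z-score, and Shapiro-Wilk-tests those; sets of 5
genes degrade visibly while 10–20 stay near-normal).

The **baseline Z method** summarizes each gene as −log p_(m) and each set
as Z_i = (x̄_i − μ)√N_i/σ with μ, σ the mean and SD over all genes (upper
tail normal p). It ignores both LD and variance heterogeneity and is
included as the comparison method whose large-gene false-positive inflation
the corrected test removes.

**Multiple testing** uses Storey q-values with π̂₀ estimated at λ = 0.5
(capped at 1, floored at 1/n); with π̂₀ = 1 the procedure reduces exactly
to Benjamini-Hochberg, which the tests exploit as an oracle.

## Associated pipeline choices

* Marker QC: exclude MAF < 0.01, missing call rate > 5%, HWE p < 1e-6
  (1-df chi-square goodness of fit; computed on controls only when a
  phenotype is available — an exact test adds nothing at the 1e-6
  threshold). Missing dosages are handled per SNP by complete-case analysis
  in the scan and mean imputation in covariance estimation only.
* Association: per-SNP logistic regression (additive dosage coding, Wald
  1-df p-value) with covariates; or, in `fast` mode, the covariate-free
  Cochran-Armitage trend (score) test, vectorised across SNPs. The two
  agree asymptotically and the downstream method only consumes p-values.
  Complete separation is flagged per SNP rather than failing the scan.
* SNP→gene mapping: nearest gene within 500 kb of either boundary
  (distance 0 inside the gene body); equidistant ties go to the smaller
  gene id for determinism. BED input is converted from 0-based half-open to
  1-based inclusive at the reader.

## Synthetic data generator

The generator emulates a pathway-annotated case/control study at the scale
of the published design: 5 gene sets × 20 genes, gene sizes uniform on
9–12, 12–20, 20–30, 26–40 and 36–49 SNPs per set, 500 individuals.
Genotypes come from a Gaussian copula: within each LD block of 3–8 SNPs a
latent equicorrelated normal (ρ ~ U[0.4, 0.8]) is thresholded to
Hardy-Weinberg genotype frequencies at each SNP's MAF (~U[0.05, 0.5]).
One causal SNP (MAF pinned to 0.2) is planted in each of 5 causal genes of
a designated set, and case status follows
P(case|g) = expit(β₀ + β Σ_j g_j) over the causal dosages, with β the
per-allele log odds ratio and β₀ solved by root-finding so the expected
case fraction is 0.5. Genes sit 2 Mb apart on one synthetic chromosome so
the 500 kb rule recovers the intended SNP→gene assignment exactly.

What it does *not* emulate: real LD is neither exchangeable within blocks
nor zero between them; MAFs and block lengths are not independent of gene
structure; no missing genotypes, population stratification, genotyping
error or covariate effects. Passing the simulation study therefore
validates the statistical machinery under the model's own assumptions, not
robustness to real-cohort artefacts.

Determinism: every replicate r of a study draws its generator from
`SeedSequence(entropy=(master_seed, ...r))`, so any single replicate can be
reproduced in isolation.

## Size/power study and problem sizes

`size_power_study` reruns the full pipeline per replicate (fast trend scan)
and tabulates the fraction of replicates in which the designated causal
set's p-value falls below α. Under β = 0 the data distribution does not
depend on which set is labelled causal, so one batch of null replicates is
scored for all three causal configurations. The package's reference runs
use 1000 null replicates for type-I error and 100 replicates per effect
size for power (Monte-Carlo SE ≈ 0.007 and ≈ 0.04 respectively), roughly
six minutes on one core.

A caveat on power: with 500 individuals, causal MAF 0.2 and per-allele log
odds ratio β = 0.3, the per-causal-SNP test statistic has noncentrality
β·sqrt(n·0.25·2q(1−q)) ≈ 1.9, so individual causal SNPs are barely
significant and set-level power at α = 0.05 is modest (an oracle Fisher
combination over the five causal SNPs' own p-values reaches only ~0.65).
Published powers above 0.9 for this configuration imply per-SNP
noncentralities near 3.2–3.5 and are not reproducible from these parameter
values; the package reports what the stated design actually yields, and
power ordering (β = 0.6 > 0.3; small-gene > large-gene causal sets, whose
many null SNPs dilute the minimum-p signal) is preserved.

## Numerical notes and degenerate inputs

* ρ̂ per block is clipped to [0, 0.999]; negative average correlations
  (only possible by sampling noise) floor at 0.
* p-values exactly 0 (upstream underflow) are clamped to the smallest
  positive double with a warning; p-values of 1 are legal (−log p = 0).
* Genes with fewer than m SNPs use all their p-values in the top-m mean;
  the baseline falls back to the largest available order statistic with a
  warning. Monomorphic SNPs are flagged and never tested.
* AIC ties resolve toward fewer parameters (IND before CS before LD-CS),
  so a single-SNP gene reports IND and ñ = 1.
* Zero pooled variance, sets with fewer than 2 measured genes on either
  side, and constant gene measures raise explicit errors rather than
  returning NaN silently.

## Known limitations

* Genes shared by several sets contribute to each set independently;
  overlap correction is out of scope.
* The greedy blocking depends on SNP order (by design — LD is positional)
  and only approximates an optimal partition.
* The effective-size correction is exact for neither means nor minima
  under real LD; residual gene-size trend of a few percent remains even
  under the generator's idealised block model.
* The Welch reference is asymptotic in the number of genes per set; sets
  below 10 genes are flagged rather than tested more exactly.
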