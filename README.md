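# snpprage

LD-aware parametric competitive gene-set enrichment analysis for
genome-wide association studies.

Single-SNP GWAS scans miss phenotypes driven by many weak effects. A
competitive gene-set test asks whether the genes of a pathway are more
associated with a case/control phenotype than the genes outside it, working
only from per-SNP p-values — no permutation. Doing that naively fails twice:
the minimum p-value of a gene shrinks with its SNP count (the m-th order
statistic of n uniform p-values is Beta(m, n−m+1) with mean m/(n+1)), and
linkage disequilibrium (LD) makes SNP p-values within a gene redundant.
`snpprage` implements the corrected SNP-PRAGE procedure and the PAGE-style
Z-statistic baseline it improves on:

1. **QC + association scan** — MAF/missingness/Hardy-Weinberg marker
   filters, then per-SNP additive logistic regression (Wald 1-df p-values,
   covariate-adjusted) or a fast vectorised Cochran-Armitage trend test.
2. **Gene mapping** — each SNP is assigned to its nearest gene within
   500 kb.
3. **Effective gene size ñ_ij** — each gene's SNPs are partitioned into LD
   blocks (greedy rule on dosage r² ≤ 0.05), block-wise
   compound-symmetric correlation structures (IND / CS / LD-CS) are fitted
   by Gaussian ML and selected by AIC, and the fitted ρ̂ per block converts
   the SNP count n_ij into an effective number of independent SNPs ñ_ij.
4. **Gene measure** — g_ij = (ñ_ij + 1) × mean of the m smallest SNP
   p-values; under independence E[g] = (m+1)/2 regardless of gene size.
5. **Set test** — Welch's heterogeneous-variance t comparing the set's
   gene measures (on the −log scale) against all other genes, with
   Satterthwaite degrees of freedom df_i; Storey q-values across sets.

The package also ships a block-LD genotype simulator (Gaussian copula,
Hardy-Weinberg thresholds) and a size/power study harness that reproduce
the method's simulation validation end to end: the corrected test holds its
type-I error across gene-size regimes where the Z baseline's false-positive
rate explodes.

## Worked example

Simulate a 500-sample study (5 sets × 20 genes, gene sizes 9–49 SNPs,
block LD) with five causal SNPs of effect log-OR 0.6 planted in `Set1`,
then fit:

```python
import snpprage as sp

ds = sp.simulate_dataset(sp.SimulationConfig(seed=7, beta=0.6, causal_set_id="Set1"))
model = sp.SnpPrage(ds.genotypes, ds.phenotype, ds.genes, ds.gene_sets)
res = model.fit(m=1, fast=True)
print(res.summary())
```

```
Competitive gene-set enrichment — method=prage, m=1
SNPs: 2576 in, 2576 post-QC, 2576 mapped; genes: 100; sets tested: 5

set_id  n_genes  statistic    df  pvalue  qvalue
  Set1       20      2.322 19.35 0.01565 0.07823
  Set5       20      -1.11 91.87  0.8651  0.9852
  Set4       20     -1.586 90.83  0.9418  0.9852
  Set3       20     -1.872 94.78  0.9679  0.9852
  Set2       20     -2.217 77.88  0.9852  0.9852
```

The planted causal set ranks first: its 20 gene measures are shifted
towards significance relative to the 80 complement genes (Welch t = 2.32 on
19.3 Satterthwaite df, one-sided p = 0.016). The remaining sets sit in the
null tail. `res.genes` and `res.snps` hold the per-gene measures
(n_snps, ñ, g_ij, −log p_(m)) and the per-SNP scan; `res.to_tsv(outdir)`
writes everything plus a run manifest.

The same run from the shell:

```sh
snpprage simulate --scale paper --beta 0.6 --outdir sim/
snpprage run --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
    --snp-map sim/snp_map.tsv --genes sim/genes.bed --gene-sets sim/gene_sets.gmt \
    --fast --outdir out/
```

Per-stage subcommands (`qc`, `assoc`, `map`, `ld`, `summarize`, `settest`)
expose each pipeline step over shared TSV intermediates, and
`snpprage benchmark` tabulates type-I error and power over replicated
simulations.

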