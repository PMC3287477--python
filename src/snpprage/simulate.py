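"""Synthetic GWA data with block LD, and the size/power simulation study.

The generator emulates a small pathway-annotated case/control GWA study:

* five gene sets of 20 genes each, with per-set gene-size (SNP-count) ranges
  (9-12, 12-20, 20-30, 26-40, 36-49) spanning small to large genes;
* genotypes from a Gaussian-copula block-LD model: within each block of 3-8
  SNPs a latent equicorrelated normal (rho uniform on [0.4, 0.8]) is
  thresholded to Hardy-Weinberg genotype frequencies at each SNP's MAF
  (uniform on [0.05, 0.5]);
* one causal SNP (MAF 0.2) in each of 5 causal genes of a designated causal
  set; case/control status follows a logistic model
  P(case|g) = expit(beta0 + beta * sum_j g_j) over the causal dosages, with
  beta the per-allele log odds ratio (0, 0.3 or 0.6) and beta0 solved so the
  expected case fraction is 0.5;
* genes laid out 2 Mb apart on one synthetic chromosome so the 500 kb
  nearest-gene rule recovers the intended SNP-to-gene assignment exactly.

``size_power_study`` runs the full pipeline over replicated datasets and
tabulates rejection rates of the causal set: the type-I error when beta = 0
and the power when beta > 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import io as sio
from .types import GeneAnnotation, GenotypeMatrix, GeneSetCollection, PhenotypeTable

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_dataset",
    "size_power_study",
    "fixture_generator",
    "replicate_seed",
]

#: gene-size (SNP count) ranges per simulated set, inclusive
DEFAULT_SET_SIZES = {
    "Set1": (9, 12),
    "Set2": (12, 20),
    "Set3": (20, 30),
    "Set4": (26, 40),
    "Set5": (36, 49),
}


@dataclass
class SimulationConfig:
    """Design of one simulated dataset (defaults = the study conditions)."""

    n_individuals: int = 500
    sets: dict = field(default_factory=lambda: dict(DEFAULT_SET_SIZES))
    n_genes_per_set: int = 20
    causal_set_id: str = "Set1"
    n_causal_genes: int = 5
    causal_maf: float = 0.2
    beta: float = 0.0
    intercept_mode: str = "prevalence_0.5"   # or "fixed" (beta0 = 0)
    block_size_range: tuple = (3, 8)
    rho_range: tuple = (0.4, 0.8)
    maf_range: tuple = (0.05, 0.5)
    gene_spacing_bp: int = 2_000_000
    snp_spacing_bp: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.causal_set_id not in self.sets:
            raise ValueError(f"causal_set_id {self.causal_set_id!r} not among sets")
        lo, hi = self.rho_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("rho_range must lie in [0, 1)")
        if not (0.0 < self.causal_maf < 0.5 + 1e-9):
            raise ValueError("causal_maf must be in (0, 0.5]")
        if self.beta < 0:
            raise ValueError("beta (log odds ratio) must be >= 0")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotype: PhenotypeTable
    genes: list
    gene_sets: GeneSetCollection
    truth: dict   # causal_snps, causal_genes, causal_set_id, beta


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    """Independent, reproducible RNG stream for one replicate."""
    return np.random.SeedSequence(entropy=(int(master_seed), int(replicate)))


def _simulate_block(rng, n, mafs, rho):
    """Dosages for one LD block via a Gaussian copula with exchangeable rho."""
    b = len(mafs)
    shared = rng.standard_normal((n, 1))
    z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, b))
    q = np.asarray(mafs)
    p0 = (1.0 - q) ** 2                       # HWE genotype frequencies
    t0 = special.ndtri(p0)
    t1 = special.ndtri(p0 + 2.0 * q * (1.0 - q))
    return (z > t0[None, :]).astype(float) + (z > t1[None, :])


def simulate_genotypes(config: SimulationConfig, rng=None):
    """Generate genotypes, gene/set annotations and causal-SNP truth.

    Returns ``(GenotypeMatrix, genes, GeneSetCollection, truth)``; the
    phenotype is generated separately so the same genotypes can be reused
    across effect sizes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    blocks_cols, metas, genes = [], [], []
    set_members: dict[str, list[str]] = {sid: [] for sid in config.sets}
    gene_index = 0

    # choose causal genes/SNPs up front so their MAF can be pinned
    causal_gene_pos = set()
    causal_set = config.causal_set_id
    chosen = rng.choice(config.n_genes_per_set, size=config.n_causal_genes, replace=False)
    causal_gene_pos = {int(c) for c in chosen}
    causal_snps, causal_genes = [], []

    for sid, (size_lo, size_hi) in config.sets.items():
        for g in range(config.n_genes_per_set):
            gene_id = f"{sid}_G{g + 1:02d}"
            p = int(rng.integers(size_lo, size_hi + 1))
            mafs = rng.uniform(*config.maf_range, size=p)
            is_causal_gene = sid == causal_set and g in causal_gene_pos
            if is_causal_gene:
                causal_idx = int(rng.integers(p))
                mafs[causal_idx] = config.causal_maf
            # partition the gene's SNPs into LD blocks of 3-8
            cols, start = [], 0
            blk_lo, blk_hi = config.block_size_range
            while start < p:
                b = min(int(rng.integers(blk_lo, blk_hi + 1)), p - start)
                rho = rng.uniform(*config.rho_range)
                cols.append(_simulate_block(rng, n, mafs[start : start + b], rho))
                start += b
            X = np.hstack(cols)
            blocks_cols.append(X)

            base = (gene_index + 1) * config.gene_spacing_bp
            pos = base + config.snp_spacing_bp * np.arange(p)
            snp_ids = [f"{gene_id}_snp{j + 1:03d}" for j in range(p)]
            metas.append(pd.DataFrame({"snp_id": snp_ids, "chrom": "1", "pos": pos}))
            genes.append(GeneAnnotation(gene_id, "1", int(pos[0]), int(pos[-1])))
            set_members[sid].append(gene_id)
            if is_causal_gene:
                causal_snps.append(snp_ids[causal_idx])
                causal_genes.append(gene_id)
            gene_index += 1

    gmat = GenotypeMatrix(
        dosages=np.hstack(blocks_cols),
        snp_meta=pd.concat(metas, ignore_index=True),
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
    )
    sets = GeneSetCollection(
        sets=set_members,
        descriptions={sid: f"simulated set, gene size {lo}-{hi} SNPs" for sid, (lo, hi) in config.sets.items()},
    )
    truth = {
        "causal_set_id": causal_set,
        "causal_genes": causal_genes,
        "causal_snps": causal_snps,
        "beta": config.beta,
    }
    return gmat, genes, sets, truth


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    truth: dict,
    beta: float,
    intercept_mode: str = "prevalence_0.5",
    rng=None,
    seed=None,
) -> PhenotypeTable:
    """Case/control status from the logistic model over the causal dosages."""
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = list(genotypes.snp_ids)
    try:
        cols = [ids.index(s) for s in truth["causal_snps"]]
    except ValueError as err:
        raise ValueError(f"causal SNP absent from genotype matrix: {err}")
    eta = beta * genotypes.dosages[:, cols].sum(axis=1) if cols else np.zeros(genotypes.n_samples)
    if beta > 0 and np.ptp(eta) == 0:
        raise ValueError("no variation in the linear predictor despite beta > 0")
    if intercept_mode == "prevalence_0.5":
        beta0 = optimize.brentq(
            lambda b0: special.expit(b0 + eta).mean() - 0.5, -30.0, 30.0
        )
    elif intercept_mode == "fixed":
        beta0 = 0.0
    else:
        raise ValueError(f"unknown intercept_mode {intercept_mode!r}")
    prob = special.expit(beta0 + eta)
    status = (rng.random(genotypes.n_samples) < prob).astype(int)
    return PhenotypeTable(status=status, sample_ids=list(genotypes.sample_ids))


def simulate_dataset(config: SimulationConfig, rng=None) -> SimulatedDataset:
    """One full dataset (genotypes + phenotype + annotations + truth)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gmat, genes, sets, truth = simulate_genotypes(config, rng)
    pheno = simulate_phenotype(gmat, truth, config.beta, config.intercept_mode, rng=rng)
    return SimulatedDataset(gmat, pheno, genes, sets, truth)


def size_power_study(
    causal_set_ids=("Set1", "Set3", "Set5"),
    beta_reps=None,
    m_values=(1,),
    methods=("prage", "zmethod"),
    alphas=(0.05, 0.01),
    seed: int = 0,
    config_kwargs=None,
    progress=None,
) -> pd.DataFrame:
    """Rejection-rate study of the causal set across effect sizes.

    Parameters
    ----------
    causal_set_ids : which sets act as the causal configuration.
    beta_reps : dict beta -> number of replicates; default
        ``{0.0: 1000, 0.3: 100, 0.6: 100}``.
    m_values, methods, alphas : analysis grid.
    seed : master seed; replicate r of effect beta uses an independent
        stream derived from (seed, beta-index, causal-set, r).

    Returns
    -------
    DataFrame with one row per (causal set, beta, method, m, alpha):
    rejection rate of the causal set, Monte-Carlo SE, replicate counts and
    the number of replicates excluded by QC/association failures.

    Notes
    -----
    Under beta = 0 the data distribution does not depend on which set is
    labelled causal, so one batch of null replicates is scored for every
    causal configuration at once.
    """
    from .pipeline import analyze_dataset  # deferred: avoids a cycle

    if not methods:
        raise ValueError("methods list is empty")
    if beta_reps is None:
        beta_reps = {0.0: 1000, 0.3: 100, 0.6: 100}
    config_kwargs = dict(config_kwargs or {})
    rows = []
    for bi, (beta, n_reps) in enumerate(sorted(beta_reps.items())):
        if n_reps < 1:
            raise ValueError("each effect size needs >= 1 replicate")
        targets = list(causal_set_ids) if beta > 0 else [causal_set_ids[0]]
        for ci, causal_set in enumerate(targets):
            cfg = SimulationConfig(
                causal_set_id=causal_set, beta=beta, **config_kwargs
            )
            hits = {}   # (set_id, method, m, alpha) -> rejection count
            n_failed = 0
            for rep in range(n_reps):
                ss = np.random.SeedSequence(entropy=(int(seed), bi, ci, rep))
                rng = np.random.default_rng(ss)
                ds = simulate_dataset(cfg, rng=rng)
                try:
                    pvals = analyze_dataset(ds, m_values=m_values, methods=methods)
                except Exception:
                    n_failed += 1
                    continue
                for (method, m), series in pvals.items():
                    for sid, p in series.items():
                        for alpha in alphas:
                            key = (sid, method, m, alpha)
                            hits[key] = hits.get(key, 0) + int(p < alpha)
                if progress is not None:
                    progress(beta, causal_set, rep)
            n_used = n_reps - n_failed
            report_sets = causal_set_ids if beta == 0 else [causal_set]
            for sid in report_sets:
                lo, hi = cfg.sets[sid]
                for method in methods:
                    for m in m_values:
                        for alpha in alphas:
                            rate = hits.get((sid, method, m, alpha), 0) / max(n_used, 1)
                            rows.append(
                                {
                                    "causal_set": sid,
                                    "gene_size_range": f"{lo}-{hi}",
                                    "beta": beta,
                                    "method": method,
                                    "m": m,
                                    "alpha": alpha,
                                    "rejection_rate": rate,
                                    "mc_se": float(np.sqrt(rate * (1 - rate) / max(n_used, 1))),
                                    "n_reps": n_used,
                                    "n_excluded": n_failed,
                                }
                            )
    return pd.DataFrame(rows)


TINY_CONFIG = dict(
    n_individuals=50,
    sets={"SetA": (3, 5), "SetB": (4, 6)},
    n_genes_per_set=5,
    causal_set_id="SetA",
    n_causal_genes=2,
)


def fixture_generator(scale: str, outdir, seed: int = 0, beta: float = 0.0) -> dict:
    """Write a complete on-disk dataset (genotypes, phenotype, map, BED, GMT,
    truth JSON) and return the file paths.

    ``scale="tiny"`` is a 50-sample, 2-set toy for fast tests;
    ``scale="paper"`` is the full 5-set / 20-gene / 500-sample design.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scale == "tiny":
        cfg = SimulationConfig(seed=seed, beta=beta, **TINY_CONFIG)
    elif scale == "paper":
        cfg = SimulationConfig(seed=seed, beta=beta)
    else:
        raise ValueError("scale must be 'tiny' or 'paper'")
    ds = simulate_dataset(cfg)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "snp_map": outdir / "snp_map.tsv",
        "genes": outdir / "genes.bed",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    sio.write_genotypes_tsv(ds.genotypes, paths["genotypes"])
    sio.write_phenotypes(ds.phenotype, paths["phenotypes"])
    sio.write_snp_map(ds.genotypes.snp_meta, paths["snp_map"])
    sio.write_genes_bed(ds.genes, paths["genes"])
    sio.write_gmt(ds.gene_sets, paths["gene_sets"])
    with open(paths["truth"], "w") as fh:
        json.dump({**ds.truth, "config": asdict(cfg)}, fh, indent=1, default=str)
    return {k: str(v) for k, v in paths.items()}
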