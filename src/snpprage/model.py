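"""Model/Results interface tying the pipeline stages together.

``SnpPrage`` is constructed from data (or files) and holds the analysis
configuration; ``fit()`` runs marker QC, the per-SNP association scan, the
500 kb nearest-gene mapping, per-gene LD modelling, gene summarisation and
the competitive set test, and returns an ``EnrichmentResults`` object with
per-SNP, per-gene and per-set tables plus a run manifest.  Intermediate
stages are cached on the model, so refitting with a different ``m`` or
method reuses the QC, scan and LD work.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import __version__
from .assoc import snp_logistic_scan
from .genesummary import summarize_genes
from .ld import gene_ld_summary
from .mapping import genes_to_snp_lists, map_snps_to_genes
from .qc import QcThresholds, qc_filter
from .settest import prage_set_test, zmethod_set_test
from .types import GenotypeMatrix, GeneSetCollection, PhenotypeTable

__all__ = ["SnpPrage", "EnrichmentResults"]


class SnpPrage:
    """LD-aware competitive gene-set enrichment model for GWAS.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    phenotype : PhenotypeTable (sample order must match the genotypes)
    genes : list of GeneAnnotation
    gene_sets : GeneSetCollection
    window_bp : SNP-to-gene mapping window (default 500 kb).
    r2_threshold : LD-block split threshold on r² (default 0.05).
    min_set_size : sets with fewer measured genes are flagged (default 10).
    qc : QcThresholds (MAF >= 0.01, missingness <= 5%, HWE p >= 1e-6).
    scale : "log" or "natural" — scale the Welch set test operates on.
    comparison : "complement" or "global" reference group for the set test.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        phenotype: PhenotypeTable,
        genes: list,
        gene_sets: GeneSetCollection,
        *,
        window_bp: int = 500_000,
        r2_threshold: float = 0.05,
        min_set_size: int = 10,
        qc: QcThresholds = QcThresholds(),
        scale: str = "log",
        comparison: str = "complement",
        eff_size: str = "galwey",
    ):
        if genotypes.n_samples != phenotype.n_samples:
            raise ValueError("genotype and phenotype sample counts differ")
        self.genotypes = genotypes
        self.phenotype = phenotype
        self.genes = genes
        self.gene_sets = gene_sets
        self.window_bp = window_bp
        self.r2_threshold = r2_threshold
        self.min_set_size = min_set_size
        self.qc = qc
        self.scale = scale
        self.comparison = comparison
        self.eff_size = eff_size
        self._cache: dict = {}

    @classmethod
    def from_files(
        cls, genotypes, phenotypes, snp_map=None, genes=None, gene_sets=None, **kwargs
    ) -> "SnpPrage":
        """Build a model from on-disk inputs (TSV/.raw, TSV, BED, GMT)."""
        from . import io as sio

        gmat = sio.read_genotypes(genotypes, snp_map)
        pheno = sio.read_phenotypes(phenotypes, sample_ids=gmat.sample_ids)
        if genes is None or gene_sets is None:
            raise ValueError("gene annotation (BED/TSV) and gene sets (GMT) are required")
        gene_list = (
            sio.read_genes_bed(genes)
            if str(genes).endswith(".bed")
            else sio.read_genes_tsv(genes)
        )
        sets = sio.read_gmt(gene_sets)
        return cls(gmat, pheno, gene_list, sets, **kwargs)

    # ---------------------------------------------------------- stages

    def _qc_stage(self):
        if "qc" not in self._cache:
            self._cache["qc"] = qc_filter(
                self.genotypes,
                maf_min=self.qc.maf_min,
                miss_max=self.qc.miss_max,
                hwe_alpha=self.qc.hwe_alpha,
                phenotype=self.phenotype,
            )
        return self._cache["qc"]

    def _scan_stage(self, fast: bool):
        key = ("scan", fast)
        if key not in self._cache:
            gmat, _ = self._qc_stage()
            self._cache[key] = snp_logistic_scan(gmat, self.phenotype, fast=fast)
        return self._cache[key]

    def _map_stage(self):
        if "map" not in self._cache:
            gmat, _ = self._qc_stage()
            snp_map = map_snps_to_genes(gmat.snp_meta, self.genes, self.window_bp)
            gene_snps = genes_to_snp_lists(snp_map, snp_order=gmat.snp_ids)
            self._cache["map"] = (snp_map, gene_snps)
        return self._cache["map"]

    def _ld_stage(self):
        """Per-gene LD blocks and effective sizes on the QC-passed dosages."""
        if "ld" not in self._cache:
            gmat, _ = self._qc_stage()
            _, gene_snps = self._map_stage()
            col_of = {s: j for j, s in enumerate(gmat.snp_ids)}
            n_eff, ld_rows = {}, []
            for gid, snps in gene_snps.items():
                cols = [col_of[s] for s in snps]
                blocks, fit, ne = gene_ld_summary(
                    gmat.dosages[:, cols],
                    self.r2_threshold,
                    snp_ids=snps,
                    eff_size=self.eff_size,
                )
                n_eff[gid] = ne
                for bi, blk in enumerate(blocks):
                    for ci in blk.snp_indices:
                        ld_rows.append(
                            {
                                "gene_id": gid,
                                "block_index": bi,
                                "snp_id": snps[ci],
                                "rho_hat": blk.rho_hat,
                                "structure": fit.structure,
                            }
                        )
            self._cache["ld"] = (n_eff, pd.DataFrame(ld_rows))
        return self._cache["ld"]

    # ------------------------------------------------------------- fit

    def fit(
        self,
        m: int = 1,
        method: str = "prage",
        fast: bool = False,
        alternative: str = "less",
    ) -> "EnrichmentResults":
        """Run the full analysis and return results.

        ``method="prage"`` uses the LD-corrected top-m mean measure and the
        heterogeneous-variance Welch set test; ``method="zmethod"`` is the
        PAGE-style baseline (-log p_(m) measure, global Z).  ``fast=True``
        replaces per-SNP logistic regression by the covariate-free trend
        test.
        """
        if method not in ("prage", "zmethod"):
            raise ValueError("method must be 'prage' or 'zmethod'")
        gmat_qc, exclusions = self._qc_stage()
        scan = self._scan_stage(fast)
        snp_map, gene_snps = self._map_stage()
        if method == "prage":
            n_eff, ld_table = self._ld_stage()
        else:
            n_eff, ld_table = None, pd.DataFrame()
        genes_df = summarize_genes(scan, gene_snps, n_eff=n_eff, m=m)
        if method == "prage":
            sets_df = prage_set_test(
                genes_df,
                self.gene_sets,
                min_set_size=self.min_set_size,
                alternative=alternative,
                scale=self.scale,
                comparison=self.comparison,
            )
        else:
            sets_df = zmethod_set_test(genes_df, self.gene_sets, self.min_set_size)
        sets_df = sets_df.sort_values(
            ["qvalue", "pvalue"], na_position="last"
        ).reset_index(drop=True)

        manifest = {
            "package": "snpprage",
            "version": __version__,
            "method": method,
            "m": m,
            "fast_association": fast,
            "counts": {
                "snps_in": self.genotypes.n_snps,
                "snps_post_qc": gmat_qc.n_snps,
                "snps_mapped": len(snp_map.snp_to_gene),
                "genes_summarized": int(len(genes_df)),
                "sets_tested": int(sets_df["pvalue"].notna().sum()),
            },
            "warnings": {
                "snps_excluded_qc": int(len(exclusions)),
                "snps_unmapped": len(snp_map.unmapped),
                "small_sets": int(sets_df["flagged_small"].sum()),
            },
            "params": {
                "window_bp": self.window_bp,
                "r2_threshold": self.r2_threshold,
                "min_set_size": self.min_set_size,
                "qc": asdict(self.qc),
                "scale": self.scale,
                "comparison": self.comparison,
                "alternative": alternative,
            },
        }
        return EnrichmentResults(
            model=self,
            sets=sets_df,
            genes=genes_df,
            snps=scan,
            exclusions=exclusions,
            ld_blocks=ld_table,
            manifest=manifest,
        )


@dataclass
class EnrichmentResults:
    """Fitted enrichment results (per-SNP, per-gene and per-set tables)."""

    model: SnpPrage
    sets: pd.DataFrame
    genes: pd.DataFrame
    snps: pd.DataFrame
    exclusions: pd.DataFrame
    ld_blocks: pd.DataFrame
    manifest: dict

    def set_pvalue(self, set_id: str) -> float:
        row = self.sets[self.sets["set_id"] == set_id]
        if row.empty:
            raise KeyError(f"unknown set {set_id!r}")
        return float(row["pvalue"].iloc[0])

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary with the top gene sets by q-value."""
        c = self.manifest["counts"]
        lines = [
            "Competitive gene-set enrichment"
            f" — method={self.manifest['method']}, m={self.manifest['m']}",
            f"SNPs: {c['snps_in']} in, {c['snps_post_qc']} post-QC, "
            f"{c['snps_mapped']} mapped; genes: {c['genes_summarized']}; "
            f"sets tested: {c['sets_tested']}",
            "",
        ]
        cols = ["set_id", "n_genes", "statistic", "df", "pvalue", "qvalue"]
        table = self.sets[cols].head(top)
        lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, outdir) -> dict:
        """Write per-SNP, per-gene, per-set tables and the manifest."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "snps": outdir / "snp_results.tsv",
            "genes": outdir / "gene_results.tsv",
            "sets": outdir / "set_results.tsv",
            "exclusions": outdir / "qc_exclusions.tsv",
            "ld_blocks": outdir / "ld_blocks.tsv",
            "manifest": outdir / "manifest.json",
        }
        self.snps.to_csv(paths["snps"], sep="\t", index=False)
        self.genes.to_csv(paths["genes"], sep="\t", index=False)
        self.sets.to_csv(paths["sets"], sep="\t", index=False)
        self.exclusions.to_csv(paths["exclusions"], sep="\t", index=False)
        if len(self.ld_blocks):
            self.ld_blocks.to_csv(paths["ld_blocks"], sep="\t", index=False)
        manifest = dict(self.manifest)
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(manifest["params"], sort_keys=True).encode()
        ).hexdigest()[:16]
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1)
        return {k: str(v) for k, v in paths.items()}
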