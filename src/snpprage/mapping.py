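"""SNP-to-gene and gene-to-set assignment.

Each SNP is assigned to its nearest gene, provided the gene lies within a
window (default 500 kb) upstream or downstream; SNPs inside a gene body have
distance zero.  Rationale for the window: most enhancers/repressors and most
LD blocks fall within 500 kb of a gene, so more distant SNPs carry little
attributable signal.  A SNP maps to at most one gene; equidistant ties go to
the lexicographically smaller gene id so runs are deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import GeneAnnotation, SnpGeneMap

log = logging.getLogger(__name__)

__all__ = ["map_snps_to_genes", "genes_to_snp_lists"]


def map_snps_to_genes(
    snp_meta: pd.DataFrame, genes: list, window_bp: int = 500_000
) -> SnpGeneMap:
    """Assign every SNP to its nearest gene within ``window_bp``.

    Parameters
    ----------
    snp_meta : DataFrame with columns snp_id, chrom, pos (1-based).
    genes : list of GeneAnnotation (1-based inclusive intervals).
    window_bp : int >= 0
        Maximum distance from a gene boundary for a SNP to be mapped.

    Returns
    -------
    SnpGeneMap
        ``snp_to_gene`` for mapped SNPs, ``unmapped`` for the rest.  SNPs on
        chromosomes with no annotated gene are unmapped with a warning.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for gene in genes:
        by_chrom.setdefault(str(gene.chrom), []).append(gene)

    snp_to_gene: dict[str, str] = {}
    unmapped: list[str] = []
    warned_chroms = set()
    for chrom, grp in snp_meta.groupby("chrom", sort=False):
        chrom = str(chrom)
        cand = by_chrom.get(chrom)
        if not cand:
            if chrom not in warned_chroms:
                log.warning("no genes annotated on chromosome %s; SNPs left unmapped", chrom)
                warned_chroms.add(chrom)
            unmapped.extend(grp["snp_id"].tolist())
            continue
        pos = grp["pos"].to_numpy(dtype=np.int64)
        # distance to each candidate gene: 0 inside the body, else boundary gap
        best_dist = np.full(pos.shape, np.iinfo(np.int64).max, dtype=np.int64)
        best_gene = np.full(pos.shape, "", dtype=object)
        for gene in sorted(cand, key=lambda x: x.gene_id):
            dist = np.maximum.reduce([gene.start - pos, pos - gene.end, np.zeros_like(pos)])
            better = dist < best_dist  # strict: first (smallest id) wins ties
            best_dist = np.where(better, dist, best_dist)
            best_gene = np.where(better, gene.gene_id, best_gene)
        ok = best_dist <= window_bp
        for snp_id, gid, within in zip(grp["snp_id"], best_gene, ok):
            if within:
                snp_to_gene[snp_id] = gid
            else:
                unmapped.append(snp_id)
    return SnpGeneMap(snp_to_gene=snp_to_gene, unmapped=unmapped)


def genes_to_snp_lists(snp_map: SnpGeneMap, snp_order=None) -> dict:
    """Invert a SnpGeneMap: gene_id -> list of snp_ids.

    If ``snp_order`` (an iterable of snp ids, e.g. position-sorted metadata)
    is given, each gene's SNP list follows that order.
    """
    out: dict[str, list[str]] = {}
    if snp_order is None:
        items = snp_map.snp_to_gene.items()
        for snp_id, gid in items:
            out.setdefault(gid, []).append(snp_id)
        return out
    for snp_id in snp_order:
        gid = snp_map.snp_to_gene.get(snp_id)
        if gid is not None:
            out.setdefault(gid, []).append(snp_id)
    return out
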