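"""Gene-level summaries of SNP p-values.

Two summaries are produced per gene:

* the size-corrected top-m mean ("PRAGE measure"):
  ``g = (n_eff + 1) * mean(m smallest p-values)``.  For independent uniform
  p-values the mth order statistic of n has mean m/(n+1) (Beta(m, n-m+1)),
  so multiplying by (n+1) removes the gene-size trend: the measure's
  expectation is (m+1)/2 whatever the gene size.  Under LD the SNP count n
  overstates the information in a gene, so the effective size n_eff is used
  instead; small values indicate association.

* the baseline measure ``-log p_(m)`` used by the PAGE-style Z method; it
  grows with gene size (E[p_(1)] = 1/(n+1)), which is exactly the bias the
  corrected measure removes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["prage_gene_measure", "zmethod_gene_measure", "summarize_genes"]

_TINY = np.finfo(float).tiny


def _clean_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        log.warning("p-value underflow: clamping %d zero p-value(s)", int((p == 0).sum()))
        p = np.maximum(p, _TINY)
    return p


def prage_gene_measure(pvals, m: int, n_eff: float) -> float:
    """Size-corrected gene measure ``(n_eff + 1) * mean(top-m p-values)``.

    Genes with fewer than m SNPs use all their p-values (m acts as
    min(m, n)), so set membership does not change with m.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_eff < 1:
        raise ValueError("effective gene size must be >= 1")
    p = np.sort(_clean_pvals(pvals))
    top = p[: min(m, p.size)]
    return float((n_eff + 1.0) * top.mean())


def zmethod_gene_measure(pvals, m: int = 1) -> float:
    """Baseline gene measure ``-log(p_(m))`` (natural log).

    If the gene has fewer than m SNPs the largest available order statistic
    is used, with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.sort(_clean_pvals(pvals))
    if p.size < m:
        log.warning("gene has %d SNP(s) < m=%d; using the largest order statistic", p.size, m)
    pm = p[min(m, p.size) - 1]
    return float(-np.log(pm))


def summarize_genes(
    snp_results: pd.DataFrame,
    gene_snps: dict,
    n_eff: dict | None = None,
    m: int = 1,
) -> pd.DataFrame:
    """Collapse per-SNP p-values into one row per gene.

    Parameters
    ----------
    snp_results : DataFrame
        Association scan output (columns ``snp_id``, ``pvalue``,
        ``status_flag``); only rows with status ``ok`` contribute.
    gene_snps : dict gene_id -> list of snp_ids (position order).
    n_eff : dict gene_id -> effective size; defaults to the SNP count
        (no LD correction).
    m : int
        Number of smallest p-values averaged in the corrected measure, and
        the order statistic used by the baseline.

    Returns
    -------
    DataFrame with columns gene_id, n_snps, n_eff, measure, baseline_measure,
    top_pvals (ascending, comma-joined).  Genes whose SNPs were all untested
    (monomorphic etc.) are dropped.
    """
    ok = snp_results[snp_results["status_flag"] == "ok"]
    pmap = dict(zip(ok["snp_id"], ok["pvalue"]))
    rows = []
    for gid, snps in gene_snps.items():
        pv = np.array([pmap[s] for s in snps if s in pmap], dtype=float)
        if pv.size == 0:
            continue
        ne = float(n_eff.get(gid, pv.size)) if n_eff is not None else float(pv.size)
        ne = min(ne, float(pv.size))  # guard: n_eff cannot exceed the tested SNP count
        top = np.sort(pv)[: min(m, pv.size)]
        rows.append(
            {
                "gene_id": gid,
                "n_snps": int(pv.size),
                "n_eff": ne,
                "measure": prage_gene_measure(pv, m, ne),
                "baseline_measure": zmethod_gene_measure(pv, m),
                "top_pvals": ",".join(f"{x:.6g}" for x in top),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_snps", "n_eff", "measure", "baseline_measure", "top_pvals"])
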