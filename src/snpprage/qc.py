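"""Marker quality control.

Three standard GWAS marker filters: minor-allele frequency, per-SNP missing
call rate, and a 1-df chi-square goodness-of-fit test of Hardy-Weinberg
equilibrium.  HWE is evaluated on controls only when a phenotype is supplied
(cases can deviate under a true association), otherwise on all samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix, PhenotypeTable

__all__ = ["qc_filter", "hwe_pvalues", "snp_maf", "QcThresholds"]


class NoMarkersError(ValueError):
    """Raised when no markers survive QC."""


from dataclasses import dataclass


@dataclass(frozen=True)
class QcThresholds:
    """Marker QC thresholds; defaults follow routine GWAS practice
    (exclude MAF < 1%, missingness > 5%, HWE p < 1e-6)."""

    maf_min: float = 0.01
    miss_max: float = 0.05
    hwe_alpha: float = 1e-6


def snp_maf(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency from additive dosages (NaN-aware)."""
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dosages, axis=0) / 2.0
    f = np.where(np.isnan(f), 0.0, f)
    return np.minimum(f, 1.0 - f)


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """1-df chi-square goodness-of-fit p-value for HWE, per SNP.

    Expected genotype counts use the allele frequency estimated from the
    observed (non-missing) genotypes.  Monomorphic SNPs return p = 1 (no
    deviation is estimable).
    """
    valid = np.isfinite(dosages)
    n = valid.sum(axis=0).astype(float)
    n2 = np.nansum(dosages == 2, axis=0).astype(float)
    n1 = np.nansum(dosages == 1, axis=0).astype(float)
    n0 = n - n1 - n2
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (2 * n2 + n1) / (2 * n)  # minor-ish allele freq; symmetry makes the label irrelevant
    p = 1.0 - q
    e0, e1, e2 = n * p**2, 2 * n * p * q, n * q**2
    chi2 = np.zeros_like(q)
    for obs, exp in ((n0, e0), (n1, e1), (n2, e2)):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (obs - exp) ** 2 / exp
        chi2 += np.where(exp > 0, term, 0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    mono = (q <= 0) | (q >= 1) | ~np.isfinite(q)
    return np.where(mono, 1.0, pvals)


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    miss_max: float = 0.05,
    hwe_alpha: float = 1e-6,
    phenotype: PhenotypeTable | None = None,
):
    """Apply MAF / missingness / HWE filters.

    Parameters
    ----------
    g : GenotypeMatrix
    maf_min, miss_max, hwe_alpha : float in (0, 1)
        Exclude SNPs with MAF < ``maf_min``, missing fraction > ``miss_max``
        or HWE p-value < ``hwe_alpha``.
    phenotype : PhenotypeTable, optional
        When given, HWE is tested on controls only.

    Returns
    -------
    (GenotypeMatrix, DataFrame)
        The filtered matrix and an exclusion log with one row per dropped
        SNP (columns ``snp_id``, ``reason``); the reason lists every rule
        the SNP failed, comma-separated.
    """
    for name, v in (("maf_min", maf_min), ("miss_max", miss_max), ("hwe_alpha", hwe_alpha)):
        if not (0.0 < v < 1.0):
            raise ValueError(f"{name} must be in (0,1), got {v}")

    maf = snp_maf(g.dosages)
    miss = np.mean(~np.isfinite(g.dosages), axis=0)
    hwe_dos = g.dosages
    if phenotype is not None:
        controls = np.asarray(phenotype.status) == 0
        if controls.sum() >= 2:
            hwe_dos = g.dosages[controls]
    hwe_p = hwe_pvalues(hwe_dos)

    fail = {
        "low_maf": maf < maf_min,
        "high_missing": miss > miss_max,
        "hwe_deviation": hwe_p < hwe_alpha,
    }
    any_fail = np.zeros(g.n_snps, dtype=bool)
    for mask in fail.values():
        any_fail |= mask

    records = []
    for j in np.flatnonzero(any_fail):
        reasons = ",".join(name for name, mask in fail.items() if mask[j])
        records.append({"snp_id": g.snp_meta["snp_id"].iloc[j], "reason": reasons})
    exclusions = pd.DataFrame(records, columns=["snp_id", "reason"])

    if any_fail.all():
        raise NoMarkersError("no markers survive QC")
    return g.subset_snps(~any_fail), exclusions
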