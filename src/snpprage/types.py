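"""Core in-memory containers shared across the pipeline.

Genotypes are held as an additive-dosage matrix (samples x SNPs, minor-allele
counts 0/1/2, NaN for missing) together with a SNP map; phenotypes as a binary
status vector plus optional covariates; gene annotations and gene sets as
plain records.  Everything downstream (QC, association, LD modelling, set
testing) consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "GeneAnnotation",
    "SnpGeneMap",
    "GeneSetCollection",
]


@dataclass
class GenotypeMatrix:
    """Additive genotype dosages with SNP metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_snps)
        Minor-allele counts in {0, 1, 2}; ``nan`` marks a missing call.
    snp_meta : DataFrame
        One row per SNP column with columns ``snp_id``, ``chrom``, ``pos``
        (1-based bp).  Within each chromosome rows must be ordered by ``pos``.
    sample_ids : list of str
        Row labels, same order as ``dosages``.
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-d (samples x SNPs)")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ValueError(
                f"snp_meta has {len(self.snp_meta)} rows for "
                f"{self.dosages.shape[1]} dosage columns"
            )
        for col in ("snp_id", "chrom", "pos"):
            if col not in self.snp_meta.columns:
                raise ValueError(f"snp_meta missing column {col!r}")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(self.dosages.shape[0])]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        if (self.snp_meta["pos"] < 0).any():
            raise ValueError("SNP positions must be non-negative")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages != 0) & (self.dosages != 1) & (self.dosages != 2)
        if np.any(bad & np.isfinite(self.dosages)):
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("SNPs must be position-sorted within chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given SNP columns.

        ``keep`` may be a boolean mask or an integer index array; column
        order (hence position sorting) is preserved.
        """
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            snp_meta=self.snp_meta.iloc[keep].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class PhenotypeTable:
    """Binary case/control status plus optional covariates.

    ``status`` is 1 for cases and 0 for controls, aligned with the sample
    order of the genotype matrix it is analysed with.  ``covariates`` is a
    DataFrame (possibly empty) of numeric or categorical adjustment columns.
    """

    status: np.ndarray
    covariates: pd.DataFrame = None
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.status = np.asarray(self.status)
        uniq = set(np.unique(self.status).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"status must be binary 0/1, saw values {sorted(uniq)}")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=range(len(self.status)))
        if len(self.covariates) != len(self.status):
            raise ValueError("covariates and status lengths differ")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(len(self.status))]

    @property
    def n_samples(self) -> int:
        return len(self.status)

    def check_both_classes(self):
        if len(np.unique(self.status)) < 2:
            raise ValueError("phenotype must contain both cases and controls")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval in 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class SnpGeneMap:
    """Nearest-gene assignment of SNPs (at most one gene per SNP)."""

    snp_to_gene: dict
    unmapped: list = field(default_factory=list)

    def genes(self) -> set:
        return set(self.snp_to_gene.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": list(self.snp_to_gene), "gene_id": list(self.snp_to_gene.values())}
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set id -> member gene ids."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self):
        for sid, genes in self.sets.items():
            if len(genes) != len(set(genes)):
                raise ValueError(f"set {sid} has duplicate member genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def small_sets(self, min_set_size: int) -> list:
        return [sid for sid, genes in self.sets.items() if len(genes) < min_set_size]
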