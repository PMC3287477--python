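"""Readers and writers for the plain-text interchange formats.

Supported inputs
----------------
* genotypes: sample-per-row TSV (first column ``sample_id``, one column per
  SNP, header = SNP ids) and a PLINK ``.raw``-style dialect
  (``FID IID PAT MAT SEX PHENOTYPE`` then dosage columns);
* SNP map: 3-column TSV (``chrom  snp_id  pos``) and 6-column ``.bim``;
* phenotype/covariates: TSV keyed by sample id with a ``status`` column;
* genes: BED (0-based half-open, converted to 1-based inclusive on read)
  and a 4-column TSV already in 1-based inclusive coordinates;
* gene sets: GMT (set id, description, then member genes, tab-separated).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import GeneAnnotation, GenotypeMatrix, GeneSetCollection, PhenotypeTable

log = logging.getLogger(__name__)

RAW_META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


# ---------------------------------------------------------------- SNP map

def read_snp_map(path) -> pd.DataFrame:
    """Read a SNP map as a DataFrame with columns snp_id, chrom, pos.

    Accepts either the native 3-column TSV (chrom, snp_id, pos; header
    optional) or a 6-column PLINK .bim file (chrom, snp_id, cM, pos,
    allele1, allele2).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] == 6:  # .bim
        out = pd.DataFrame(
            {"snp_id": df[1], "chrom": df[0], "pos": df[3].astype(int)}
        )
        return out
    if df.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 (TSV) or 6 (.bim) columns, got {df.shape[1]}")
    if df.iloc[0].tolist() == ["chrom", "snp_id", "pos"]:
        df = df.iloc[1:].reset_index(drop=True)
    return pd.DataFrame(
        {"snp_id": df[1], "chrom": df[0], "pos": df[2].astype(int)}
    )


def write_snp_map(snp_meta: pd.DataFrame, path):
    snp_meta[["chrom", "snp_id", "pos"]].to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- genotypes

def read_genotypes(path, snp_map=None) -> GenotypeMatrix:
    """Read a genotype matrix from TSV or PLINK .raw dialect.

    The dialect is sniffed from the header: a header starting with
    ``FID IID`` is treated as .raw.  ``snp_map`` (path or DataFrame) supplies
    chrom/pos metadata; without it SNPs are placed on a pseudo-chromosome
    "0" at consecutive positions.
    """
    head = pd.read_csv(path, sep=r"\s+", nrows=0)
    cols = list(head.columns)
    if cols[:2] == ["FID", "IID"]:
        df = pd.read_csv(path, sep=r"\s+")
        sample_ids = df["IID"].astype(str).tolist()
        snp_cols = [c for c in cols if c not in RAW_META_COLS]
        # .raw may suffix the counted allele, e.g. rs123_A; strip only that
        snp_ids = [
            c.rsplit("_", 1)[0]
            if "_" in c and c.rsplit("_", 1)[1] in {"A", "C", "G", "T"}
            else c
            for c in snp_cols
        ]
        dosages = df[snp_cols].to_numpy(dtype=float)
    else:
        df = pd.read_csv(path, sep="\t")
        sample_ids = df.iloc[:, 0].astype(str).tolist()
        snp_ids = list(df.columns[1:])
        dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    meta = _resolve_snp_meta(snp_ids, snp_map)
    # order columns to match the (position-sorted) metadata
    order = [snp_ids.index(s) for s in meta["snp_id"]]
    return GenotypeMatrix(dosages=dosages[:, order], snp_meta=meta, sample_ids=sample_ids)


def _resolve_snp_meta(snp_ids, snp_map) -> pd.DataFrame:
    if snp_map is None:
        return pd.DataFrame(
            {"snp_id": snp_ids, "chrom": "0", "pos": np.arange(1, len(snp_ids) + 1)}
        )
    if not isinstance(snp_map, pd.DataFrame):
        snp_map = read_snp_map(snp_map)
    meta = snp_map[snp_map["snp_id"].isin(snp_ids)].copy()
    missing = set(snp_ids) - set(meta["snp_id"])
    if missing:
        raise ValueError(
            f"{len(missing)} genotype columns absent from the SNP map "
            f"(e.g. {sorted(missing)[:3]})"
        )
    meta = meta.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return meta[["snp_id", "chrom", "pos"]]


def write_genotypes_tsv(g: GenotypeMatrix, path):
    df = pd.DataFrame(g.dosages, columns=g.snp_ids)
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")


def write_genotypes_raw(g: GenotypeMatrix, path, phenotype: PhenotypeTable = None):
    """Write the PLINK .raw dialect (space-separated, PHENOTYPE coded 1/2)."""
    df = pd.DataFrame(g.dosages, columns=g.snp_ids)
    pheno = (
        (np.asarray(phenotype.status) + 1) if phenotype is not None else np.full(g.n_samples, -9)
    )
    meta = pd.DataFrame(
        {
            "FID": g.sample_ids,
            "IID": g.sample_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": pheno,
        }
    )
    pd.concat([meta, df], axis=1).to_csv(
        path, sep=" ", index=False, na_rep="NA", float_format="%g"
    )


# -------------------------------------------------------------- phenotype

def read_phenotypes(path, sample_ids=None) -> PhenotypeTable:
    """Read a phenotype/covariate TSV with columns sample_id, status, [covariates...].

    If ``sample_ids`` is given the table is reindexed to that order; missing
    samples raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table must have a {col!r} column")
    df = df.set_index("sample_id")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValueError(f"phenotype table lacks samples {missing[:3]}...")
        df = df.loc[[str(s) for s in sample_ids]]
    covars = df.drop(columns=["status"])
    return PhenotypeTable(
        status=df["status"].to_numpy(dtype=int),
        covariates=covars.reset_index(drop=True),
        sample_ids=list(df.index),
    )


def write_phenotypes(ph: PhenotypeTable, path):
    df = ph.covariates.copy()
    df.insert(0, "status", ph.status)
    df.insert(0, "sample_id", ph.sample_ids)
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ genes

def read_genes_bed(path) -> list:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    genes = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs >= 4 columns (chrom start end name)")
    for _, row in df.iterrows():
        genes.append(
            GeneAnnotation(
                gene_id=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]) + 1,
                end=int(row[2]),
            )
        )
    _check_unique_genes(genes)
    return genes


def read_genes_tsv(path) -> list:
    """Read gene intervals from 4-column TSV (gene_id chrom start end), 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene_id", "chrom", "start", "end"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: gene TSV must have columns {sorted(need)}")
    genes = [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    _check_unique_genes(genes)
    return genes


def _check_unique_genes(genes):
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dup[:3]}")


def write_genes_bed(genes, path):
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# -------------------------------------------------------------------- GMT

def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file.

    Each line is ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.  Duplicate
    genes within a line are dropped with a warning; an empty file yields an
    empty collection with a warning; a line with fewer than 3 columns is an
    error naming the line number.
    """
    sets, descriptions = {}, {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs set id, description and >=1 gene"
                )
            sid, desc, genes = parts[0], parts[1], parts[2:]
            genes = [g for g in genes if g]
            uniq = list(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                log.warning("GMT set %s: %d duplicate gene(s) dropped", sid, len(genes) - len(uniq))
            if sid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {sid}")
            sets[sid] = uniq
            descriptions[sid] = desc
    if n_lines == 0:
        log.warning("GMT file %s is empty", path)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path):
    with open(path, "w") as fh:
        for sid, genes in collection:
            desc = collection.descriptions.get(sid, "na")
            fh.write("\t".join([sid, desc] + list(genes)) + "\n")
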