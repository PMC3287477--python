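"""One-shot pipeline runs: file-based orchestration and the in-memory fast
path used by the simulation study."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import pandas as pd

from .model import SnpPrage
from .qc import QcThresholds

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_dataset"]


@dataclass
class RunConfig:
    """Configuration of a file-based pipeline run (defaults = the method's
    stated parameters: 500 kb window, r² 0.05, minimum set size 10, m = 1)."""

    genotypes: str
    phenotypes: str
    gene_sets: str
    genes: str
    snp_map: str | None = None
    outdir: str = "snpprage_out"
    m: int = 1
    method: str = "prage"
    window_bp: int = 500_000
    r2_threshold: float = 0.05
    min_set_size: int = 10
    maf_min: float = 0.01
    miss_max: float = 0.05
    hwe_alpha: float = 1e-6
    alternative: str = "less"
    scale: str = "log"
    comparison: str = "complement"
    fast: bool = False
    seed: int = 0

    def to_file(self, path):
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}={'' if v is None else v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                kv[k.strip()] = v.strip()
        import dataclasses

        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in kv:
                continue
            raw = kv[f.name]
            if raw == "":
                kwargs[f.name] = None
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            elif f.type in ("bool", bool):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


def run_pipeline(config: RunConfig):
    """Run QC -> association -> mapping -> LD -> summary -> set test from
    files, writing TSV outputs plus a manifest into ``config.outdir``.

    All inputs are checked before any output is written, so a missing file
    fails cleanly with its name and leaves no partial results.
    """
    inputs = {
        "genotypes": config.genotypes,
        "phenotypes": config.phenotypes,
        "genes": config.genes,
        "gene_sets": config.gene_sets,
    }
    if config.snp_map:
        inputs["snp_map"] = config.snp_map
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input {name!r}: {path}")

    model = SnpPrage.from_files(
        genotypes=config.genotypes,
        phenotypes=config.phenotypes,
        snp_map=config.snp_map,
        genes=config.genes,
        gene_sets=config.gene_sets,
        window_bp=config.window_bp,
        r2_threshold=config.r2_threshold,
        min_set_size=config.min_set_size,
        qc=QcThresholds(config.maf_min, config.miss_max, config.hwe_alpha),
        scale=config.scale,
        comparison=config.comparison,
    )
    try:
        results = model.fit(
            m=config.m,
            method=config.method,
            fast=config.fast,
            alternative=config.alternative,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed: {err}") from err

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = results.to_tsv(outdir)
    config.to_file(outdir / "run_config.txt")
    paths["config"] = str(outdir / "run_config.txt")
    for stage, count in results.manifest["counts"].items():
        log.info("%s: %d", stage, count)
    return results, paths


def analyze_dataset(
    ds,
    m_values=(1,),
    methods=("prage", "zmethod"),
    fast: bool = True,
    min_set_size: int = 10,
    r2_threshold: float = 0.05,
    scale: str = "log",
    eff_size: str = "galwey",
) -> dict:
    """Score an in-memory :class:`~snpprage.simulate.SimulatedDataset`.

    Returns ``{(method, m): Series set_id -> p-value}``; QC, the association
    scan and the LD stage are shared across the (method, m) grid.
    """
    model = SnpPrage(
        ds.genotypes,
        ds.phenotype,
        ds.genes,
        ds.gene_sets,
        min_set_size=min_set_size,
        r2_threshold=r2_threshold,
        scale=scale,
        eff_size=eff_size,
    )
    out = {}
    for method in methods:
        for m in m_values:
            res = model.fit(m=m, method=method, fast=fast)
            out[(method, m)] = pd.Series(
                res.sets["pvalue"].to_numpy(), index=res.sets["set_id"].to_numpy()
            )
    return out
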