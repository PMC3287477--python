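import numpy as np
import pandas as pd
import pytest

import snpprage as sp
from snpprage.simulate import TINY_CONFIG


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 50-sample, 2-set synthetic dataset shared across tests."""
    return sp.simulate_dataset(sp.SimulationConfig(seed=3, **TINY_CONFIG))


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    """The tiny dataset written to disk in every interchange format."""
    outdir = tmp_path_factory.mktemp("tiny_fixture")
    paths = sp.fixture_generator("tiny", outdir, seed=3)
    return paths


def make_genotypes(dosages, chrom="1", start_pos=100, spacing=10, snp_ids=None):
    """GenotypeMatrix from a raw dosage array with auto-generated metadata."""
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.shape[1]
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids or [f"rs{j + 1}" for j in range(p)],
            "chrom": chrom,
            "pos": start_pos + spacing * np.arange(p),
        }
    )
    return sp.GenotypeMatrix(dosages=dosages, snp_meta=meta)


def genotypes_from_counts(n0, n1, n2):
    """A single-SNP dosage column realising given genotype counts."""
    col = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2.0)])
    return col


@pytest.fixture
def rng():
    return np.random.default_rng(42)
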