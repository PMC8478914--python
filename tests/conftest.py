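import numpy as np
import pandas as pd
import pytest

from gradmap.io import MarkerMap, PhenotypeTable
from gradmap.fixtures import single_locus_architecture
from gradmap.simulate import f2_from_inbreds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_map():
    """Five markers, two chromosomes."""
    return MarkerMap(
        pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3", "m4", "m5"],
                "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
                "pos_bp": [100, 10_000, 2_000_000, 500, 900_000],
                "pos_cM": [0.0, 0.05, 8.0, 0.0, 3.6],
            }
        )
    )


@pytest.fixture
def pheno_table():
    vals = pd.DataFrame(
        {"rep1": [5.0, 5.1, 6.0, 6.1], "rep2": [5.0, 5.1, 6.0, 6.1]},
        index=pd.Index(["P1", "P2", "P3", "P4"], name="accession"),
    )
    return PhenotypeTable(vals)


@pytest.fixture
def additive_f2():
    """Noiseless single-locus additive F2 of 200 (QTL at marker M11)."""
    arch = single_locus_architecture(a=1.0, d=0.0, sigma_e=0.0)
    return arch, f2_from_inbreds(arch, 200, np.random.default_rng(7))
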