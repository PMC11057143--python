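import numpy as np
import pandas as pd
import pytest

from cattlegp.genotypes import GenotypeMatrix
from cattlegp.simdata import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small additive+non-additive cohort shared across tests."""
    cfg = SimConfig(
        n_individuals=200, n_markers=120, n_qtl_additive=30,
        n_qtl_dominance=10, n_qtl_epistatic_pairs=10,
        target_h2=0.35, target_d2=0.08, target_ep2=0.10, target_batch2=0.15,
        n_batches=8, seed=42,
    )
    g, arch, traits = simulate_cohort(cfg)
    return cfg, g, arch, traits


@pytest.fixture()
def tiny_genotypes():
    """Hand-built 4 x 3 genotype matrix with one missing call."""
    dos = np.array(
        [
            [0.0, 1.0, 2.0],
            [1.0, 1.0, 0.0],
            [2.0, np.nan, 1.0],
            [0.0, 1.0, 1.0],
        ]
    )
    meta = pd.DataFrame(
        {
            "id": ["m1", "m2", "m3"],
            "chrom": ["1", "2", "3"],
            "pos": [100, 200, 300],
            "a1": ["A", "C", "G"],
            "a2": ["B", "T", "A"],
        }
    )
    return GenotypeMatrix(dos, np.array(["s1", "s2", "s3", "s4"], dtype=object), meta)
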