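import numpy as np
import pandas as pd
import pytest

from magicgs.genotypes import GenotypeMatrix, filter_maf, vanraden_grm
from magicgs.phenotypes import derive_traits
from magicgs.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim():
    """Modest synthetic MAGIC study shared across suites (80 lines, 400 SNPs)."""
    cfg = SimConfig(seed=11, n_magic_lines=80, n_phenotyped=60, n_snps=400)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def derived(sim):
    return derive_traits(sim.pheno)


@pytest.fixture(scope="session")
def grm(sim):
    return vanraden_grm(filter_maf(sim.gm, 0.04))


@pytest.fixture()
def tiny_gm():
    """Hand-written 3-line x 4-SNP genotype matrix."""
    dosages = np.array(
        [
            [0, 1, 2, 1],
            [1, 1, 0, 2],
            [2, 0, 1, 1],
        ],
        dtype=float,
    )
    marker_map = pd.DataFrame(
        {
            "marker": ["m1", "m2", "m3", "m4"],
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "pos": [100, 5000, 200, 9000],
        }
    )
    return GenotypeMatrix(["A", "B", "C"], dosages, marker_map)
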