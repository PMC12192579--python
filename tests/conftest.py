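import numpy as np
import pytest

from mlgscan.genotypes import GenotypeMatrix
from mlgscan.simulate import SimulationConfig, simulate_genotypes


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_genome():
    """10 individuals x 80 SNPs, mild LD — enough for window/stretch math."""
    return simulate_genotypes(SimulationConfig(n=10, L=80, rho=0.3, seed=7))


@pytest.fixture()
def tiny_matrix():
    """Hand-sized 4 x 6 genotype matrix with known content."""
    G = np.array(
        [
            [0, 1, 2, 0, 1, 2],
            [0, 1, 2, 0, 1, 2],
            [2, 1, 0, 2, 1, 0],
            [1, 1, 1, 1, 1, 1],
        ]
    )
    return GenotypeMatrix(
        chrom="chrT",
        positions=np.array([10, 20, 30, 40, 50, 60]),
        G=G,
        sample_ids=["a", "b", "c", "d"],
    )
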