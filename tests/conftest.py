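import numpy as np
import pytest

from gpbench.genosim import GenotypeMatrix, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geno():
    """200 x 120 binomial genotype matrix, fixed seed."""
    return simulate_genotypes(200, 120, maf=0.4, seed=42)


@pytest.fixture
def tiny_geno():
    """Hand-constructed 4 x 3 matrix for exact-value checks."""
    dosages = np.array(
        [
            [0, 1, 2],
            [1, 1, 0],
            [2, 0, 1],
            [0, 2, 1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        marker_ids=np.array(["m1", "m2", "m3"], dtype=object),
        chromosome=np.array(["chr1", "chr1", "chr2"], dtype=object),
        position_bp=np.array([1000, 2000, 1000]),
    )
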