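import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from refugia.genotypes import GenotypeDataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def worked_dataset():
    """Fixed 3-population x 4-individual x 2-locus table for oracle checks."""
    alleles = np.array(
        [
            # pop 0
            [[10, 10], [7, 8]],
            [[10, 11], [8, 8]],
            [[11, 11], [7, 7]],
            [[10, 12], [8, 9]],
            # pop 1
            [[12, 12], [7, 9]],
            [[11, 12], [9, 9]],
            [[12, 13], [8, 9]],
            [[11, 11], [9, 9]],
            # pop 2
            [[13, 13], [7, 7]],
            [[12, 13], [7, 8]],
            [[13, 14], [7, 7]],
            [[10, 13], [8, 8]],
        ],
        dtype=np.int64,
    )
    pops = np.repeat([0, 1, 2], 4)
    return GenotypeDataset(alleles=alleles, pops=pops)


def random_dataset(rng, n_pops=4, n_per_pop=12, n_loci=3, allele_range=(8, 15)):
    """Random polymorphic dataset for property checks."""
    n = n_pops * n_per_pop
    alleles = rng.integers(allele_range[0], allele_range[1], size=(n, n_loci, 2))
    return GenotypeDataset(alleles=alleles, pops=np.repeat(np.arange(n_pops), n_per_pop))
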