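import numpy as np
import pytest

from hybridscaf import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """A 2 x 300 kb genome shared by fast unit tests."""
    genome, truth = sim.simulate_genome(
        n_chrom=2, chrom_length_bp=300_000, repeat_copy_number=3, seed=1234
    )
    return genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
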