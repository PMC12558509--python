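import numpy as np
import pytest

from ddcfdna.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def small_config():
    """Two 100-kb chromosomes plus the absent-control chromosome."""
    return SimulationConfig(
        chrom_lengths={"chr1": 100_000, "chr2": 100_000, "chrY": 20_000},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One full simulated dataset reused by read-only tests."""
    config = SimulationConfig(
        chrom_lengths={"chr1": 100_000, "chr2": 100_000, "chrY": 20_000},
        donor_fraction=0.05,
        mean_depth=500.0,
        error_rate=0.001,
        seed=23,
    )
    return simulate_dataset(config, n_fragments=2000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
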