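import numpy as np
import pytest

from aptapanel import (
    SimulationConfig,
    generate_cohort,
    generate_library,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A quick 60-aptamer pool with 4 planted families and 2x10 samples."""
    return SimulationConfig(
        n_aptamers=60,
        n_families=4,
        fraction_in_families=0.5,
        group_sizes={"healthy": 0, "MASLD_no_SH": 10, "MASH": 10},
        library_size_range=(20_000, 40_000),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return generate_library(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_config, small_library, small_cohort):
    return simulate_counts(small_library, small_cohort, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
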