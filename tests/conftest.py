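import numpy as np
import pytest

from thermoniche import (
    SyntheticWorldConfig,
    generate_bias_surface,
    generate_ecoregions,
    generate_world,
    sample_occurrences,
)
from thermoniche.compare import run_species_pipeline
from thermoniche.sdm import HyperparameterSpace


@pytest.fixture(scope="session")
def small_config():
    return SyntheticWorldConfig(
        seed=11, extent=(0.0, 40.0, 2.0, 42.0), cell_size=0.05, n_occurrences=400
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_ecoregions(small_world):
    return generate_ecoregions(small_world)


@pytest.fixture(scope="session")
def small_bias(small_world):
    return generate_bias_surface(small_world)


@pytest.fixture(scope="session")
def small_records(small_world, small_bias):
    return sample_occurrences(small_world, bias=small_bias)


@pytest.fixture(scope="session")
def tiny_space():
    """Minimal tuning budget for unit tests that need a fitted model."""
    return HyperparameterSpace(max_boost_rounds=60, max_opt_rounds=3, early_stopping_rounds=10)


@pytest.fixture(scope="session")
def small_pipeline(small_config, tiny_space):
    """One full pipeline run shared by interpretation/importance tests."""
    return run_species_pipeline(small_config, n_bootstrap=2, space=tiny_space)
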