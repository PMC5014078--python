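import numpy as np
import pytest

from lesionprog import generate_cohort, pipeline
from lesionprog.simulate import SimulationConfig


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down cohort: quick to simulate, same structure."""
    defaults = dict(
        n_group_a=60,
        n_group_b=16,
        n_regions=16,
        n_tasks=4,
        grid_dims=(10, 12, 10),
        voxel_volume=125.0,
        n_active_regions=4,
        noise_sd=4.0,
        noise_shared_sd=0.0,  # task-independent noise: per-task machinery tests
        missing_rate=0.0,
        seed=123,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort under the null: lambda = 1, no intercept shift."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def shifted_cohort():
    """Small cohort with enhanced group-b lesion sensitivity (lambda=1.5)."""
    return generate_cohort(small_config(lambda_sensitivity=1.5, seed=321))


@pytest.fixture(scope="session")
def null_tables(null_cohort):
    return pipeline.split_tables(null_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
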