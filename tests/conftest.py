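import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plastedit.fixtures import load_table1_fixture
from plastedit.simulate import SimulationConfig, build_synthetic_plastome

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def small_config():
    """A small plastome configuration shared by simulator-level tests."""
    return SimulationConfig(
        genome_length=4000,
        gene_count=4,
        intron_fraction=0.5,
        mean_coverage=50.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_plastome(small_config):
    return build_synthetic_plastome(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
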