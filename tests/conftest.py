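import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from pdxresist.somatic_filters import apply_exclusion_filters
from pdxresist.synthetic_data import SimulationConfig, simulate_variant_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    """Noise-free default cohort: the planted study conditions."""
    return SimulationConfig(seed=7, noise_free=True)


@pytest.fixture(scope="session")
def noise_free_cohort(default_config):
    table, truth = simulate_variant_cohort(default_config)
    return table, truth, default_config.roles()


@pytest.fixture(scope="session")
def somatic_cohort(noise_free_cohort):
    table, truth, roles = noise_free_cohort
    somatic, dropped = apply_exclusion_filters(table, roles)
    return somatic, dropped, truth, roles
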