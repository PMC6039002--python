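import pytest
from hypothesis import HealthCheck, settings

from mztsim.config import preset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_scenario():
    return preset("table1_default")


@pytest.fixture(scope="session")
def two_generation_records(default_scenario):
    """The canonical two-generation run at default parameters (shared, read-only)."""
    from mztsim.lifecycle import run_simulation

    s = default_scenario
    return run_simulation(
        s.growth, s.sexes, env=s.env, n_generations=2, initial_state=s.initial_states
    )
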