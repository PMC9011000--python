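import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from circena import simulate  # noqa: E402


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_reference(sim_config):
    return simulate.simulate_reference(sim_config)


@pytest.fixture(scope="session")
def sim_reads(sim_config, sim_reference):
    bundle, truth = sim_reference
    return simulate.simulate_reads(bundle, truth, sim_config)


@pytest.fixture(scope="session")
def sim_expression(sim_config, sim_reference):
    _, truth = sim_reference
    return simulate.simulate_expression_and_traits(sim_config, truth)
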