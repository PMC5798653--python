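import pytest
from hypothesis import HealthCheck, settings

from igfmr.harmonize import harmonize_tables
from igfmr.simulate import SimConfig, default_instrument_specs, simulate_two_sample

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel_specs():
    """The packaged 10-SNP instrument panel (9 main + bivariate-opposite)."""
    return default_instrument_specs(include_bivariate=True)


@pytest.fixture(scope="session")
def fixture_config(panel_specs):
    return SimConfig(n_snps=10, specs=panel_specs, seed=1729)


@pytest.fixture(scope="session")
def fixture_sim(fixture_config):
    return simulate_two_sample(fixture_config)


@pytest.fixture(scope="session")
def harmonized(fixture_sim):
    iset, report = harmonize_tables(fixture_sim.exposure, fixture_sim.outcome, fixture_sim.specs)
    return iset, report
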