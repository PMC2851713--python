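import pytest

from hipscreen import CostParams, PopulationParams, enumerate_scenarios


@pytest.fixture(scope="session")
def pop():
    return PopulationParams()


@pytest.fixture(scope="session")
def costs():
    return CostParams()


@pytest.fixture(scope="session")
def specs():
    return enumerate_scenarios()


@pytest.fixture(scope="session")
def expected_results(pop, costs, specs):
    """Deterministic closed-form results for all 72 scenarios."""
    from hipscreen import expected_scenario

    return [expected_scenario(s, pop, costs) for s in specs]
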