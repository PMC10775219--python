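import pytest

import pocplan as p

CANONICAL_SEED = 1  # the packaged synthetic county used across tests


@pytest.fixture(scope="session")
def county():
    """The packaged 146-clinic synthetic county."""
    return p.generate_instance(p.GeneratorConfig(seed=CANONICAL_SEED))


@pytest.fixture(scope="session")
def scenario_reports(county):
    """Scenario 1-3 reports on the canonical county (solved once)."""
    return {
        1: p.run_scenario(county, 1),
        2: p.run_scenario(county, 2),
        3: p.run_scenario(county, 3, p_add=7, fairness=True),
    }


@pytest.fixture()
def small_instance():
    return p.make_fixture_small(seed=0)
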