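import pytest
from hypothesis import settings

from screencea import Policy, ScreeningCEA, baseline_scenario
from screencea.synthetic import ScenarioSampler, toy_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def baseline():
    return baseline_scenario()


@pytest.fixture(scope="session")
def gov_policy():
    return Policy(name="government", private_share=0.0)


@pytest.fixture(scope="session")
def private_policy():
    return Policy(name="private", private_share=1.0)


@pytest.fixture(scope="session")
def toy():
    return toy_fixture()


@pytest.fixture(scope="session")
def sampler():
    return ScenarioSampler(seed=20260101)


@pytest.fixture(scope="session")
def model(baseline):
    return ScreeningCEA(baseline)
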