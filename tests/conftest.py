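import pytest

from chirodeb import ForcingScenario, chironomus_riparius, simulate_lifecycle


@pytest.fixture(scope="session")
def params():
    return chironomus_riparius()


@pytest.fixture(scope="session")
def scenario21():
    return ForcingScenario(T_celsius=21.0, f_constant=1.0)


@pytest.fixture(scope="session")
def sim21(params, scenario21):
    """Full ad-libitum life cycle at 21 degC, shared across tests."""
    return simulate_lifecycle(params, scenario21)


@pytest.fixture(scope="session")
def report21(sim21):
    return sim21.report
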