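import pytest

from cmnutricycle import nbalance, params


@pytest.fixture(scope="session")
def scenario():
    return params.default_scenario()


@pytest.fixture(scope="session")
def cm(scenario):
    return scenario.cm_batch


@pytest.fixture(scope="session")
def animals(scenario):
    return scenario.animals


@pytest.fixture(scope="session")
def soy(scenario):
    return scenario.feedstocks["soy"]


@pytest.fixture(scope="session")
def corn(scenario):
    return scenario.feedstocks["corn"]


@pytest.fixture(scope="session")
def econ(scenario):
    return scenario.economics


@pytest.fixture(scope="session")
def batch(cm):
    return nbalance.batch_balance(cm)


@pytest.fixture(scope="session")
def scen_high(cm, batch):
    return nbalance.scale_scenario(cm, 25.0, 1e7, batch)


@pytest.fixture(scope="session")
def scen_low(cm, batch):
    return nbalance.scale_scenario(cm, 10.0, 1e7, batch)
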