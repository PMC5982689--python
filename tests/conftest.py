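import pytest

from gripsim import load_scenario


@pytest.fixture(scope="session")
def paper_scenario():
    return load_scenario("paper_default")


@pytest.fixture(scope="session")
def bhp_scenario():
    return load_scenario("cell_BHP")


@pytest.fixture(scope="session")
def serpentine_scenario():
    return load_scenario("serpentine_springs")
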