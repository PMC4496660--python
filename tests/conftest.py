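import pytest

from semfood import MatchConfig
from semfood.fixtures import worked_example


@pytest.fixture(scope="session")
def worked():
    """(graph, consumer, product1, product2) of the packaged worked example."""
    return worked_example()


@pytest.fixture(scope="session")
def graph(worked):
    return worked[0]


@pytest.fixture
def example_cfg():
    return MatchConfig(convention="example")


@pytest.fixture
def definition_cfg():
    return MatchConfig(convention="definition")
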