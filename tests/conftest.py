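import pytest

from meridian_balance.patterns import balanced_quads, counting_cascade
from meridian_balance.systems import enumerate_systems, merged_balance_graph


@pytest.fixture(scope="session")
def systems():
    return enumerate_systems()


@pytest.fixture(scope="session")
def graph(systems):
    return merged_balance_graph(systems=systems)


@pytest.fixture(scope="session")
def graph_with_step5(systems):
    return merged_balance_graph(exclude_step5=False, systems=systems)


@pytest.fixture(scope="session")
def quads(graph):
    return balanced_quads(graph)


@pytest.fixture(scope="session")
def cascade(graph):
    return counting_cascade(graph)
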