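import numpy as np
import pytest

from cycleflow.fixtures import (
    EXAMPLE_DHG_XML,
    chain_mid_loop_graph,
    chain_tail_loop_graph,
    example_dhg_graph,
    increment_bindings,
    two_node_loop_graph,
)
from cycleflow.model import graph as make_graph


@pytest.fixture
def example_graph():
    return example_dhg_graph()


@pytest.fixture
def example_xml():
    return EXAMPLE_DHG_XML


@pytest.fixture
def tail_loop():
    """A→B→(C+D)→E→F↔G: chain feeding a terminal dicycle."""
    return chain_tail_loop_graph()


@pytest.fixture
def mid_loop():
    """A→B→(C+D)→E↔F→(G+H)→I: dicycle between two DAG segments."""
    return chain_mid_loop_graph()


@pytest.fixture
def increment_ring():
    """Three-node cycle A→B→C→A, every service x↦x+1, initial input 0."""
    g = make_graph(
        ["A", "B", "C"],
        [("eab", "A", "B"), ("ebc", "B", "C"), ("eca", "C", "A")],
        entrypoint="A",
        initial_values={"A": {"init": 0}},
    )
    return g, increment_bindings(g)


@pytest.fixture
def pm_ctl_loop():
    """Minimal two-node plant↔controller loop (entrypoint PM)."""
    g = two_node_loop_graph("PM", "CTL", init=0)
    return g, increment_bindings(g)


@pytest.fixture
def rng():
    return np.random.default_rng(20211)
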