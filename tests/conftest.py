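import numpy as np
import pandas as pd
import pytest

from dagsem import (
    DirectedGraph,
    SEMParameters,
    draw_weights,
    population_covariance,
    random_dag,
    simulate_sem,
)


@pytest.fixture
def chain3():
    """Y1 -> Y2 -> Y3 with beta = 0.8, unit error variance."""
    dag = DirectedGraph(["Y1", "Y2", "Y3"], [("Y1", "Y2"), ("Y2", "Y3")])
    return SEMParameters(dag, {("Y1", "Y2"): 0.8, ("Y2", "Y3"): 0.8})


@pytest.fixture
def chain2():
    """Y2 = 0.8 * Y1 + U with unit error variance."""
    dag = DirectedGraph(["Y1", "Y2"], [("Y1", "Y2")])
    return SEMParameters(dag, {("Y1", "Y2"): 0.8})


@pytest.fixture
def diamond():
    return DirectedGraph("abcd", [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")])


@pytest.fixture
def chain_graph():
    return DirectedGraph("abc", [("a", "b"), ("b", "c")])


def random_sem(p, edge_prob, seed, magnitude=(0.5, 1.0)):
    dag = random_dag(p, edge_prob, seed)
    return draw_weights(dag, magnitude, seed=seed + 10_000)


def peel_layers_oracle(g: DirectedGraph):
    """Independent layer oracle: iterated in-degree-0 peeling via networkx."""
    import networkx as nx

    nxg = g.to_networkx()
    layers = []
    while nxg.number_of_nodes():
        sources = sorted(v for v in nxg.nodes if nxg.in_degree(v) == 0)
        layers.append(tuple(sources))
        nxg.remove_nodes_from(sources)
    return tuple(layers)
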