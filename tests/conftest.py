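import networkx as nx
import numpy as np
import pandas as pd
import pytest

from tippingnet.dnb import LogRatioMatrix
from tippingnet.io import GeneNetwork
from tippingnet.propagation import PropagationModule


@pytest.fixture
def triangle() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_abc() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def worked_matrix() -> LogRatioMatrix:
    """3 genes x 4 patients with known SD/correlation structure."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [1.0, -1.0, 1.0, -1.0]],
        index=["G1", "G2", "G3"],
        columns=["p1", "p2", "p3", "p4"],
    )
    return LogRatioMatrix(values=values)


def make_module(seed: str, members: set[str], score: float = 0.5) -> PropagationModule:
    return PropagationModule(
        seed=seed, members=set(members), scores={g: score for g in members}
    )


def random_connected_graph(rng: np.random.Generator, n: int, p: float = 0.05) -> GeneNetwork:
    """Erdos-Renyi graph patched to be connected by a random spanning path."""
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
    order = list(g.nodes)
    rng.shuffle(order)
    for a, b in zip(order, order[1:]):
        g.add_edge(a, b)
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in g.nodes})
    return GeneNetwork(g)
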