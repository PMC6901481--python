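import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pahomics.interactome as pin
import pahomics.synthio as psy
from pahomics.omics_io import IntensityMatrix

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 features x 4 samples raw matrix with one missing cell."""
    values = pd.DataFrame(
        [[100.0, 110.0, 95.0, 105.0],
         [10.0, 12.0, np.nan, 11.0],
         [1000.0, 900.0, 1100.0, 950.0],
         [50.0, 55.0, 45.0, 52.0]],
        index=["F1", "F2", "F3", "F4"],
        columns=["c1", "c2", "k1", "k2"])
    groups = {"c1": "case", "c2": "case", "k1": "control", "k2": "control"}
    return IntensityMatrix(values=values, groups=groups)


@pytest.fixture(scope="session")
def ba_graph_500():
    """Scale-free 500-node graph used by the proximity simulations."""
    cfg = psy.SimConfig(seed=7, n_nodes=500, edges_per_node=3)
    return psy.generate_interactome(cfg)


def random_interactome(rng, n_nodes, p_edge=0.15):
    """Erdos-Renyi-style random graph as an Interactome (test helper)."""
    import networkx as nx
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(nodes[i], nodes[j], evidence=frozenset({"LIT"}))
    if g.number_of_edges() == 0:
        g.add_edge(nodes[0], nodes[1], evidence=frozenset({"LIT"}))
    return pin.Interactome(g)


def floyd_warshall_oracle(net):
    """Independent all-pairs shortest paths by the classic triple loop."""
    nodes = net.sorted_nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in net.graph.edges:
        dist[idx[u], idx[v]] = 1.0
        dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k][:, None] + dist[k, :][None, :])
    return dist, idx
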