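import itertools

import networkx as nx
import numpy as np
import pytest


def random_small_graphs(max_nodes=8, count=30, seed=123, min_nodes=3):
    """A reproducible battery of small random graphs (some disconnected)."""
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(count):
        n = int(rng.integers(min_nodes, max_nodes + 1))
        p = float(rng.uniform(0.15, 0.8))
        nodes = [f"N{i}" for i in range(n)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < p:
                g.add_edge(a, b)
        graphs.append(g)
    return graphs


@pytest.fixture(scope="session")
def small_graph_battery():
    return random_small_graphs()


@pytest.fixture()
def tmp_tsv(tmp_path):
    def write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write
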