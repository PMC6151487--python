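import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from subpathways import PathwayGraph, PathwayNode


def path_graph(node_ids):
    """A simple chain of compound nodes (valid: every edge touches a compound)."""
    g = PathwayGraph(pathway_id="path:test")
    for i, node_id in enumerate(node_ids):
        g.add_node(PathwayNode(node_id, "compound", frozenset({f"C{i:05d}"})))
    for u, v in zip(node_ids, node_ids[1:]):
        g.add_edge(u, v)
    return g


def random_connected_graph(rng, n_nodes, extra_edge_prob=0.15):
    """Random connected undirected adjacency dict over string node ids."""
    nodes = [f"v{i:02d}" for i in range(n_nodes)]
    adjacency = {v: set() for v in nodes}
    order = list(nodes)
    rng.shuffle(order)
    for i, node in enumerate(order[1:], start=1):
        anchor = order[int(rng.integers(i))]
        adjacency[node].add(anchor)
        adjacency[anchor].add(node)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            if v not in adjacency[u] and rng.random() < extra_edge_prob:
                adjacency[u].add(v)
                adjacency[v].add(u)
    return adjacency


def graph_from_adjacency(adjacency, pathway_id="path:rnd"):
    """Wrap an adjacency dict as a compound-only PathwayGraph."""
    g = PathwayGraph(pathway_id=pathway_id)
    for i, node_id in enumerate(sorted(adjacency)):
        g.add_node(PathwayNode(node_id, "compound", frozenset({f"C{i:05d}"})))
    seen = set()
    for u, nbrs in adjacency.items():
        for v in nbrs:
            if frozenset((u, v)) not in seen:
                seen.add(frozenset((u, v)))
                g.add_edge(u, v)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
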