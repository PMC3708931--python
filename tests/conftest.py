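"""Shared fixtures: small graphs and oracle implementations.

The oracles here are deliberately naive (exhaustive enumeration,
repeated pruning) and independent of the library code paths they
check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from coexmod.network import MI_KEY


def make_weighted(edges) -> nx.Graph:
    """Graph from (u, v, mi) triples."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, **{MI_KEY: float(w)})
    return g


def random_mi_graph(rng: np.random.Generator, n_nodes: int, p_edge: float) -> nx.Graph:
    g = nx.Graph()
    labels = [f"n{i:02d}" for i in range(n_nodes)]
    g.add_nodes_from(labels)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.uniform() < p_edge:
            g.add_edge(labels[i], labels[j], **{MI_KEY: float(rng.uniform(0.01, 1.0))})
    return g


def dpi_oracle(net: nx.Graph, eps: float = 0.0) -> nx.Graph:
    """Exhaustive all-triangles DPI: mark weakest strict-minimum edges."""
    marked = set()
    for a, b, c in itertools.combinations(sorted(net.nodes), 3):
        if not (net.has_edge(a, b) and net.has_edge(a, c) and net.has_edge(b, c)):
            continue
        trio = [
            (net[a][b][MI_KEY], (a, b)),
            (net[a][c][MI_KEY], (a, c)),
            (net[b][c][MI_KEY], (b, c)),
        ]
        trio.sort(key=lambda t: t[0])
        lo, mid, _ = trio
        if lo[0] < mid[0] and lo[0] < (1.0 - eps) * mid[0]:
            marked.add(lo[1])
    out = net.copy()
    out.remove_edges_from(marked)
    return out


def kcore_by_pruning(g: nx.Graph, k: int) -> set:
    """k-core via repeated removal of low-degree nodes (no networkx)."""
    nodes = set(g.nodes)
    changed = True
    while changed:
        changed = False
        for v in list(nodes):
            deg = sum(1 for u in g.neighbors(v) if u in nodes)
            if deg < k:
                nodes.discard(v)
                changed = True
    return nodes


def vertex_weight_oracle(g: nx.Graph, v) -> float:
    """Brute force: try every k until the k-core of N[v] empties."""
    closed = {v} | set(g.neighbors(v))
    sub = g.subgraph(closed)
    best_k, best_nodes = 0, set()
    for k in range(1, len(closed) + 1):
        nodes = kcore_by_pruning(sub, k)
        if nodes:
            best_k, best_nodes = k, nodes
        else:
            break
    if best_k == 0:
        return 0.0
    core = g.subgraph(best_nodes)
    n = core.number_of_nodes()
    density = 0.0 if n < 2 else 2.0 * core.number_of_edges() / (n * (n - 1))
    return best_k * density


@pytest.fixture
def triangle() -> nx.Graph:
    return make_weighted([("a", "b", 0.5), ("b", "c", 0.4), ("a", "c", 0.3)])


@pytest.fixture
def two_cliques_with_bridge_vertex() -> nx.Graph:
    """Two K5s whose attachment vertices are joined through a low-degree
    bridge vertex."""
    g = nx.Graph()
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(5)]
    for grp in (a, b):
        for u, v in itertools.combinations(grp, 2):
            g.add_edge(u, v, **{MI_KEY: 1.0})
    g.add_edge("a4", "bridge", **{MI_KEY: 1.0})
    g.add_edge("bridge", "b4", **{MI_KEY: 1.0})
    return g
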