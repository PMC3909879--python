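"""Shared test helpers: independent brute-force betweenness oracle.

The oracle enumerates every simple path between each unordered node
pair with its own recursive DFS, keeps the shortest ones, and
accumulates the through-node / through-edge path fractions directly
from the definitions.  It shares no code with the implementation under
test and is only feasible on tiny graphs (<= ~8 nodes).
"""

from __future__ import annotations

import itertools
import random
from typing import Dict, List, Tuple

import networkx as nx
import pytest

from netintegrity.graph import build_graph


def _all_simple_paths(adj, start, goal) -> List[Tuple[str, ...]]:
    paths = []

    def dfs(node, visited, path):
        if node == goal:
            paths.append(tuple(path))
            return
        for nxt in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                dfs(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    dfs(start, {start}, [start])
    return paths


def brute_force_betweenness(g: nx.Graph):
    """(node betweenness, edge betweenness) from first principles."""
    adj = {n: sorted(g.neighbors(n)) for n in g.nodes}
    nodes = sorted(g.nodes)
    node_b: Dict[str, float] = {n: 0.0 for n in nodes}
    edge_b: Dict[Tuple[str, str], float] = {
        tuple(sorted(e)): 0.0 for e in g.edges
    }
    for i, j in itertools.combinations(nodes, 2):
        paths = _all_simple_paths(adj, i, j)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sps = [p for p in paths if len(p) == shortest]
        g_ij = len(sps)
        for k in nodes:
            if k in (i, j):
                continue
            g_ikj = sum(1 for p in sps if k in p)
            node_b[k] += g_ikj / g_ij
        for edge in edge_b:
            u, v = edge
            g_iej = sum(
                1
                for p in sps
                if any(
                    (p[t], p[t + 1]) == (u, v) or (p[t], p[t + 1]) == (v, u)
                    for t in range(len(p) - 1)
                )
            )
            edge_b[edge] += g_iej / g_ij
    return node_b, edge_b


def random_small_graph(rng: random.Random, max_nodes: int = 8) -> nx.Graph:
    """Seeded random simple graph on <= max_nodes string-labeled nodes."""
    n = rng.randint(2, max_nodes)
    p = rng.uniform(0.1, 0.9)
    names = [f"V{i}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return build_graph(edges, extra_nodes=names)


@pytest.fixture
def path4():
    return build_graph([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def star4():
    return build_graph([("X", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def triangle():
    return build_graph([("A", "B"), ("B", "C"), ("A", "C")])
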