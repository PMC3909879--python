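"""Deterministic synthetic graphs and expression tables.

These fixtures emulate the topologies the analysis targets — chains,
hubs, and in particular ``parallel_cascades``: k node-disjoint
signal-transduction chains sharing one source and one sink, the motif
(ERK1/2, JNK, p38 ...) whose simultaneous targeting motivates
removal-based ranking.  Every generator is fully determined by its
parameters (plus a seed for the random kinds), so identical calls yield
identical graphs.
"""

from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np

from netintegrity.graph import build_graph
from netintegrity.restriction import ExpressionTable

FIXTURE_KINDS = (
    "path",
    "cycle",
    "star",
    "complete",
    "barbell",
    "parallel_cascades",
    "random_gnp",
)

CASCADE_SOURCE = "SRC"
CASCADE_SINK = "SNK"


def _label(i: int) -> str:
    return f"N{i:03d}"


def generate_fixture(kind: str, seed: Optional[int] = None, **params) -> nx.Graph:
    """Generate a synthetic graph of the given kind.

    Kinds and size parameters:

    * ``path(n)`` — chain of n nodes;
    * ``cycle(n)`` — ring of n >= 3 nodes;
    * ``star(leaves)`` — hub ``HUB`` with the given number of leaves;
    * ``complete(n)`` — K_n;
    * ``barbell(clique, bridge)`` — two K_clique joined by a path of
      ``bridge`` intermediate nodes (0 for a direct bridge edge);
    * ``parallel_cascades(k, length)`` — k >= 2 node-disjoint chains of
      ``length`` nodes each, all sharing source ``SRC`` and sink
      ``SNK``: 2 + k*length nodes, k*(length+1) edges;
    * ``random_gnp(n, p)`` — Erdős–Rényi G(n, p), requires ``seed``.
    """
    if kind == "path":
        n = _positive(params, "n")
        return build_graph(
            [(_label(i), _label(i + 1)) for i in range(n - 1)],
            extra_nodes=[_label(0)] if n == 1 else None,
        )
    if kind == "cycle":
        n = _positive(params, "n")
        if n < 3:
            raise ValueError(f"a cycle needs n >= 3 nodes, got {n}")
        return build_graph(
            [(_label(i), _label((i + 1) % n)) for i in range(n)]
        )
    if kind == "star":
        leaves = _positive(params, "leaves")
        return build_graph([("HUB", f"LEAF{i:03d}") for i in range(leaves)])
    if kind == "complete":
        n = _positive(params, "n")
        if n < 2:
            raise ValueError(f"a complete graph needs n >= 2, got {n}")
        return build_graph(
            [(_label(i), _label(j)) for i in range(n) for j in range(i + 1, n)]
        )
    if kind == "barbell":
        clique = _positive(params, "clique")
        bridge = params.get("bridge", 0)
        if clique < 3 or bridge < 0:
            raise ValueError("barbell needs clique >= 3 and bridge >= 0")
        left = [f"L{i:03d}" for i in range(clique)]
        right = [f"R{i:03d}" for i in range(clique)]
        mid = [f"M{i:03d}" for i in range(bridge)]
        edges = [(a, b) for side in (left, right) for a in side for b in side if a < b]
        chain = [left[0], *mid, right[0]]
        edges += list(zip(chain, chain[1:]))
        return build_graph(edges)
    if kind == "parallel_cascades":
        k = _positive(params, "k")
        length = _positive(params, "length")
        if k < 2:
            raise ValueError(f"parallel_cascades needs k >= 2 chains, got {k}")
        edges = []
        for c in range(1, k + 1):
            chain = [f"C{c}_{j:02d}" for j in range(1, length + 1)]
            edges += list(zip([CASCADE_SOURCE, *chain], [*chain, CASCADE_SINK]))
        return build_graph(edges)
    if kind == "random_gnp":
        n = _positive(params, "n")
        p = params.get("p")
        if p is None or not 0 <= p <= 1:
            raise ValueError(f"random_gnp needs p in [0, 1], got {p}")
        if seed is None:
            raise ValueError("random_gnp requires a seed")
        raw = nx.gnp_random_graph(n, p, seed=seed)
        return build_graph(
            [(_label(u), _label(v)) for u, v in raw.edges()],
            extra_nodes=[_label(i) for i in raw.nodes()],
        )
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")


def _positive(params: dict, name: str) -> int:
    value = params.get(name)
    if not isinstance(value, int) or value < 1:
        raise ValueError(f"parameter {name!r} must be a positive integer, got {value!r}")
    return value


def cascade_of(node: str) -> Optional[str]:
    """Cascade label ("C1", "C2", ...) of a parallel_cascades chain
    node; None for the shared source/sink."""
    if node in (CASCADE_SOURCE, CASCADE_SINK):
        return None
    return node.split("_", 1)[0]


def generate_expression_fixture(
    g: nx.Graph, fraction_unexpressed: float, seed: int
) -> ExpressionTable:
    """Numeric expression table over g's nodes with a known answer.

    A seeded random subset of ``round(fraction * n)`` genes receives
    RPKM-like values in [0, 0.5) (unexpressed at the 0.5 threshold);
    the rest receive values in [1, 10].
    """
    if not 0 <= fraction_unexpressed <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction_unexpressed}")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    n_low = round(fraction_unexpressed * len(nodes))
    low = set(rng.choice(nodes, size=n_low, replace=False)) if n_low else set()
    calls = {}
    for node in nodes:
        if node in low:
            calls[node] = float(rng.uniform(0.0, 0.49))
        else:
            calls[node] = float(rng.uniform(1.0, 10.0))
    return ExpressionTable(calls=calls, mode="numeric", label=f"synthetic-seed{seed}")
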