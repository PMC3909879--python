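"""Graph data model and summary statistics.

Graphs are undirected, simple (no self-loops, no parallel edges), over
opaque string node identifiers, represented as :class:`networkx.Graph`.
Directed or duplicated input records are symmetrized/collapsed at build
time; isolated nodes and multiple connected components are allowed —
curated pathways are frequently not a single connected component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import networkx as nx

log = logging.getLogger(__name__)


class EmptyGraphError(ValueError):
    """Raised when an operation requires a nonempty graph."""


@dataclass(frozen=True)
class GraphStats:
    """Summary statistics of a graph.

    ``avg_degree`` is the edges-per-node ratio |E|/|V| — the convention
    used when reporting pathway statistics here (a sparse pathway with
    235 nodes and 249 edges has avg_degree 1.06).  The conventional mean
    degree 2|E|/|V| is exposed separately as ``mean_degree``.
    ``density`` is the fraction of possible edges, undefined (``None``)
    for graphs with fewer than two nodes.
    """

    n_nodes: int
    n_edges: int
    avg_degree: float
    mean_degree: float
    density: Optional[float]
    n_components: int

    def rounded(self, ndigits: int = 2) -> "GraphStats":
        """Report-parity copy with ratios rounded half-up to `ndigits`."""
        return GraphStats(
            n_nodes=self.n_nodes,
            n_edges=self.n_edges,
            avg_degree=round_half_up(self.avg_degree, ndigits),
            mean_degree=round_half_up(self.mean_degree, ndigits),
            density=(
                None if self.density is None else round_half_up(self.density, ndigits)
            ),
            n_components=self.n_components,
        )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (0.665 -> 0.67), not banker's."""
    factor = 10**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def build_graph(
    edge_pairs: Iterable[Tuple[str, str]],
    extra_nodes: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Build an undirected simple graph from node-id pairs.

    Self-loops are dropped, duplicate and reversed-duplicate records are
    collapsed to a single undirected edge, and ``extra_nodes`` are added
    as isolated nodes.  Counts of dropped records are logged.

    Raises
    ------
    EmptyGraphError
        If no nodes remain after cleaning.
    ValueError
        If a node identifier is empty or not a string.
    """
    g = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    for u, v in edge_pairs:
        _check_node_id(u)
        _check_node_id(v)
        if u == v:
            n_self_loops += 1
            continue
        if g.has_edge(u, v):
            n_duplicates += 1
            continue
        g.add_edge(u, v)
    for node in extra_nodes or ():
        _check_node_id(node)
        g.add_node(node)
    if n_self_loops:
        log.info("dropped %d self-loop record(s)", n_self_loops)
    if n_duplicates:
        log.info("collapsed %d duplicate edge record(s)", n_duplicates)
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("no nodes remain after cleaning the input records")
    return g


def _check_node_id(node: object) -> None:
    if not isinstance(node, str) or not node:
        raise ValueError(f"node identifiers must be non-empty strings, got {node!r}")


def graph_stats(g: nx.Graph) -> GraphStats:
    """Node/edge counts, |E|/|V| average degree, density, components.

    Density is ``None`` for a single-node graph, where the fraction of
    possible edges is undefined.
    """
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        raise EmptyGraphError("graph statistics require a nonempty graph")
    if n < 2:
        density = None
        log.warning("density undefined for a graph with fewer than 2 nodes")
    else:
        density = m / (n * (n - 1) / 2)
    return GraphStats(
        n_nodes=n,
        n_edges=m,
        avg_degree=m / n,
        mean_degree=2 * m / n,
        density=density,
        n_components=nx.number_connected_components(g),
    )


def h_neighborhood(g: nx.Graph, center: str, h: int) -> nx.Graph:
    """Induced subgraph on all nodes within `h` edges of `center`.

    The center is included, so the result is connected: every retained
    node reaches the center inside the retained ball.
    """
    if center not in g:
        raise KeyError(f"node {center!r} not in graph")
    if h < 1:
        raise ValueError(f"h must be a positive integer, got {h}")
    return nx.ego_graph(g, center, radius=h).copy()


def induced_subgraph(g: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Induced subgraph on ``g.nodes ∩ keep``; absent ids are ignored."""
    keep = set(keep)
    present = keep & set(g.nodes)
    absent = len(keep) - len(present)
    if absent:
        log.info("ignored %d identifier(s) absent from the graph", absent)
    return g.subgraph(present).copy()


def connected_components(g: nx.Graph) -> Sequence[frozenset]:
    """Partition of the node set into connected components."""
    return [frozenset(c) for c in nx.connected_components(g)]
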