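"""Node and edge importance measures.

Four node measures and one edge measure:

* degree centrality  c_d(i) = number of edges incident to i;
* node betweenness   c_b(k) = Σ_{i<j} g_ikj / g_ij, summing over
  unordered pairs the fraction of shortest i–j paths through k;
* edge betweenness   e_b(e) = Σ_{i<j} g_iej / g_ij, the edge analogue
  (the endpoint pair of an edge counts: the edge is its own shortest
  path);
* eigenvector centrality, the dominant eigenvector of the adjacency
  matrix, non-negative and of unit Euclidean length;
* spectral gap centrality  c_s^h(i) = λ2(L of the h-neighborhood of i)
  / log2(d_i) for d_i > 1, +inf otherwise, where L is the symmetric
  normalized Laplacian and λ2 its second-smallest eigenvalue (the
  spectral gap).  Lower values mark more critical nodes; all other
  measures are higher-is-critical.

Betweenness is unnormalized and computed on unweighted shortest paths;
pairs in different components contribute nothing (0/0 := 0).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import networkx as nx
import numpy as np

from netintegrity.graph import EmptyGraphError, h_neighborhood

log = logging.getLogger(__name__)

HIGHER_IS_CRITICAL = "higher_is_critical"
LOWER_IS_CRITICAL = "lower_is_critical"

#: eigenvalues closer to 0 than this are treated as exactly 0 when
#: detecting disconnection / degenerate dominant eigenspaces
ZERO_TOL = 1e-12

Edge = Tuple[str, str]


@dataclass(frozen=True)
class CentralityResult:
    """One node measure's value for every node of a graph."""

    measure: str
    values: Mapping[str, float]
    orientation: str = HIGHER_IS_CRITICAL
    params: Mapping[str, object] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["node\tvalue"]
        for node in sorted(self.values):
            v = self.values[node]
            lines.append(f"{node}\t{'inf' if math.isinf(v) else repr(v)}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "measure": self.measure,
                "orientation": self.orientation,
                "params": dict(self.params),
                "values": {
                    k: ("inf" if math.isinf(v) else v) for k, v in self.values.items()
                },
            },
            indent=2,
            sort_keys=True,
        )


@dataclass(frozen=True)
class EdgeCentralityResult:
    """Edge betweenness for every edge; keys are lexicographic pairs."""

    values: Mapping[Edge, float]
    measure: str = "edge_betweenness"

    def to_tsv(self) -> str:
        lines = ["source\ttarget\tvalue"]
        for (u, v), val in sorted(self.values.items()):
            lines.append(f"{u}\t{v}\t{val!r}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SpectralSummary:
    """Normalized-Laplacian spectrum, sorted ascending.

    ``spectral_gap`` is λ2, the second-smallest eigenvalue; ``None``
    when the graph has fewer than two nodes.  All eigenvalues lie in
    [0, 2]; one eigenvalue is 0 per connected component, so λ2 = 0
    exactly when the graph is disconnected.
    """

    eigenvalues: np.ndarray
    spectral_gap: Optional[float]


def degree_centrality(g: nx.Graph) -> CentralityResult:
    """c_d(i): count of edges incident to node i."""
    return CentralityResult(measure="degree", values={n: float(d) for n, d in g.degree()})


def node_betweenness(g: nx.Graph) -> CentralityResult:
    """Unnormalized shortest-path betweenness over unordered pairs."""
    values = nx.betweenness_centrality(g, normalized=False)
    return CentralityResult(measure="node_betweenness", values=dict(values))


def edge_betweenness(g: nx.Graph) -> EdgeCentralityResult:
    """Unnormalized edge betweenness; endpoint pairs are included."""
    raw = nx.edge_betweenness_centrality(g, normalized=False)
    return EdgeCentralityResult(
        values={_as_edge(u, v): val for (u, v), val in raw.items()}
    )


def _as_edge(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


def eigenvector_centrality(g: nx.Graph) -> CentralityResult:
    """Dominant adjacency eigenvector, non-negative, unit L2 norm.

    Computed by direct symmetric eigendecomposition.  On disconnected
    graphs whose dominant eigenvalue is (near-)degenerate across
    components, the decomposition's vector is reported with
    non-negative orientation and a warning is logged.

    Raises
    ------
    EmptyGraphError
        If the graph has no edges (the dominant eigenvalue is 0 and
        the measure is undefined).
    """
    if g.number_of_edges() == 0:
        raise EmptyGraphError("eigenvector centrality undefined for an edgeless graph")
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    eigvals, eigvecs = np.linalg.eigh(a)
    if len(eigvals) > 1 and eigvals[-1] - eigvals[-2] < 1e-10:
        log.warning(
            "dominant adjacency eigenvalue is (near-)degenerate "
            "(λ_max=%.6g, next=%.6g); eigenvector centrality is not unique",
            eigvals[-1],
            eigvals[-2],
        )
    vec = eigvecs[:, -1]
    # orient non-negative: flip so the largest-magnitude entry is positive
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    vec = vec / np.linalg.norm(vec)
    return CentralityResult(
        measure="eigenvector", values=dict(zip(nodes, vec.tolist()))
    )


def normalized_laplacian_matrix(g: nx.Graph) -> np.ndarray:
    """Symmetric normalized Laplacian, Chung's convention.

    L_ii = 1 for d_i >= 1 and 0 for isolated nodes;
    L_ij = -1/sqrt(d_i d_j) for edges; 0 otherwise.
    Nodes are ordered by sorted identifier.
    """
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    deg = dict(g.degree())
    n = len(nodes)
    lap = np.zeros((n, n))
    for node in nodes:
        if deg[node] >= 1:
            lap[index[node], index[node]] = 1.0
    for u, v in g.edges():
        w = -1.0 / math.sqrt(deg[u] * deg[v])
        lap[index[u], index[v]] = w
        lap[index[v], index[u]] = w
    return lap


def normalized_laplacian_spectrum(g: nx.Graph) -> SpectralSummary:
    """Eigenvalues of the normalized Laplacian, ascending; λ2 as gap."""
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("spectrum of an empty graph is undefined")
    eigvals = np.sort(np.linalg.eigvalsh(normalized_laplacian_matrix(g)))
    gap = float(eigvals[1]) if len(eigvals) >= 2 else None
    return SpectralSummary(eigenvalues=eigvals, spectral_gap=gap)


def spectral_gap_centrality(g: nx.Graph, h: int = 2) -> CentralityResult:
    """c_s^h(i) = λ2(h-neighborhood of i) / log2(d_i); lower = critical.

    ``d_i`` is the degree in the full graph.  Nodes with degree 0 or 1
    map to +inf: log2(1) = 0 would divide by zero, and a leaf or
    isolated node is never structurally critical by this measure.  For
    d_i >= 2 the h-ball contains the node and at least two neighbors
    and is connected, so λ2 is well defined.
    """
    if h < 1:
        raise ValueError(f"h must be a positive integer, got {h}")
    values: Dict[str, float] = {}
    for node in g.nodes:
        d = g.degree(node)
        if d <= 1:
            values[node] = math.inf
            continue
        ball = h_neighborhood(g, node, h)
        lam2 = normalized_laplacian_spectrum(ball).spectral_gap
        values[node] = lam2 / math.log2(d)
    return CentralityResult(
        measure="spectral_gap",
        values=values,
        orientation=LOWER_IS_CRITICAL,
        params={"h": h},
    )
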