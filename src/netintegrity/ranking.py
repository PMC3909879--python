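"""Ranking schemes and rank-comparison statistics.

Two schemes turn centrality values into a criticality order
(rank 1 = most critical):

* ``by_value`` — sort once by the measure's values, orientation-aware,
  with competition ranks (1, 2, 2, 4) for ties;
* ``by_removal`` — repeatedly recompute the measure on the shrinking
  graph, delete the single most-critical item, and record the order of
  deletion.  Removal re-ranking surfaces redundant parallel cascades:
  once the top node of one cascade is gone, the next iteration's top
  item tends to lie on a different cascade.

Rankings are compared with Spearman's rank correlation (average ranks
for ties), and collections of rankings across conditions (cell lines,
tissues) assemble into a heatmap-ready rank matrix with ranks beyond a
cap collapsed into a single ">cap" bucket.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from netintegrity.centrality import (
    HIGHER_IS_CRITICAL,
    LOWER_IS_CRITICAL,
    CentralityResult,
    EdgeCentralityResult,
    degree_centrality,
    edge_betweenness,
    eigenvector_centrality,
    node_betweenness,
    spectral_gap_centrality,
)
from netintegrity.graph import EmptyGraphError

log = logging.getLogger(__name__)

Item = Hashable  # node id (str) or edge (tuple of two str)

NODE_MEASURES = ("degree", "node_betweenness", "eigenvector", "spectral_gap")


@dataclass(frozen=True)
class Ranking:
    """A criticality order over nodes or edges.

    ``items`` lists items most-critical first; ``ranks`` maps each item
    to its positive integer rank.  Removal rankings are strict
    permutations (ranks 1..K, no ties); value rankings use competition
    ranks, so tied items share the minimum rank of their group while
    ``items`` breaks the tie lexicographically for reproducibility.
    """

    items: Sequence[Item]
    ranks: Mapping[Item, int]
    scheme: str  # "by_value" | "by_removal"
    measure: str
    params: Mapping[str, object] = field(default_factory=dict)

    def average_ranks(self) -> Dict[Item, float]:
        """Ranks with ties averaged (1, 2.5, 2.5, 4) — Spearman input."""
        groups: Dict[int, List[Item]] = {}
        for item, r in self.ranks.items():
            groups.setdefault(r, []).append(item)
        avg: Dict[Item, float] = {}
        for r, members in groups.items():
            a = r + (len(members) - 1) / 2
            for item in members:
                avg[item] = a
        return avg

    def to_tsv(self) -> str:
        lines = ["item\trank"]
        for item in self.items:
            label = "\t".join(item) if isinstance(item, tuple) else item
            lines.append(f"{label}\t{self.ranks[item]}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RankCorrelation:
    """Spearman's rho between two rankings and the overlap size."""

    rho: float
    n_common: int


def rank_by_value(
    c: Union[CentralityResult, EdgeCentralityResult],
) -> Ranking:
    """Rank items by their centrality values, most critical first.

    Orientation-aware: descending for higher-is-critical measures,
    ascending (with +inf last) for spectral gap.  Ties share a
    competition rank; tied items are ordered lexicographically.
    """
    if isinstance(c, EdgeCentralityResult):
        orientation = HIGHER_IS_CRITICAL
        measure, params = c.measure, {}
    else:
        orientation = c.orientation
        measure, params = c.measure, dict(c.params)
    sign = -1.0 if orientation == HIGHER_IS_CRITICAL else 1.0
    items = sorted(c.values, key=lambda it: (sign * c.values[it], it))
    ranks: Dict[Item, int] = {}
    prev_value: Optional[float] = None
    prev_rank = 0
    for pos, item in enumerate(items, start=1):
        v = c.values[item]
        if prev_value is not None and v == prev_value:
            ranks[item] = prev_rank
        else:
            ranks[item] = prev_rank = pos
            prev_value = v
    return Ranking(
        items=items, ranks=ranks, scheme="by_value", measure=measure, params=params
    )


_MEASURE_FNS = {
    "degree": lambda g, h: degree_centrality(g),
    "node_betweenness": lambda g, h: node_betweenness(g),
    "betweenness": lambda g, h: node_betweenness(g),
    "eigenvector": lambda g, h: eigenvector_centrality(g),
    "spectral_gap": lambda g, h: spectral_gap_centrality(g, h=h),
}


def rank_by_removal(g: nx.Graph, measure: str, h: int = 2) -> Ranking:
    """Rank nodes by iterative removal.

    Each iteration recomputes the measure on the current graph, deletes
    the single most-critical node together with its incident edges, and
    assigns it the next rank.  Ties break by higher current degree,
    then lexicographically.  When every remaining node is uninformative
    (value 0, or +inf for spectral gap, or the graph has no edges left
    under eigenvector centrality), the remainder is ordered by degree
    descending then lexicographically and given consecutive ranks.
    """
    if measure not in _MEASURE_FNS:
        raise ValueError(f"unknown node measure {measure!r}; expected one of {NODE_MEASURES}")
    fn = _MEASURE_FNS[measure]
    work = g.copy()
    order: List[str] = []
    while work.number_of_nodes():
        try:
            result = fn(work, h)
        except EmptyGraphError:  # eigenvector on an edgeless remainder
            result = None
        best = None if result is None else _most_critical(work, result)
        if best is None:
            rest = sorted(work.nodes, key=lambda n: (-work.degree(n), n))
            log.debug("remaining %d node(s) uninformative; ordered by degree", len(rest))
            order.extend(rest)
            break
        order.append(best)
        work.remove_node(best)
    return Ranking(
        items=order,
        ranks={node: r for r, node in enumerate(order, start=1)},
        scheme="by_removal",
        measure=measure,
        params={"h": h} if measure == "spectral_gap" else {},
    )


#: relative slack for detecting tied criticality values during removal;
#: shortest-path fractions accumulated in floating point can differ by
#: ~1e-15 between symmetry-equivalent items, which must not defeat the
#: documented degree/lexicographic tie-break
_TIE_RTOL = 1e-9


def _most_critical(g: nx.Graph, result: CentralityResult) -> Optional[str]:
    """Single most-critical node, or None if all values uninformative."""
    values = result.values
    if result.orientation == LOWER_IS_CRITICAL:
        finite = [n for n in values if math.isfinite(values[n])]
        if not finite:
            return None
        best = min(values[n] for n in finite)
        slack = _TIE_RTOL * max(1.0, abs(best))
        tied = [n for n in finite if values[n] <= best + slack]
    else:
        if all(v == 0 for v in values.values()):
            return None
        best = max(values.values())
        slack = _TIE_RTOL * max(1.0, abs(best))
        tied = [n for n in values if values[n] >= best - slack]
    if len(tied) > 1:
        log.debug("tie among %d node(s) at value %.6g", len(tied), best)
    return min(tied, key=lambda n: (-g.degree(n), n))


def rank_edges_by_removal(g: nx.Graph) -> Ranking:
    """Rank edges by iterative removal under edge betweenness.

    Each iteration recomputes edge betweenness, deletes the single
    top-value edge (ties break lexicographically on the ordered
    endpoint pair), and assigns it the next rank.  Nodes are never
    removed.  An edgeless graph yields an empty ranking.
    """
    work = g.copy()
    order: List[Item] = []
    while work.number_of_edges():
        eb = edge_betweenness(work).values
        top = max(eb.values())
        slack = _TIE_RTOL * max(1.0, abs(top))
        best = min(e for e, v in eb.items() if v >= top - slack)
        order.append(best)
        work.remove_edge(*best)
    return Ranking(
        items=order,
        ranks={e: r for r, e in enumerate(order, start=1)},
        scheme="by_removal",
        measure="edge_betweenness",
    )


def spearman_rho(
    r1: Ranking, r2: Ranking, items: Optional[Iterable[Item]] = None
) -> RankCorrelation:
    """Spearman correlation between two rankings.

    Restricted to items ranked in both (or to the explicit ``items``
    subset); average ranks are used for ties.  Requires at least three
    common items for the coefficient to be meaningful.
    """
    common = set(r1.ranks) & set(r2.ranks)
    if items is not None:
        common &= set(items)
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 common items for a rank correlation, got {len(common)}"
        )
    ordered = sorted(common)
    a1 = r1.average_ranks()
    a2 = r2.average_ranks()
    rho = stats.spearmanr([a1[i] for i in ordered], [a2[i] for i in ordered]).statistic
    return RankCorrelation(rho=float(rho), n_common=len(ordered))


@dataclass(frozen=True)
class RankMatrix:
    """Conditions × items matrix of capped ranks.

    Entries are positive integer ranks, the string ``">cap"`` for ranks
    beyond the cap, or NaN for items absent from a condition's graph.
    """

    frame: pd.DataFrame
    cap: int

    def to_tsv(self) -> str:
        return self.frame.to_csv(sep="\t", na_rep="NA")

    def to_numeric(self) -> pd.DataFrame:
        """Numeric view for plotting: the ">cap" bucket becomes cap+1."""
        def conv(x):
            if isinstance(x, str):
                return self.cap + 1
            return x
        return self.frame.map(conv).astype(float)

    def plot_heatmap(self, path: str) -> None:
        """Capped-rank heatmap: rank 1 dark red through cap blue, the
        >cap bucket darkest blue, absences white."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib import colormaps

        num = self.to_numeric()
        cmap = colormaps["RdYlBu"].copy()
        cmap.set_bad("white")
        fig, ax = plt.subplots(
            figsize=(max(4, 0.3 * num.shape[1]), max(2, 0.3 * num.shape[0]))
        )
        im = ax.imshow(
            np.ma.masked_invalid(num.to_numpy()),
            cmap=cmap,
            vmin=1,
            vmax=self.cap + 1,
            aspect="auto",
        )
        ax.set_xticks(range(num.shape[1]), num.columns, rotation=90, fontsize=6)
        ax.set_yticks(range(num.shape[0]), num.index, fontsize=6)
        cbar = fig.colorbar(im, ax=ax)
        cbar.set_label(f"rank (capped at >{self.cap})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def build_rank_matrix(rankings: Mapping[str, Ranking], cap: int) -> RankMatrix:
    """Assemble per-condition rankings into a capped rank matrix.

    Rows are conditions, columns the union of ranked items; ranks above
    ``cap`` collapse to the ">cap" bucket; items missing from a
    condition stay NaN (absent, not merely low-ranked).
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    all_items = sorted({i for r in rankings.values() for i in r.ranks},
                       key=lambda it: (it,) if not isinstance(it, tuple) else it)
    labels = ["--".join(i) if isinstance(i, tuple) else i for i in all_items]
    bucket = f">{cap}"
    frame = pd.DataFrame(index=list(rankings), columns=labels, dtype=object)
    for cond, ranking in rankings.items():
        for item, label in zip(all_items, labels):
            if item in ranking.ranks:
                r = ranking.ranks[item]
                frame.loc[cond, label] = r if r <= cap else bucket
    return RankMatrix(frame=frame, cap=cap)
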