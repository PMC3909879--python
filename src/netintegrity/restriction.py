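"""Expression-conditioned pathway restriction and PPI subnetwork induction.

A canonical pathway is specialized to a tissue or cell line by deleting
nodes whose genes are not expressed there, along with their incident
edges.  Expression comes either as precomputed binary calls (e.g., from
a microarray barcode analysis) or as numeric RPKM-like levels that are
thresholded: a gene with value strictly below the threshold is
unexpressed, so a gene exactly at the threshold counts as expressed.
The conventional conservative threshold is 0.5 RPKM; 3.0 serves as a
more aggressive preset removing roughly half the genes of a typical
pathway.

A PPI subnetwork of a pathway is the subgraph of the full
protein-protein interaction network induced on the intersection of the
pathway's gene set with the PPI node set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Set

import networkx as nx

from netintegrity.graph import induced_subgraph

log = logging.getLogger(__name__)

#: conventional conservative RPKM cutoff for calling a gene expressed
DEFAULT_RPKM_THRESHOLD = 0.5
#: aggressive preset, removes ~40-60% of a typical pathway's genes
AGGRESSIVE_RPKM_THRESHOLD = 3.0

EXPRESSED = "expressed"
UNEXPRESSED = "unexpressed"


class NoOverlapError(ValueError):
    """Pathway gene set and PPI network share no genes."""


@dataclass(frozen=True)
class ExpressionTable:
    """Per-gene expression for one condition (cell line or tissue).

    ``mode`` is ``"numeric"`` (RPKM-like levels >= 0) or ``"binary"``
    (precomputed expressed/unexpressed calls, stored as the strings
    "expressed"/"unexpressed").
    """

    calls: Mapping[str, object]
    mode: str
    label: str = ""

    def __post_init__(self):
        if self.mode not in ("numeric", "binary"):
            raise ValueError(f"mode must be 'numeric' or 'binary', got {self.mode!r}")
        for gene, value in self.calls.items():
            if not isinstance(gene, str) or not gene:
                raise ValueError(f"gene ids must be non-empty strings, got {gene!r}")
            if self.mode == "numeric":
                if not isinstance(value, (int, float)) or value < 0:
                    raise ValueError(
                        f"numeric expression must be >= 0, got {gene}={value!r}"
                    )
            elif value not in (EXPRESSED, UNEXPRESSED):
                raise ValueError(
                    f"binary calls must be 'expressed'/'unexpressed', got {gene}={value!r}"
                )


def call_expressed(
    t: ExpressionTable, threshold: float = DEFAULT_RPKM_THRESHOLD
) -> Set[str]:
    """Genes with expression >= threshold (strict < means unexpressed)."""
    if t.mode != "numeric":
        raise ValueError("call_expressed requires a numeric-mode table")
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return {g for g, v in t.calls.items() if v >= threshold}


def restrict_pathway(
    g: nx.Graph,
    t: ExpressionTable,
    threshold: Optional[float] = None,
    unmeasured_policy: str = "keep",
) -> nx.Graph:
    """Delete unexpressed genes (and incident edges) from a pathway.

    Numeric tables need a ``threshold``; binary tables use their calls
    directly.  Pathway nodes absent from the table follow
    ``unmeasured_policy``: ``"keep"`` (default — absence of evidence)
    retains them, ``"drop"`` removes them.  Returns the induced
    subgraph on the surviving nodes and logs a removal report.
    """
    if unmeasured_policy not in ("keep", "drop"):
        raise ValueError(f"unmeasured_policy must be 'keep' or 'drop', got {unmeasured_policy!r}")
    if t.mode == "numeric":
        if threshold is None:
            raise ValueError("a threshold is required with a numeric expression table")
        expressed = call_expressed(t, threshold)
    else:
        if threshold is not None:
            raise ValueError("threshold is meaningless for a binary expression table")
        expressed = {g_ for g_, c in t.calls.items() if c == EXPRESSED}
    measured = set(t.calls)
    nodes = set(g.nodes)
    unmeasured = nodes - measured
    keep = nodes & expressed
    if unmeasured_policy == "keep":
        keep |= unmeasured
    removed = len(nodes) - len(keep)
    log.info(
        "pathway restriction (%s): removed %d, kept %d, unmeasured %d (%s)",
        t.label or "unlabeled condition",
        removed,
        len(keep),
        len(unmeasured),
        unmeasured_policy,
    )
    return induced_subgraph(g, keep)


def ppi_subnetwork(ppi: nx.Graph, pathway_genes: Iterable[str]) -> nx.Graph:
    """Subgraph of the PPI network induced on a pathway's genes.

    Raises :class:`NoOverlapError` if no pathway gene occurs in the PPI
    network.
    """
    genes = set(pathway_genes)
    intersection = genes & set(ppi.nodes)
    if not intersection:
        raise NoOverlapError("no pathway gene is present in the PPI network")
    log.info(
        "PPI subnetwork: %d of %d pathway genes present in the PPI network "
        "(%d absent)",
        len(intersection),
        len(genes),
        len(genes) - len(intersection),
    )
    return induced_subgraph(ppi, intersection)
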