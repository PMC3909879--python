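"""Readers and writers for graph and expression files.

Supported graph formats, chosen by file extension:

* ``.sif`` — Simple Interaction Format: ``source relation target [target2 ...]``
  per line (whitespace-delimited); the relation is ignored on read; a
  line with a single token declares an isolated node; '#' comments and
  blank lines are skipped.
* ``.tsv`` / ``.txt`` / ``.edges`` — two-column tab-separated edge
  list; a one-column line declares an isolated node.
* ``.graphml`` — undirected GraphML, via networkx.

Expression tables are TSV with a header: either ``gene_id<TAB>value``
(numeric) or ``gene_id<TAB>call`` with calls in {0, 1, expressed,
unexpressed}; wide multi-condition tables are accepted with a condition
column selector.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

import networkx as nx
import pandas as pd

from netintegrity.graph import build_graph
from netintegrity.restriction import EXPRESSED, UNEXPRESSED, ExpressionTable

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_graph(path: PathLike) -> nx.Graph:
    """Read a graph, dispatching on file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".sif":
        return read_sif(path)
    if suffix == ".graphml":
        return read_graphml(path)
    return read_edge_tsv(path)


def write_graph(g: nx.Graph, path: PathLike) -> None:
    """Write a graph, dispatching on file extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".sif":
        write_sif(g, path)
    elif suffix == ".graphml":
        write_graphml(g, path)
    else:
        write_edge_tsv(g, path)


def _tokenized_lines(path: Path) -> Iterable[List[str]]:
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield line.split()


def read_sif(path: PathLike) -> nx.Graph:
    """Read a SIF file; multi-target lines fan out from the source."""
    edges: List[Tuple[str, str]] = []
    singletons: List[str] = []
    for tokens in _tokenized_lines(Path(path)):
        if len(tokens) == 1:
            singletons.append(tokens[0])
        elif len(tokens) >= 3:
            source = tokens[0]
            edges.extend((source, target) for target in tokens[2:])
        else:
            raise ValueError(
                f"malformed SIF line (need 1 or >=3 tokens): {' '.join(tokens)!r}"
            )
    return build_graph(edges, extra_nodes=singletons)


def write_sif(g: nx.Graph, path: PathLike, relation: str = "pp") -> None:
    lines = [f"{u}\t{relation}\t{v}" for u, v in sorted(map(sorted, g.edges()))]
    lines += sorted(n for n in g.nodes if g.degree(n) == 0)
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_tsv(path: PathLike) -> nx.Graph:
    """Two-column TSV edge list; one-column lines are isolated nodes."""
    edges: List[Tuple[str, str]] = []
    singletons: List[str] = []
    for tokens in _tokenized_lines(Path(path)):
        if len(tokens) == 1:
            singletons.append(tokens[0])
        elif len(tokens) == 2:
            edges.append((tokens[0], tokens[1]))
        else:
            raise ValueError(f"expected 1 or 2 columns, got {len(tokens)}: {tokens!r}")
    return build_graph(edges, extra_nodes=singletons)


def write_edge_tsv(g: nx.Graph, path: PathLike) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(map(sorted, g.edges()))]
    lines += sorted(n for n in g.nodes if g.degree(n) == 0)
    Path(path).write_text("\n".join(lines) + "\n")


def read_node_list(path: PathLike) -> List[str]:
    """One node identifier per line; '#' comments skipped."""
    return [tokens[0] for tokens in _tokenized_lines(Path(path))]


def read_graphml(path: PathLike) -> nx.Graph:
    g = nx.read_graphml(Path(path))
    return build_graph([(str(u), str(v)) for u, v in g.edges()],
                       extra_nodes=[str(n) for n in g.nodes()])


def write_graphml(g: nx.Graph, path: PathLike) -> None:
    nx.write_graphml(g, Path(path))


_BINARY_CALLS = {
    "0": UNEXPRESSED,
    "1": EXPRESSED,
    "expressed": EXPRESSED,
    "unexpressed": UNEXPRESSED,
}


def read_expression_tsv(
    path: PathLike, condition: Optional[str] = None
) -> ExpressionTable:
    """Read an expression table.

    Two-column tables need no ``condition``; wide tables (gene column
    plus one column per condition) require one.  Mode (numeric vs
    binary) is inferred from the values: a column consisting solely of
    {0, 1, expressed, unexpressed} is binary.
    """
    frame = pd.read_csv(Path(path), sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("expression table needs a gene column and >= 1 value column")
    gene_col = frame.columns[0]
    if condition is None:
        if frame.shape[1] > 2:
            raise ValueError(
                f"multi-condition table; choose one of {list(frame.columns[1:])}"
            )
        value_col = frame.columns[1]
    else:
        if condition not in frame.columns[1:]:
            raise ValueError(
                f"condition {condition!r} not found; available: {list(frame.columns[1:])}"
            )
        value_col = condition
    genes = frame[gene_col].astype(str)
    raw = frame[value_col].astype(str).str.strip()
    if raw.str.lower().isin(_BINARY_CALLS).all():
        calls = {g: _BINARY_CALLS[v.lower()] for g, v in zip(genes, raw)}
        return ExpressionTable(calls=calls, mode="binary", label=value_col)
    calls = {g: float(v) for g, v in zip(genes, raw)}
    return ExpressionTable(calls=calls, mode="numeric", label=value_col)


def write_expression_tsv(t: ExpressionTable, path: PathLike) -> None:
    header = "gene_id\t" + (t.label or "value")
    lines = [header] + [f"{g}\t{t.calls[g]}" for g in sorted(t.calls)]
    Path(path).write_text("\n".join(lines) + "\n")
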