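"""File formats: edge-list TSV, GraphML, adjacency CSV, data matrices.

Edge lists are tab-separated with a required ``from<TAB>to`` header and an
optional third ``weight`` column.  Adjacency CSVs are square labelled
matrices where a nonzero entry (k, j) encodes the edge k -> j.  GraphML
goes through networkx and must contain directed edges only.  All writers
emit label-sorted rows so output is byte-stable across runs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Union

import networkx as nx
import numpy as np
import pandas as pd

from .graph import DirectedGraph, LayerAssignment, NodeOrdering
from .regression import WeightedDAG

__all__ = [
    "read_graph",
    "write_graph",
    "read_matrix",
    "write_matrix",
    "write_ordering",
    "read_ordering",
]

GraphFormat = Literal["edge_tsv", "graphml", "adjacency_csv"]


def _infer_format(path: Path) -> GraphFormat:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "edge_tsv"
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".csv":
        return "adjacency_csv"
    raise ValueError(f"cannot infer graph format from {path.name!r}; pass format explicitly")


def read_graph(path: str | Path, format: GraphFormat | None = None) -> DirectedGraph:
    """Read a directed graph; returns weights too if the file carries them.

    For weighted edge lists the weights are ignored here (use the third
    column downstream if needed); duplicate edges and malformed rows raise
    with the offending line number.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edge_tsv":
        return _read_edge_tsv(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        if not g.is_directed():
            raise ValueError(f"{path.name}: GraphML graph is undirected")
        return DirectedGraph.from_networkx(g)
    if fmt == "adjacency_csv":
        adj = pd.read_csv(path, index_col=0)
        if adj.shape[0] != adj.shape[1] or list(adj.index) != list(adj.columns):
            raise ValueError(f"{path.name}: adjacency matrix must be square and labelled")
        edges = [
            (str(k), str(j))
            for k in adj.index
            for j in adj.columns
            if k != j and adj.loc[k, j] != 0
        ]
        return DirectedGraph([str(v) for v in adj.index], edges)
    raise ValueError(f"unknown format {fmt!r}")


def _read_edge_tsv(path: Path) -> DirectedGraph:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path.name}: empty file (header required)")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0] != "from" or header[1] != "to":
        raise ValueError(f"{path.name}:1: expected header 'from\\tto[\\tweight]'")
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    nodes: list[str] = []
    node_seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line.split("\t")
            if parts[0] == "#node" and len(parts) > 1 and parts[1] not in node_seen:
                node_seen.add(parts[1])
                nodes.append(parts[1])
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path.name}:{lineno}: expected at least 2 tab-separated fields")
        k, j = parts[0], parts[1]
        if (k, j) in seen:
            raise ValueError(f"{path.name}:{lineno}: duplicate edge {k} -> {j}")
        seen.add((k, j))
        edges.append((k, j))
        for v in (k, j):
            if v not in node_seen:
                node_seen.add(v)
                nodes.append(v)
    return DirectedGraph(sorted(nodes), edges)


def write_graph(
    g: Union[DirectedGraph, WeightedDAG], path: str | Path, format: GraphFormat | None = None
) -> None:
    """Write a graph (weight column included for a :class:`WeightedDAG`)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    weights = None
    if isinstance(g, WeightedDAG):
        weights = g.coefficients
        g = g.graph
    if fmt == "edge_tsv":
        lines = ["from\tto\tweight" if weights is not None else "from\tto"]
        connected = {v for e in g.edges for v in e}
        # isolated nodes survive the round trip via comment lines
        for v in sorted(set(g.nodes) - connected):
            lines.append(f"#node\t{v}")
        for k, j in sorted(g.edges):
            if weights is not None:
                lines.append(f"{k}\t{j}\t{weights[(k, j)]!r}")
            else:
                lines.append(f"{k}\t{j}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        nxg = g.to_networkx()
        if weights is not None:
            nx.set_edge_attributes(nxg, {e: w for e, w in weights.items()}, "weight")
        nx.write_graphml(nxg, path)
    elif fmt == "adjacency_csv":
        nodes = sorted(g.nodes)
        adj = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for k, j in sorted(g.edges):
            adj.loc[k, j] = weights[(k, j)] if weights is not None else 1.0
        adj.to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read an n x p data matrix (CSV or TSV, labelled columns, numeric body)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    seen, dups = set(), []
    for label in header:
        if label in seen:
            dups.append(label)
        seen.add(label)
    if dups:
        raise ValueError(f"{path.name}: duplicate column labels {sorted(set(dups))}")
    df = pd.read_csv(path, sep=sep)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric or missing value at row {bad[0] + 2}, column {col!r}"
            )
        df[col] = numeric
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path.name}: non-finite values present")
    return df


def write_matrix(data: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    data.to_csv(path, sep=sep, index=False)


def write_ordering(ordering: NodeOrdering | LayerAssignment, path: str | Path) -> None:
    """JSON: a list of labels (vertex order) or list of label-lists (layers)."""
    if isinstance(ordering, NodeOrdering):
        payload = {"granularity": "vertex", "order": list(ordering.sequence)}
    else:
        payload = {"granularity": "layer", "layers": [list(layer) for layer in ordering.layers]}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_ordering(path: str | Path) -> NodeOrdering | LayerAssignment:
    payload = json.loads(Path(path).read_text())
    if payload.get("granularity") == "vertex":
        return NodeOrdering(payload["order"])
    return LayerAssignment(payload["layers"])
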