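"""Directed-graph data model and topological machinery.

A DAG ``G = (V, E)`` encodes causal structure: an edge ``(k, j)`` means
``k -> j``, i.e. *k* is a parent of *j*.  Two orderings of its vertices
matter for order-based structure learning:

* a **topological (vertex) order** -- a permutation in which every edge
  points forward; generally non-unique;
* the **topological layer decomposition** ``L(G) = (L0, ..., Ld)`` -- the
  unique partition in which ``L0`` is the source set and ``Lj`` collects
  the sources of the subgraph left after removing ``L0 .. L(j-1)``.  Every
  parent of a node in ``Lj`` lies in a strictly earlier layer, so any
  flattening of ``L(G)`` is a valid topological order.

The layer decomposition is computed by iterative leaf removal on the
transposed graph: leaves of the transpose are exactly the sources of the
original graph, so peeling them layer by layer and reading the peeling
order top-down realises the recursive definition above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import networkx as nx

__all__ = [
    "DirectedGraph",
    "NodeOrdering",
    "LayerAssignment",
    "GraphSummary",
    "CyclicGraphError",
    "is_acyclic",
    "transpose",
    "topological_sort",
    "layer_decomposition",
    "graph_to_dag",
    "graph_summary",
]


class CyclicGraphError(ValueError):
    """Raised when an operation requiring a DAG receives a cyclic graph."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__(
            "graph contains a directed cycle: " + " -> ".join(self.cycle + [self.cycle[0]])
        )


@dataclass(frozen=True)
class DirectedGraph:
    """A labelled directed graph with unique nodes and no duplicate edges.

    Parameters
    ----------
    nodes
        Ordered collection of unique string labels (the vertex set V).
    edges
        Iterable of ``(k, j)`` pairs meaning ``k -> j`` (the edge set E).
        Self-loops are rejected here; use :func:`graph_to_dag` to sanitise
        raw prior-knowledge graphs that may carry them.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        nodes = tuple(str(v) for v in nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node labels")
        node_set = set(nodes)
        edge_list = [(str(k), str(j)) for k, j in edges]
        edge_set = frozenset(edge_list)
        if len(edge_set) != len(edge_list):
            raise ValueError("duplicate edges")
        for k, j in edge_set:
            if k not in node_set or j not in node_set:
                raise ValueError(f"edge ({k!r}, {j!r}) has endpoint outside the node set")
            if k == j:
                raise ValueError(f"self-loop on {k!r} not allowed")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edge_set)

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents(self, j: str) -> set[str]:
        """pa(j): in-neighbours of *j*."""
        return {k for k, jj in self.edges if jj == j}

    def children(self, k: str) -> set[str]:
        """sib(k): out-neighbours of *k*."""
        return {j for kk, j in self.edges if kk == k}

    def sources(self) -> list[str]:
        """Nodes with no parents, in label order."""
        targets = {j for _, j in self.edges}
        return sorted(v for v in self.nodes if v not in targets)

    def sinks(self) -> list[str]:
        """Nodes with no children, in label order."""
        origins = {k for k, _ in self.edges}
        return sorted(v for v in self.nodes if v not in origins)

    def subgraph(self, keep: Iterable[str]) -> "DirectedGraph":
        keep_set = set(keep)
        return DirectedGraph(
            [v for v in self.nodes if v in keep_set],
            [(k, j) for k, j in self.edges if k in keep_set and j in keep_set],
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedGraph":
        return cls(sorted(g.nodes), g.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DirectedGraph(p={self.n_nodes}, edges={self.n_edges})"


@dataclass(frozen=True)
class NodeOrdering:
    """A permutation of node labels; position(k) < position(j) means k ≺ j."""

    sequence: tuple[str, ...]
    _pos: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __init__(self, sequence: Iterable[str]):
        seq = tuple(sequence)
        if len(set(seq)) != len(seq):
            raise ValueError("ordering contains repeated labels")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "_pos", {v: i for i, v in enumerate(seq)})

    def position(self, node: str) -> int:
        try:
            return self._pos[node]
        except KeyError:
            raise KeyError(f"node {node!r} not in ordering") from None

    def precedes(self, k: str, j: str) -> bool:
        return self.position(k) < self.position(j)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LayerAssignment:
    """The unique layer partition ``(L0, ..., Ld)`` of a DAG.

    Layers are stored as sorted tuples; ``depth`` is d (number of layers
    minus one).  Parents of any node in ``Lj`` lie in strictly earlier
    layers.
    """

    layers: tuple[tuple[str, ...], ...]

    def __init__(self, layers: Iterable[Iterable[str]]):
        tidy = tuple(tuple(sorted(layer)) for layer in layers)
        if any(not layer for layer in tidy):
            raise ValueError("empty layer")
        flat = [v for layer in tidy for v in layer]
        if len(set(flat)) != len(flat):
            raise ValueError("layers are not disjoint")
        object.__setattr__(self, "layers", tidy)

    @property
    def depth(self) -> int:
        return len(self.layers) - 1

    def layer_of(self, node: str) -> int:
        for i, layer in enumerate(self.layers):
            if node in layer:
                return i
        raise KeyError(f"node {node!r} not in any layer")

    def flatten(self) -> NodeOrdering:
        """Flatten in layer order (labels sorted within each layer)."""
        return NodeOrdering(v for layer in self.layers for v in layer)

    def __iter__(self) -> Iterator[tuple[str, ...]]:
        return iter(self.layers)

    def __len__(self) -> int:
        return len(self.layers)


@dataclass(frozen=True)
class GraphSummary:
    """Descriptive statistics of a directed graph."""

    n_vertices: int
    n_edges: int
    n_sources: int
    n_sinks: int
    mean_degree: float
    mean_betweenness: float


# ---------------------------------------------------------------------------


def is_acyclic(g: DirectedGraph) -> bool:
    """True iff *g* contains no directed cycle."""
    return nx.is_directed_acyclic_graph(g.to_networkx())


def transpose(g: DirectedGraph) -> DirectedGraph:
    """Flip the orientation of every edge."""
    return DirectedGraph(g.nodes, [(j, k) for k, j in g.edges])


def topological_sort(g: DirectedGraph) -> NodeOrdering:
    """Topological vertex order with ties broken by ascending label.

    Raises :class:`CyclicGraphError` (naming one cycle) on cyclic input.
    """
    nxg = g.to_networkx()
    try:
        order = list(nx.lexicographical_topological_sort(nxg))
    except nx.NetworkXUnfeasible:
        cycle = [k for k, _ in nx.find_cycle(nxg)]
        raise CyclicGraphError(cycle) from None
    return NodeOrdering(order)


def layer_decomposition(g: DirectedGraph) -> LayerAssignment:
    """Unique topological layer partition via leaf removal on the transpose.

    At each step the leaves of the transposed graph (equivalently, the
    sources of the current subgraph) are peeled off as one layer; reading
    the peeled layers in order gives ``L0 = sources`` and
    ``Lj = sources of G after removing L0 .. L(j-1)``.
    """
    if not is_acyclic(g):
        cycle = [k for k, _ in nx.find_cycle(g.to_networkx())]
        raise CyclicGraphError(cycle)
    t = transpose(g)
    layers: list[tuple[str, ...]] = []
    while t.n_nodes:
        leaves = t.sinks()  # leaves of the transpose = sources of g
        layers.append(tuple(leaves))
        t = t.subgraph(set(t.nodes) - set(leaves))
    return LayerAssignment(layers)


def graph_to_dag(g: DirectedGraph) -> DirectedGraph:
    """Break cycles deterministically, yielding an acyclic subgraph.

    Self-loops (tolerated only here, as raw edge pairs) are dropped first;
    then a depth-first traversal started from nodes in ascending label
    order deletes every back edge (an edge into a vertex currently on the
    DFS stack) as it is encountered.  An already-acyclic input is returned
    unchanged.

    Accepts either a :class:`DirectedGraph` or a ``(nodes, edges)`` pair so
    that raw prior graphs with self-loops can be sanitised.
    """
    if isinstance(g, tuple):
        nodes, raw_edges = g
        nodes = tuple(str(v) for v in nodes)
        edges = {(str(k), str(j)) for k, j in raw_edges if str(k) != str(j)}
        g = DirectedGraph(nodes, edges)

    WHITE, GRAY, BLACK = 0, 1, 2
    color = {v: WHITE for v in g.nodes}
    adj = {v: sorted(g.children(v)) for v in g.nodes}
    dropped: set[tuple[str, str]] = set()

    def visit(root: str) -> None:
        # iterative DFS; edges into GRAY vertices are back edges
        stack: list[tuple[str, Iterator[str]]] = [(root, iter(adj[root]))]
        color[root] = GRAY
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if color[w] == GRAY:
                    dropped.add((v, w))
                elif color[w] == WHITE:
                    color[w] = GRAY
                    stack.append((w, iter(adj[w])))
                    advanced = True
                    break
            if not advanced:
                color[v] = BLACK
                stack.pop()

    for v in sorted(g.nodes):
        if color[v] == WHITE:
            visit(v)
    if not dropped:
        return g
    return DirectedGraph(g.nodes, g.edges - dropped)


def graph_summary(g: DirectedGraph) -> GraphSummary:
    """Vertex/edge/source/sink counts, mean total degree, mean betweenness.

    Betweenness is directed, unnormalised shortest-path betweenness with
    unit edge weights (how often a node lies strictly inside shortest
    paths between other node pairs).
    """
    nxg = g.to_networkx()
    p = g.n_nodes
    mean_degree = 2.0 * g.n_edges / p if p else 0.0
    if p:
        bc = nx.betweenness_centrality(nxg, normalized=False)
        mean_betweenness = sum(bc.values()) / p
    else:
        mean_betweenness = 0.0
    return GraphSummary(
        n_vertices=p,
        n_edges=g.n_edges,
        n_sources=len(g.sources()),
        n_sinks=len(g.sinks()),
        mean_degree=mean_degree,
        mean_betweenness=mean_betweenness,
    )
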