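"""Graph data model, shortest-path machinery, and neighborhood probability measures.

The central object is :class:`WeightedGraph`, a simple connected undirected
graph with strictly positive edge weights, optional node features (n x d) and
optional edge features (m x q, aligned with a fixed edge ordering).  Node
order is first-appearance order in the input and defines the 0-based index
used in every matrix and tie-break throughout the package.

The neighborhood probability measure ``m_x^alpha`` places mass ``alpha`` on
the center node x and spreads ``1 - alpha`` over its neighbors proportionally
to a transform ``gamma`` of the incident edge weights (identity by default):

    m_x^alpha(y) = alpha                                    if y = x
                 = (1 - alpha) * gamma(w_xy) / sum_z gamma(w_xz)   if y ~ x
                 = 0                                        otherwise

This measure is the ground object of the discrete Ricci curvature computed in
:mod:`curvgt.ricci`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GraphError",
    "WeightedGraph",
    "NodeMeasure",
    "load_graph",
    "parse_edge_list",
    "parse_graph_json",
    "shortest_path_distances",
    "shortest_path_nodes",
    "neighborhood_measure",
    "degree",
]


class GraphError(ValueError):
    """Raised for invalid graph input (self-loop, duplicate edge, disconnected, ...)."""


class WeightedGraph:
    """Simple connected undirected graph with positive edge weights.

    Parameters
    ----------
    node_ids
        Distinct node labels in first-appearance order; position defines the
        node index used everywhere.
    edges
        Iterable of ``(u, v, w)`` with labels ``u != v`` and weight ``w > 0``;
        the iteration order fixes the edge index used to align edge features.
    node_features
        Optional ``(n, d)`` real matrix.
    edge_features
        Optional ``(m, q)`` real matrix aligned with the edge ordering.
    node_labels
        Optional integer class label per node (used by the karate study).
    """

    def __init__(
        self,
        node_ids: Sequence,
        edges: Iterable[tuple],
        node_features: np.ndarray | None = None,
        edge_features: np.ndarray | None = None,
        node_labels: np.ndarray | None = None,
    ):
        self.node_ids = list(node_ids)
        if len(set(map(str, self.node_ids))) != len(self.node_ids):
            raise GraphError("duplicate node ids")
        if len(self.node_ids) < 2:
            raise GraphError("graph needs at least 2 nodes")
        self.index = {u: i for i, u in enumerate(self.node_ids)}
        n = len(self.node_ids)

        self.edges: list[tuple[int, int, float]] = []
        seen: set[tuple[int, int]] = set()
        A = np.zeros((n, n), dtype=np.int8)
        W = np.zeros((n, n), dtype=float)
        for k, (u, v, *rest) in enumerate(edges):
            w = float(rest[0]) if rest else 1.0
            if u not in self.index or v not in self.index:
                raise GraphError(f"edge {k}: unknown node in ({u!r}, {v!r})")
            i, j = self.index[u], self.index[v]
            if i == j:
                raise GraphError(f"edge {k}: self-loop on node {u!r}")
            if w <= 0:
                raise GraphError(f"edge {k}: non-positive weight {w}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise GraphError(f"edge {k}: duplicate edge ({u!r}, {v!r})")
            seen.add(key)
            self.edges.append((i, j, w))
            A[i, j] = A[j, i] = 1
            W[i, j] = W[j, i] = w
        self.adjacency = A
        self.weight_matrix = W
        self._check_connected()

        self.node_features = None if node_features is None else np.asarray(node_features, dtype=float)
        if self.node_features is not None and self.node_features.shape[0] != n:
            raise GraphError("node_features row count != n")
        self.edge_features = None if edge_features is None else np.asarray(edge_features, dtype=float)
        if self.edge_features is not None and self.edge_features.shape[0] != len(self.edges):
            raise GraphError("edge_features row count != m")
        self.node_labels = None if node_labels is None else np.asarray(node_labels)

        # adjacency lists as sorted index arrays (deterministic iteration)
        self._nbrs = [np.flatnonzero(A[i]).astype(int) for i in range(n)]
        self._edge_index = {(min(i, j), max(i, j)): k for k, (i, j, _) in enumerate(self.edges)}
        self._cache: dict = {}

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def m(self) -> int:
        return len(self.edges)

    def neighbors(self, i: int) -> np.ndarray:
        return self._nbrs[i]

    def edge_weight(self, i: int, j: int) -> float:
        w = self.weight_matrix[i, j]
        if w == 0:
            raise GraphError(f"({i}, {j}) is not an edge")
        return float(w)

    def edge_id(self, i: int, j: int) -> int:
        """Index of edge {i, j} in the fixed edge ordering."""
        return self._edge_index[(min(i, j), max(i, j))]

    def _check_connected(self):
        n = len(self.node_ids)
        seen = np.zeros(n, dtype=bool)
        stack = [0]
        seen[0] = True
        adj = self.adjacency
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adj[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        if not seen.all():
            comp_a = [self.node_ids[i] for i in np.flatnonzero(seen)]
            comp_b = [self.node_ids[i] for i in np.flatnonzero(~seen)]
            raise GraphError(
                f"graph is disconnected: component {comp_a} is separate from {comp_b[:5]}..."
                if len(comp_b) > 5
                else f"graph is disconnected: component {comp_a} is separate from {comp_b}"
            )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_weighted_edges_from((i, j, w) for i, j, w in self.edges)
        return g

    def relabel(self, perm: Sequence[int]) -> "WeightedGraph":
        """Return an isomorphic copy where old node i becomes new node perm[i]."""
        perm = list(perm)
        order = np.argsort(perm)  # new index -> old index
        new_ids = [self.node_ids[o] for o in order]
        new_edges = []
        for i, j, w in self.edges:
            new_edges.append((self.node_ids[i], self.node_ids[j], w))
        X = None if self.node_features is None else self.node_features[order]
        y = None if self.node_labels is None else self.node_labels[order]
        return WeightedGraph(new_ids, new_edges, node_features=X,
                             edge_features=self.edge_features, node_labels=y)

    def __repr__(self):
        return f"WeightedGraph(n={self.n}, m={self.m})"


@dataclass
class NodeMeasure:
    """Probability measure ``m_x^alpha`` supported on a node and its neighbors."""

    center: int
    alpha: float
    mass: dict[int, float] = field(default_factory=dict)

    def as_array(self, n: int) -> np.ndarray:
        out = np.zeros(n)
        for i, p in self.mass.items():
            out[i] = p
        return out

    def support(self) -> list[int]:
        return sorted(i for i, p in self.mass.items() if p > 0)


# -- parsing -------------------------------------------------------------

def parse_edge_list(text: str) -> WeightedGraph:
    """Parse edge-list TSV: ``u<TAB>v[<TAB>weight]``, ``#`` comments, blank lines ok."""
    nodes: list = []
    seen: set = set()
    edges = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) not in (2, 3):
            raise GraphError(f"line {lineno}: expected 2 or 3 columns, got {len(parts)}")
        u, v = parts[0], parts[1]
        try:
            w = float(parts[2]) if len(parts) == 3 else 1.0
        except ValueError:
            raise GraphError(f"line {lineno}: bad weight {parts[2]!r}") from None
        for x in (u, v):
            if x not in seen:
                seen.add(x)
                nodes.append(x)
        if u == v:
            raise GraphError(f"line {lineno}: self-loop on node {u!r}")
        if w <= 0:
            raise GraphError(f"line {lineno}: non-positive weight {w}")
        edges.append((u, v, w))
    return WeightedGraph(nodes, edges)


def parse_graph_json(text: str) -> WeightedGraph:
    """Parse the graph-JSON dialect.

    ``{"nodes": [{"id": ..., "features": [...]}, ...],
       "edges": [{"u": ..., "v": ..., "weight": w, "features": [...]}, ...]}``
    with ``weight`` defaulting to 1.0 and both feature keys optional.
    """
    obj = json.loads(text)
    nodes = [nd["id"] for nd in obj["nodes"]]
    feats = [nd.get("features") for nd in obj["nodes"]]
    X = None
    if any(f is not None for f in feats):
        if any(f is None for f in feats):
            raise GraphError("either all or no nodes must carry features")
        X = np.asarray(feats, dtype=float)
    edges = [(e["u"], e["v"], float(e.get("weight", 1.0))) for e in obj["edges"]]
    efeats = [e.get("features") for e in obj["edges"]]
    E = None
    if any(f is not None for f in efeats):
        if any(f is None for f in efeats):
            raise GraphError("either all or no edges must carry features")
        E = np.asarray(efeats, dtype=float)
    labels = [nd.get("label") for nd in obj["nodes"]]
    y = np.asarray(labels) if all(l is not None for l in labels) else None
    return WeightedGraph(nodes, edges, node_features=X, edge_features=E, node_labels=y)


def load_graph(path: str) -> WeightedGraph:
    """Load a graph from an edge-list TSV or graph-JSON file (by extension/content)."""
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if str(path).endswith(".json") or stripped.startswith("{"):
        return parse_graph_json(text)
    return parse_edge_list(text)


# -- shortest paths ------------------------------------------------------

def shortest_path_distances(g: WeightedGraph) -> np.ndarray:
    """All-pairs Dijkstra distance matrix (n x n, symmetric, zero diagonal).

    Edge weights act as lengths; with unit weights this is the hop-count SPD.
    Cached on the graph.
    """
    if "dist" in g._cache:
        return g._cache["dist"]
    nxg = g.to_networkx()
    D = np.zeros((g.n, g.n))
    for src, lengths in nx.all_pairs_dijkstra_path_length(nxg, weight="weight"):
        for dst, d in lengths.items():
            D[src, dst] = d
    D = (D + D.T) / 2.0  # symmetrize away float round-off asymmetry
    g._cache["dist"] = D
    return D


def shortest_path_nodes(g: WeightedGraph, x: int, y: int) -> list[int]:
    """One deterministic shortest path from x to y, as a node-index list.

    Among all shortest paths the lexicographically smallest index sequence is
    returned: from each node the smallest-index neighbor that still lies on
    some shortest path is taken.  Repeated calls give identical output.
    """
    if x == y:
        raise GraphError("shortest_path_nodes requires x != y")
    D = shortest_path_distances(g)
    total = D[x, y]
    path = [x]
    cur = x
    tol = 1e-9 * max(1.0, total)
    while cur != y:
        walked = D[x, cur] if cur != x else 0.0
        for j in g.neighbors(cur):
            if abs(walked + g.weight_matrix[cur, j] + D[j, y] - total) <= tol and abs(
                D[x, j] - (walked + g.weight_matrix[cur, j])
            ) <= tol:
                path.append(int(j))
                cur = int(j)
                break
        else:  # pragma: no cover - impossible on a connected graph
            raise GraphError(f"no tight edge continuing the shortest path at node {cur}")
    return path


# -- neighborhood measure ------------------------------------------------

def neighborhood_measure(
    g: WeightedGraph,
    x: int,
    alpha: float,
    gamma: Callable[[float], float] | None = None,
) -> NodeMeasure:
    """The measure m_x^alpha: mass alpha at x, the rest on N(x) weighted by gamma(w)."""
    if not 0.0 <= alpha <= 1.0:
        raise GraphError(f"alpha must lie in [0, 1], got {alpha}")
    nbrs = g.neighbors(x)
    if gamma is None:
        gw = np.array([g.weight_matrix[x, j] for j in nbrs])
    else:
        gw = np.array([gamma(g.weight_matrix[x, j]) for j in nbrs])
        if (gw < 0).any():
            raise GraphError("gamma produced a negative value")
    denom = gw.sum()
    if denom <= 0:
        raise GraphError("gamma transform gives zero total neighbor weight")
    mass = {int(j): (1.0 - alpha) * float(w) / denom for j, w in zip(nbrs, gw)}
    if alpha > 0:
        mass[x] = mass.get(x, 0.0) + alpha
    return NodeMeasure(center=x, alpha=alpha, mass=mass)


def degree(g: WeightedGraph, v: int) -> int:
    """Unweighted degree: number of neighbors of v."""
    if not 0 <= v < g.n:
        raise GraphError(f"unknown node index {v}")
    return int(len(g.neighbors(v)))
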