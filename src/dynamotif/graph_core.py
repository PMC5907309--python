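"""Undirected simple graphs, edit operations, and distance primitives.

The evolving network is modelled as a plain undirected simple graph whose
topology changes through an ordered sequence of single-edge insertions and
deletions (an :class:`EditScript`).  Node insertions/deletions are expressed
as edge operations: inserting an edge whose endpoint is unknown implicitly
adds that node, and deleting every incident edge of a node leaves it
isolated (isolated nodes cannot host embeddings of connected motifs with at
least one edge, so motif counts are unaffected).

Edges are identified by the unordered node pair, stored in one canonical
orientation (lexicographically smaller endpoint first, comparing the string
form of the labels).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Hashable

Node = Hashable
Edge = tuple  # canonical (u, v) pair


class ScriptConsistencyError(ValueError):
    """An edit operation is inconsistent with the current graph state.

    Raised when a script tries to insert an edge that already exists or
    delete an edge that is absent.  The raw edit-sequence formalism would
    silently toggle the edge instead; rejecting the operation makes
    malformed scripts fail loudly.
    """


def edge_key(u: Node, v: Node) -> Edge:
    """Return the canonical orientation of the unordered pair ``{u, v}``."""
    if u == v:
        raise ValueError(f"self-loop ({u!r}, {v!r}) is not a valid edge")
    try:
        return (u, v) if u <= v else (v, u)
    except TypeError:  # mixed label types: order on the string form
        return (u, v) if str(u) <= str(v) else (v, u)


class Graph:
    """Mutable undirected simple graph with opaque hashable node labels.

    Adjacency is stored as insertion-ordered dicts (values unused), so
    iteration order is a deterministic function of the construction
    history, independent of interpreter hash randomization.  Embedding
    ids, greedy tie-breaks, and file output are therefore reproducible
    across runs.
    """

    __slots__ = ("adj", "_n_edges")

    def __init__(self, edges: Iterable[tuple[Node, Node]] = (), nodes: Iterable[Node] = ()):
        self.adj: dict[Node, dict[Node, None]] = {}
        self._n_edges = 0
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -----------------------------------------------------

    def add_node(self, n: Node) -> None:
        self.adj.setdefault(n, {})

    def add_edge(self, u: Node, v: Node) -> None:
        """Insert edge {u, v}; missing endpoints are added as nodes."""
        if u == v:
            raise ValueError(f"self-loop ({u!r}, {v!r}) rejected")
        if u in self.adj and v in self.adj[u]:
            raise ScriptConsistencyError(f"edge ({u!r}, {v!r}) already present")
        self.adj.setdefault(u, {})[v] = None
        self.adj.setdefault(v, {})[u] = None
        self._n_edges += 1

    def remove_edge(self, u: Node, v: Node) -> None:
        """Delete edge {u, v}; endpoints are retained even if isolated."""
        if u not in self.adj or v not in self.adj[u]:
            raise ScriptConsistencyError(f"edge ({u!r}, {v!r}) not present")
        del self.adj[u][v]
        del self.adj[v][u]
        self._n_edges -= 1

    # -- queries ----------------------------------------------------------

    def has_node(self, n: Node) -> bool:
        return n in self.adj

    def has_edge(self, u: Node, v: Node) -> bool:
        return u in self.adj and v in self.adj[u]

    def degree(self, n: Node) -> int:
        return len(self.adj[n])

    def neighbors(self, n: Node):
        """Neighbors of n (a mapping view: supports ``in``, iteration, len)."""
        return self.adj[n]

    @property
    def n_nodes(self) -> int:
        return len(self.adj)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def nodes(self) -> Iterator[Node]:
        return iter(self.adj)

    def edges(self) -> Iterator[Edge]:
        """Iterate over canonical edges (each unordered pair once)."""
        seen_from: set[Node] = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if v not in seen_from:
                    yield edge_key(u, v)
            seen_from.add(u)

    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.edges())

    def degree_sequence(self) -> dict[Node, int]:
        return {n: len(nbrs) for n, nbrs in self.adj.items()}

    def copy(self) -> "Graph":
        g = Graph()
        g.adj = {n: dict(nbrs) for n, nbrs in self.adj.items()}
        g._n_edges = self._n_edges
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return set(self.adj) == set(other.adj) and self.edge_set() == other.edge_set()

    def __repr__(self) -> str:
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- distances --------------------------------------------------------

    def distance(self, u: Node, v: Node) -> float:
        """Shortest-path length (edge count) between u and v; inf if disconnected."""
        if u not in self.adj or v not in self.adj:
            raise KeyError(f"unknown node in distance query: {u!r} or {v!r}")
        if u == v:
            return 0
        dist = {u: 0}
        queue = deque([u])
        while queue:
            x = queue.popleft()
            d = dist[x] + 1
            for y in self.adj[x]:
                if y not in dist:
                    if y == v:
                        return d
                    dist[y] = d
                    queue.append(y)
        return math.inf

    def _bfs_depths(self, source: Node, limit: int) -> dict[Node, int]:
        """Nodes within ``limit`` hops of ``source``, mapped to their depth."""
        dist = {source: 0}
        queue = deque([source])
        while queue:
            x = queue.popleft()
            d = dist[x]
            if d == limit:
                continue
            for y in self.adj[x]:
                if y not in dist:
                    dist[y] = d + 1
                    queue.append(y)
        return dist

    def k_neighborhood(self, edge: tuple[Node, Node], k: int) -> "Graph":
        """Subgraph of all edges with an endpoint within distance k of the seed edge.

        The seed edge (u, v) must be present.  An edge (x, y) is kept iff
        min(d(x,u), d(x,v), d(y,u), d(y,v)) <= k; the node set is the set of
        endpoints of the kept edges.  The seed edge itself always qualifies
        (its endpoints are at distance 0).
        """
        u, v = edge
        if not self.has_edge(u, v):
            raise ScriptConsistencyError(f"seed edge ({u!r}, {v!r}) not in graph")
        near = self._bfs_depths(u, k)
        for n, d in self._bfs_depths(v, k).items():
            if n not in near or d < near[n]:
                near[n] = d
        sub = Graph()
        for x in near:
            for y in self.adj[x]:
                if not sub.has_edge(x, y):
                    sub.add_edge(x, y)
        return sub


# -- edit operations ------------------------------------------------------

INSERT = "insert"
DELETE = "delete"


@dataclass(frozen=True)
class EditOp:
    """A single edge insertion or deletion on the evolving network."""

    kind: str  # INSERT or DELETE
    u: Node
    v: Node

    def __post_init__(self) -> None:
        if self.kind not in (INSERT, DELETE):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.u == self.v:
            raise ValueError("edit endpoints must be distinct")

    @property
    def edge(self) -> Edge:
        return edge_key(self.u, self.v)

    def inverted(self) -> "EditOp":
        return EditOp(DELETE if self.kind == INSERT else INSERT, self.u, self.v)


class EditScript:
    """Ordered sequence of edge edits defining the trajectory G_0 ... G_T."""

    def __init__(self, ops: Iterable[EditOp] = ()):
        self.ops: list[EditOp] = list(ops)

    def __len__(self) -> int:
        return len(self.ops)

    def __iter__(self) -> Iterator[EditOp]:
        return iter(self.ops)

    def __getitem__(self, i):
        return self.ops[i]

    def append(self, op: EditOp) -> None:
        self.ops.append(op)

    def reversed(self) -> "EditScript":
        """The inverse script: inverted ops in reverse order."""
        return EditScript(op.inverted() for op in reversed(self.ops))

    def apply(self, graph: Graph) -> Graph:
        """Apply every op to ``graph`` in place and return it."""
        for i, op in enumerate(self.ops):
            try:
                apply_edit(graph, op)
            except ScriptConsistencyError as exc:
                raise ScriptConsistencyError(f"op {i}: {exc}") from exc
        return graph


def apply_edit(graph: Graph, op: EditOp) -> Graph:
    """Apply one edit in place; |E_i - E_{i-1}| = 1 afterwards."""
    if op.kind == INSERT:
        graph.add_edge(op.u, op.v)
    else:
        graph.remove_edge(op.u, op.v)
    return graph


# -- plain-text I/O -------------------------------------------------------

def read_edge_list(path) -> Graph:
    """Read an edge-list TSV (two tab-separated labels per line, '#' comments)."""
    g = Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                g.add_edge(parts[0], parts[1])
            except ScriptConsistencyError as exc:
                raise ValueError(f"{path}:{lineno}: duplicate edge ({exc})") from exc
    return g


def write_edge_list(graph: Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges(), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{v}\n")


_OP_CODE = {INSERT: "+", DELETE: "-"}
_CODE_OP = {"+": INSERT, "-": DELETE}


def read_edit_script(path) -> EditScript:
    """Read a 3-column edit-script TSV: op in {+, -}, node u, node v."""
    script = EditScript()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[0] not in _CODE_OP:
                raise ValueError(f"{path}:{lineno}: expected '+|-\\tu\\tv'")
            script.append(EditOp(_CODE_OP[parts[0]], parts[1], parts[2]))
    return script


def write_edit_script(script: EditScript, path) -> None:
    with open(path, "w") as fh:
        for op in script:
            fh.write(f"{_OP_CODE[op.kind]}\t{op.u}\t{op.v}\n")
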