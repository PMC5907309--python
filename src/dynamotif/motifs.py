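"""Motif (pattern) representation and isomorphism testing for small graphs.

A pattern is a small connected unlabeled graph: it defines the topology of
an equivalence class of subgraphs under isomorphism.  Patterns carry a
cached diameter k (the search radius used when new embeddings must be found
around an inserted edge) and a canonical form used as the equivalence-class
key.

The canonical form is the lexicographically minimal upper-triangle
adjacency encoding over all node permutations — exhaustive, hence exact,
and perfectly adequate at motif scale (<= ~8 nodes).
"""

from __future__ import annotations

from itertools import permutations
from typing import Iterable

from .graph_core import Graph

_MAX_CANON_NODES = 10  # factorial blow-up guard


def _canonical_form(n_nodes: int, edges: set[tuple[int, int]]) -> tuple:
    """Minimal adjacency encoding of an unlabeled graph on nodes 0..n-1."""
    if n_nodes > _MAX_CANON_NODES:
        raise ValueError(
            f"canonical form limited to {_MAX_CANON_NODES} nodes, got {n_nodes}"
        )
    adj = [[0] * n_nodes for _ in range(n_nodes)]
    for u, v in edges:
        adj[u][v] = adj[v][u] = 1
    best = None
    for perm in permutations(range(n_nodes)):
        code = tuple(
            adj[perm[i]][perm[j]] for i in range(n_nodes) for j in range(i + 1, n_nodes)
        )
        if best is None or code < best:
            best = code
    return (n_nodes, best)


def _normalize_edges(edges: Iterable[tuple]) -> tuple[int, set[tuple[int, int]]]:
    """Relabel arbitrary node labels to 0..n-1 (sorted by string form)."""
    edges = list(edges)
    nodes = sorted({n for e in edges for n in e}, key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    out = set()
    for u, v in edges:
        if u == v:
            raise ValueError("self-loop in pattern")
        a, b = idx[u], idx[v]
        out.add((min(a, b), max(a, b)))
    return len(nodes), out


class Pattern:
    """A small connected unlabeled motif topology.

    Parameters
    ----------
    edges : iterable of node pairs
        The motif's edges; node labels are discarded after normalization.
    name : str, optional
        Display name (the built-ins use path2/path3/triangle/star3).
    """

    def __init__(self, edges: Iterable[tuple], name: str | None = None):
        n, norm = _normalize_edges(edges)
        if not norm:
            raise ValueError("pattern must have at least one edge")
        self.n_nodes = n
        self.edges = frozenset(norm)
        self.n_edges = len(norm)
        self.name = name
        g = Graph(norm)
        dists = [g.distance(u, v) for u in g.nodes() for v in g.nodes()]
        if any(d == float("inf") for d in dists):
            raise ValueError("pattern must be connected")
        #: diameter k — the radius searched around an inserted edge
        self.diameter: int = int(max(dists))
        self.canonical_form = _canonical_form(n, norm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pattern):
            return NotImplemented
        return self.canonical_form == other.canonical_form

    def __hash__(self) -> int:
        return hash(self.canonical_form)

    def __repr__(self) -> str:
        label = self.name or f"{self.n_nodes}n{self.n_edges}e"
        return f"Pattern({label}, diameter={self.diameter})"

    def matches_edge_set(self, edges: Iterable[tuple]) -> bool:
        """True iff the given edge set is isomorphic to this pattern."""
        n, norm = _normalize_edges(edges)
        if len(norm) != self.n_edges or n != self.n_nodes:
            return False
        return _canonical_form(n, norm) == self.canonical_form


def basic_motifs() -> list[Pattern]:
    """The four basic motifs: all connected topologies with 2 or 3 edges.

    Returned in the package's fixed reporting order — motif 1: 2-edge path,
    motif 2: 3-edge path, motif 3: triangle, motif 4: 3-edge star.  (This
    numbering is a convention of this package.)
    """
    return [
        Pattern([(0, 1), (1, 2)], name="path2"),
        Pattern([(0, 1), (1, 2), (2, 3)], name="path3"),
        Pattern([(0, 1), (1, 2), (0, 2)], name="triangle"),
        Pattern([(0, 1), (0, 2), (0, 3)], name="star3"),
    ]


BASIC_MOTIF_NAMES = ("path2", "path3", "triangle", "star3")


def motif_by_name(name: str) -> Pattern:
    for p in basic_motifs():
        if p.name == name:
            return p
    raise KeyError(f"unknown built-in motif {name!r}; choose from {BASIC_MOTIF_NAMES}")


def _as_edges(graph) -> tuple[int, set[tuple[int, int]]]:
    if isinstance(graph, Pattern):
        return graph.n_nodes, set(graph.edges)
    if isinstance(graph, Graph):
        nodes = sorted(graph.nodes(), key=str)
        idx = {n: i for i, n in enumerate(nodes)}
        return len(nodes), {
            (min(idx[u], idx[v]), max(idx[u], idx[v])) for u, v in graph.edges()
        }
    return _normalize_edges(graph)


def are_isomorphic(g1, g2) -> bool:
    """Edge-preserving bijection test for small graphs.

    Accepts :class:`~dynamotif.graph_core.Graph` objects, Patterns, or bare
    edge iterables.  Isolated nodes count (two graphs must have the same
    node count to be isomorphic); bare edge lists carry no isolated nodes.
    """
    n1, e1 = _as_edges(g1)
    n2, e2 = _as_edges(g2)
    if n1 != n2 or len(e1) != len(e2):
        return False
    return _canonical_form(n1, e1) == _canonical_form(n2, e2)
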