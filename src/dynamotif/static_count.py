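"""Static motif counting: embedding enumeration, overlap graph, greedy packing.

Three frequency definitions are supported for a pattern P in a host graph G:

* **F1** — the number of embeddings (subgraphs of G isomorphic to P),
  overlaps allowed.  An embedding is identified by its *edge set*: the
  automorphic re-mappings of one edge set are a single embedding, so F1 is
  the cardinality of the equivalence class of subgraphs.
* **F2** — the size of a maximal set of pairwise edge-disjoint embeddings.
* **F3** — the size of a maximal set of pairwise node-disjoint embeddings.

F2/F3 are obtained heuristically (the exact problems are maximum
independent set, NP-complete) by a min-degree greedy on the *overlap
graph*: one node per embedding, an edge between two embeddings that share
at least one host edge (or node, for F3).  Repeatedly the minimum-degree
node is selected and removed together with its neighbors until no node
remains; the selected embeddings form the disjoint set S'.

Enumeration is exact.  The four basic motifs (2-edge path, 3-edge path,
triangle, 3-edge star) have direct combinatorial enumerators; any other
small connected pattern falls back to anchored growth of connected edge
subsets classified by canonical form.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import networkx as nx

from .graph_core import Edge, Graph, Node, edge_key
from .motifs import Pattern, basic_motifs

Conflict = Literal["edge", "node"]

_BASIC = {p.name: p.canonical_form for p in basic_motifs()}


@dataclass(frozen=True, slots=True)
class Embedding:
    """A subgraph of the host isomorphic to the pattern, keyed by its edge set."""

    id: int
    edges: frozenset[Edge]

    @property
    def nodes(self) -> frozenset[Node]:
        return frozenset(n for e in self.edges for n in e)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _incident_edges(graph: Graph) -> dict[Node, list[tuple[Node, Edge]]]:
    """Per node: [(neighbor, canonical edge tuple)], sharing tuple objects."""
    inc: dict[Node, list[tuple[Node, Edge]]] = {n: [] for n in graph.nodes()}
    for e in graph.edges():
        u, v = e
        inc[u].append((v, e))
        inc[v].append((u, e))
    return inc


def _enum_path2(graph: Graph):
    inc = _incident_edges(graph)
    for c, lst in inc.items():
        for (x, ex), (y, ey) in combinations(lst, 2):
            yield frozenset((ex, ey))


def _enum_triangle(graph: Graph):
    rank = {n: i for i, n in enumerate(sorted(graph.nodes(), key=str))}
    adj = graph.adj
    for u in adj:
        ru = rank[u]
        for v in adj[u]:
            if rank[v] <= ru:
                continue
            rv = rank[v]
            av = adj[v]
            for w in adj[u]:
                if rank[w] > rv and w in av:
                    yield frozenset((edge_key(u, v), edge_key(u, w), edge_key(v, w)))


def _enum_star3(graph: Graph):
    inc = _incident_edges(graph)
    for c, lst in inc.items():
        if len(lst) >= 3:
            for trio in combinations(lst, 3):
                yield frozenset(e for _, e in trio)


def _enum_path3(graph: Graph):
    # every 4-node path has a unique central edge
    inc = _incident_edges(graph)
    for e in graph.edges():
        u, v = e
        for x, ex in inc[u]:
            if x == v:
                continue
            for y, ey in inc[v]:
                if y != u and y != x:
                    yield frozenset((ex, e, ey))


_FAST_ENUM = {
    _BASIC["path2"]: _enum_path2,
    _BASIC["path3"]: _enum_path3,
    _BASIC["triangle"]: _enum_triangle,
    _BASIC["star3"]: _enum_star3,
}


def _grow_edge_sets(graph: Graph, seed: Edge, size: int,
                    min_index: dict[Edge, int] | None = None):
    """All connected edge subsets of the given size that contain ``seed``.

    ``min_index`` restricts growth to edges of index greater than the
    seed's, which makes the per-anchor enumeration duplicate-free across
    anchors during full enumeration.
    """
    inc = _incident_edges(graph)
    level = {frozenset((seed,))}
    lo = min_index[seed] if min_index is not None else None
    for _ in range(size - 1):
        nxt = set()
        for s in level:
            nodes = {n for e in s for n in e}
            for n in nodes:
                for _, f in inc[n]:
                    if f in s:
                        continue
                    if lo is not None and min_index[f] <= lo:
                        continue
                    nxt.add(s | {f})
        level = nxt
    return level


def _enum_generic(graph: Graph, pattern: Pattern):
    edges = list(graph.edges())
    index = {e: i for i, e in enumerate(edges)}
    for e in edges:
        grown = _grow_edge_sets(graph, e, pattern.n_edges, min_index=index)
        # sort per anchor: discovery order must not depend on set hashing
        for s in sorted(grown, key=lambda s: sorted(map(str, s))):
            if pattern.matches_edge_set(s):
                yield s


def enumerate_embeddings(graph: Graph, pattern: Pattern) -> list[Embedding]:
    """Every embedding of ``pattern`` in ``graph``, exactly once (F1 = length).

    Ids are assigned in discovery order, which is deterministic for a given
    graph construction history.
    """
    enum = _FAST_ENUM.get(pattern.canonical_form)
    sets = enum(graph) if enum is not None else _enum_generic(graph, pattern)
    return [Embedding(i, s) for i, s in enumerate(sets)]


def embeddings_containing(graph: Graph, pattern: Pattern, edge: Edge,
                          start_id: int = 0) -> list[Embedding]:
    """Embeddings of ``pattern`` that contain the given host edge.

    This is the local search run after an edge insertion.  All such
    embeddings lie inside the k-neighborhood of the edge (k = pattern
    diameter); anchored growth from the edge explores exactly that region.
    Results are ordered deterministically (sorted by edge set) before ids
    are assigned from ``start_id``.
    """
    e = edge_key(*edge)
    adj = graph.adj
    canon = pattern.canonical_form
    found: set[frozenset[Edge]]
    if canon == _BASIC["path2"]:
        u, v = e
        found = {frozenset((e, edge_key(u, x))) for x in adj[u] if x != v}
        found |= {frozenset((e, edge_key(v, y))) for y in adj[v] if y != u}
    elif canon == _BASIC["triangle"]:
        u, v = e
        found = {
            frozenset((e, edge_key(u, w), edge_key(v, w)))
            for w in adj[u] if w in adj[v]
        }
    elif canon == _BASIC["star3"]:
        found = set()
        for c, o in (e, e[::-1]):
            others = [x for x in adj[c] if x != o]
            for x, y in combinations(others, 2):
                found.add(frozenset((e, edge_key(c, x), edge_key(c, y))))
    elif canon == _BASIC["path3"]:
        found = set()
        u, v = e
        for x in adj[u]:  # e central
            if x == v:
                continue
            ex = edge_key(u, x)
            for y in adj[v]:
                if y != u and y != x:
                    found.add(frozenset((ex, e, edge_key(v, y))))
        for a, b in (e, e[::-1]):  # e terminal, extend from b
            for w in adj[b]:
                if w == a:
                    continue
                ew = edge_key(b, w)
                for z in adj[w]:
                    if z != a and z != b:
                        found.add(frozenset((e, ew, edge_key(w, z))))
    else:
        found = {
            s for s in _grow_edge_sets(graph, e, pattern.n_edges)
            if pattern.matches_edge_set(s)
        }
    ordered = sorted(found, key=lambda s: sorted(map(str, s)))
    return [Embedding(start_id + i, s) for i, s in enumerate(ordered)]


# ---------------------------------------------------------------------------
# overlap structure
# ---------------------------------------------------------------------------

def _buckets(embeddings: Iterable[Embedding], conflict: Conflict) -> dict:
    """Conflict-key buckets: host edge (or node) -> list of embedding ids."""
    buckets: dict = {}
    for emb in embeddings:
        keys = emb.edges if conflict == "edge" else emb.nodes
        for k in keys:
            buckets.setdefault(k, []).append(emb.id)
    return buckets


def _overlap_adjacency(embeddings: Sequence[Embedding],
                       conflict: Conflict) -> dict[int, set[int]]:
    """Explicit overlap adjacency (id -> conflicting ids).

    Cost is sum over buckets of |bucket|^2; intended for small and medium
    instances (tests, worked examples, diagnostics).
    """
    adj: dict[int, set[int]] = {emb.id: set() for emb in embeddings}
    for ids in _buckets(embeddings, conflict).values():
        for i, j in combinations(ids, 2):
            adj[i].add(j)
            adj[j].add(i)
    return adj


class OverlapGraph:
    """Overlap graph G^o: one node per embedding, edges between conflicting ones.

    ``phi`` is the bijection from overlap-graph node (embedding id) to the
    embedding itself.
    """

    def __init__(self, embeddings: Sequence[Embedding], conflict: Conflict = "edge"):
        self.conflict: Conflict = conflict
        self.phi: dict[int, Embedding] = {emb.id: emb for emb in embeddings}
        if len(self.phi) != len(embeddings):
            raise ValueError("duplicate embedding ids")
        self.graph = nx.Graph()
        self.graph.add_nodes_from(self.phi)
        for i, nbrs in _overlap_adjacency(embeddings, conflict).items():
            self.graph.add_edges_from((i, j) for j in nbrs if j > i)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_overlap_graph(embeddings: Sequence[Embedding],
                        conflict: Conflict = "edge") -> OverlapGraph:
    """Build the overlap graph (edge-sharing by default, node-sharing for F3)."""
    return OverlapGraph(embeddings, conflict)


# ---------------------------------------------------------------------------
# greedy packing
# ---------------------------------------------------------------------------

def _greedy_on_adjacency(ids: Sequence[int], adj: dict[int, set[int]],
                         rng=None) -> list[int]:
    """Min-degree greedy independent set, degrees recomputed on the residual graph.

    Ties are broken by smallest id (deterministic default) or uniformly at
    random when ``rng`` is given.
    """
    alive = set(ids)
    deg = {i: len(adj[i]) for i in ids}
    chosen: list[int] = []
    if rng is None:
        heap = [(deg[i], i) for i in ids]
        heapq.heapify(heap)
        while heap:
            d, i = heapq.heappop(heap)
            if i not in alive or d != deg[i]:
                continue
            chosen.append(i)
            victims = [i] + [j for j in adj[i] if j in alive]
            for v in victims:
                alive.discard(v)
            for v in victims:
                for w in adj[v]:
                    if w in alive:
                        deg[w] -= 1
                        heapq.heappush(heap, (deg[w], w))
    else:
        while alive:
            dmin = min(deg[i] for i in alive)
            ties = sorted(i for i in alive if deg[i] == dmin)
            i = ties[rng.randrange(len(ties))]
            chosen.append(i)
            victims = [i] + [j for j in adj[i] if j in alive]
            for v in victims:
                alive.discard(v)
            for v in victims:
                for w in adj[v]:
                    if w in alive:
                        deg[w] -= 1
    return chosen


def _initial_degrees(embeddings: Sequence[Embedding],
                     conflict: Conflict) -> dict[int, int]:
    """Overlap-graph degree of every embedding, without materializing G^o.

    For edge conflicts on patterns with <= 3 edges, two distinct embeddings
    share at most 2 edges, so inclusion–exclusion over single edges and
    edge pairs gives exact distinct-neighbor counts in linear time.  Other
    cases fall back to explicit neighbor unions.
    """
    max_m = max((len(e.edges) for e in embeddings), default=0)
    buckets = _buckets(embeddings, conflict)
    sizes = {k: len(v) for k, v in buckets.items()}
    if conflict == "edge" and max_m <= 3:
        deg = {}
        pair_count: dict[tuple, int] = {}
        if max_m >= 3:
            for emb in embeddings:
                for pair in combinations(sorted(emb.edges), 2):
                    pair_count[pair] = pair_count.get(pair, 0) + 1
        for emb in embeddings:
            d = sum(sizes[e] - 1 for e in emb.edges)
            if pair_count:
                for pair in combinations(sorted(emb.edges), 2):
                    d -= pair_count[pair] - 1
            deg[emb.id] = d
        return deg
    deg = {}
    for emb in embeddings:
        keys = emb.edges if conflict == "edge" else emb.nodes
        nbrs: set[int] = set()
        for k in keys:
            nbrs.update(buckets[k])
        deg[emb.id] = len(nbrs) - 1
    return deg


def _greedy_initial_order(embeddings: Sequence[Embedding], conflict: Conflict,
                          rng=None) -> list[int]:
    """Greedy packing scanning embeddings in ascending initial-degree order.

    Degrees are computed once on the full overlap graph and not updated as
    embeddings are removed; an embedding is selected iff it conflicts with
    no previously selected one.  This scales to instances whose overlap
    graph is too dense to walk explicitly.
    """
    deg = _initial_degrees(embeddings, conflict)
    by_id = {emb.id: emb for emb in embeddings}
    if rng is None:
        order = sorted(deg, key=lambda i: (deg[i], i))
    else:
        jitter = {i: rng.random() for i in deg}
        order = sorted(deg, key=lambda i: (deg[i], jitter[i]))
    owner: dict = {}
    chosen: list[int] = []
    for i in order:
        keys = by_id[i].edges if conflict == "edge" else by_id[i].nodes
        if all(k not in owner for k in keys):
            chosen.append(i)
            for k in keys:
                owner[k] = i
    return chosen


def greedy_disjoint(overlap: OverlapGraph,
                    mode: Literal["edge_disjoint", "node_disjoint"] = "edge_disjoint",
                    rng=None) -> list[Embedding]:
    """Min-degree greedy independent set of the overlap graph (the set S').

    ``mode`` must agree with the conflict relation the overlap graph was
    built with: F2 needs edge-sharing conflicts, F3 node-sharing ones.
    """
    want = "edge" if mode == "edge_disjoint" else "node"
    if overlap.conflict != want:
        raise ValueError(
            f"{mode} requires an overlap graph built with conflict={want!r}, "
            f"got {overlap.conflict!r}"
        )
    adj = {i: set(overlap.graph.neighbors(i)) for i in overlap.graph.nodes}
    ids = sorted(adj)
    chosen = _greedy_on_adjacency(ids, adj, rng=rng)
    return [overlap.phi[i] for i in sorted(chosen)]


def disjoint_embeddings(embeddings: Sequence[Embedding],
                        conflict: Conflict = "edge",
                        degree: Literal["residual", "initial"] = "residual",
                        rng=None) -> list[Embedding]:
    """Greedy maximal disjoint subset of the embeddings (F2/F3 heuristic).

    degree="residual" recomputes overlap degrees on the residual graph
    after every selection (the faithful min-degree greedy; requires the
    explicit overlap adjacency).  degree="initial" ranks embeddings by
    their initial overlap degree only and never walks the overlap graph,
    trading a slightly different greedy order for scalability on dense
    instances.  Both produce maximal disjoint sets.
    """
    if degree == "residual":
        adj = _overlap_adjacency(embeddings, conflict)
        chosen = _greedy_on_adjacency(sorted(adj), adj, rng=rng)
    else:
        chosen = _greedy_initial_order(embeddings, conflict, rng=rng)
    by_id = {emb.id: emb for emb in embeddings}
    return [by_id[i] for i in sorted(chosen)]


def exact_disjoint_count(embeddings: Sequence[Embedding],
                         conflict: Conflict = "edge") -> int:
    """Exact maximum disjoint-set size by branch-and-bound (exponential).

    Validation oracle for small instances only.
    """
    adj = _overlap_adjacency(embeddings, conflict)

    def mis(nodes: frozenset[int]) -> int:
        if not nodes:
            return 0
        v = max(nodes, key=lambda n: (len(adj[n] & nodes), -n))
        if not adj[v] & nodes:  # v isolated: always take it
            return 1 + mis(nodes - {v})
        without = mis(nodes - {v})
        with_v = 1 + mis(nodes - {v} - adj[v])
        return max(with_v, without)

    return mis(frozenset(adj))


# ---------------------------------------------------------------------------
# convenience front end
# ---------------------------------------------------------------------------

@dataclass
class StaticCounts:
    """F1/F2/F3 counts plus the underlying embedding structures."""

    f1: int
    f2: int | None
    f3: int | None
    embeddings: list[Embedding]
    f2_set: list[Embedding] | None
    f3_set: list[Embedding] | None


def count_static(graph: Graph, pattern: Pattern,
                 frequencies: Sequence[str] = ("f1", "f2", "f3"),
                 degree: Literal["residual", "initial"] = "residual",
                 rng=None) -> StaticCounts:
    """Enumerate embeddings and compute the requested frequencies."""
    embeddings = enumerate_embeddings(graph, pattern)
    f2_set = f3_set = None
    if "f2" in frequencies:
        f2_set = disjoint_embeddings(embeddings, "edge", degree=degree, rng=rng)
    if "f3" in frequencies:
        f3_set = disjoint_embeddings(embeddings, "node", degree=degree, rng=rng)
    return StaticCounts(
        f1=len(embeddings),
        f2=len(f2_set) if f2_set is not None else None,
        f3=len(f3_set) if f3_set is not None else None,
        embeddings=embeddings,
        f2_set=f2_set,
        f3_set=f3_set,
    )
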