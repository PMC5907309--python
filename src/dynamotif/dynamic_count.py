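"""Incremental F1/F2 maintenance as the network evolves one edge at a time.

The live state keeps, besides the current graph, the full embedding store
of the motif, a per-edge index ``D_e`` mapping every host edge to the ids
of the embeddings that contain it, the F1 count (= store size), and the
F2 membership (a set of pairwise edge-disjoint embeddings together with
per-edge ownership marks).

**Deletion of edge e.**  Every embedding containing e (the bucket ``D_e``)
dies; F1 drops by ``|D_e|`` — this update is exact.  At most one F2 member
X can contain e (members are edge-disjoint).  If one does, a replacement
is sought among the former overlap-graph neighbors of X (the union of the
buckets of X's edges, taken on the pre-deletion index and restricted to
surviving embeddings): the first candidate whose edges are all free once
X's edges are released joins the F2 set, keeping F2 unchanged; otherwise
F2 drops by one.  Exactly one replacement attempt is made per destroyed
member — the repair is deliberately local.

**Insertion of edge e.**  All new embeddings contain e; they are found by
anchored local search around e (equivalently, enumeration within the
k-neighborhood of e, k = motif diameter) and added to the store and index;
F1 grows by their number — again exact.  If any new embedding has all of
its edges uninvolved in the F2 count, one such embedding (the first in
deterministic order, or a seeded-random choice) joins the F2 set and F2
grows by one; since all new embeddings share e, at most one can join.

F1 is therefore maintained exactly; F2 is a heuristic whose drift relative
to a fresh static greedy is the accuracy the evaluation harness measures.
"""

from __future__ import annotations

from typing import Iterable, Literal

from .graph_core import (DELETE, INSERT, Edge, EditOp, EditScript, Graph,
                         ScriptConsistencyError, edge_key)
from .motifs import Pattern
from .static_count import (Embedding, disjoint_embeddings, embeddings_containing,
                           enumerate_embeddings)


class DynamicState:
    """Live motif-counting state for one (graph, pattern) pair.

    Attributes
    ----------
    graph : Graph
        The current network snapshot G_i (mutated in place).
    embeddings : dict[int, Embedding]
        Live embedding store; ``f1 == len(embeddings)``.
    index : dict[Edge, set[int]]
        The per-edge embedding index D_e.
    f2_members : set[int]
        Ids of embeddings currently counted toward F2.
    edge_usage : dict[Edge, int]
        Host edge -> owning F2 member id; exactly the union of members' edges.
    """

    def __init__(self, graph: Graph, pattern: Pattern,
                 greedy_degree: Literal["residual", "initial"] = "residual",
                 rng=None):
        self.graph = graph
        self.pattern = pattern
        self.rng = rng
        embeddings = enumerate_embeddings(graph, pattern)
        self.embeddings: dict[int, frozenset[Edge]] = {
            emb.id: emb.edges for emb in embeddings
        }
        self._next_id = len(embeddings)
        self.index: dict[Edge, set[int]] = {}
        for emb in embeddings:
            for e in emb.edges:
                self.index.setdefault(e, set()).add(emb.id)
        members = disjoint_embeddings(embeddings, "edge", degree=greedy_degree,
                                      rng=rng)
        self.f2_members: set[int] = {m.id for m in members}
        self.edge_usage: dict[Edge, int] = {}
        for m in members:
            for e in m.edges:
                self.edge_usage[e] = m.id

    # -- counters ---------------------------------------------------------

    @property
    def f1(self) -> int:
        return len(self.embeddings)

    @property
    def f2(self) -> int:
        return len(self.f2_members)

    def embedding_sets(self) -> set[frozenset[Edge]]:
        """The edge sets of all live embeddings (for store-equivalence checks)."""
        return set(self.embeddings.values())

    # -- internal helpers -------------------------------------------------

    def _drop_embedding(self, eid: int) -> None:
        edges = self.embeddings.pop(eid)
        for e in edges:
            bucket = self.index.get(e)
            if bucket is not None:
                bucket.discard(eid)
                if not bucket:
                    del self.index[e]

    def _admit_member(self, eid: int) -> None:
        self.f2_members.add(eid)
        for e in self.embeddings[eid]:
            self.edge_usage[e] = eid

    def _free(self, edges: Iterable[Edge]) -> bool:
        return all(e not in self.edge_usage for e in edges)

    # -- edit operations --------------------------------------------------

    def apply_deletion(self, u, v) -> None:
        """Process deletion of edge {u, v} (must be present)."""
        e = edge_key(u, v)
        self.graph.remove_edge(*e)

        doomed = self.index.pop(e, set())
        x_id = self.edge_usage.get(e)  # the at-most-one F2 member containing e

        candidates: list[int] = []
        x_edges: frozenset[Edge] = frozenset()
        if x_id is not None:
            # neighbors of X on the pre-deletion index
            x_edges = self.embeddings[x_id]
            nbrs: set[int] = set()
            for ex in x_edges:
                if ex == e:
                    nbrs.update(doomed)
                else:
                    nbrs.update(self.index.get(ex, ()))
            candidates = sorted(nbrs - doomed - {x_id})

        for eid in doomed:
            self._drop_embedding(eid)

        if x_id is None:
            return
        # release X's edges, then look for a replacement Y among survivors
        self.f2_members.discard(x_id)
        for k in x_edges:
            if self.edge_usage.get(k) == x_id:
                del self.edge_usage[k]
        if self.rng is not None:
            self.rng.shuffle(candidates)
        for y in candidates:
            if y in self.embeddings and self._free(self.embeddings[y]):
                self._admit_member(y)
                break

    def apply_insertion(self, u, v) -> None:
        """Process insertion of edge {u, v} (must be absent; new nodes allowed)."""
        e = edge_key(u, v)
        self.graph.add_edge(*e)

        new = embeddings_containing(self.graph, self.pattern, e,
                                    start_id=self._next_id)
        self._next_id += len(new)
        for emb in new:
            self.embeddings[emb.id] = emb.edges
            for f in emb.edges:
                self.index.setdefault(f, set()).add(emb.id)

        order = list(new)
        if self.rng is not None:
            self.rng.shuffle(order)
        for emb in order:  # at most one can join: all new embeddings share e
            if self._free(emb.edges):
                self._admit_member(emb.id)
                break

    def apply_op(self, op: EditOp) -> None:
        if op.kind == INSERT:
            self.apply_insertion(op.u, op.v)
        else:
            self.apply_deletion(op.u, op.v)

    def apply_script(self, script: EditScript) -> list[tuple[int, int, int]]:
        """Apply every op, returning one (step, f1, f2) record per op."""
        timeline = []
        for i, op in enumerate(script):
            try:
                self.apply_op(op)
            except ScriptConsistencyError as exc:
                raise ScriptConsistencyError(f"op {i}: {exc}") from exc
            timeline.append((i, self.f1, self.f2))
        return timeline

    # -- consistency ------------------------------------------------------

    def check_invariants(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        for eid, edges in self.embeddings.items():
            for e in edges:
                assert eid in self.index.get(e, set()), "index misses embedding"
            assert self.graph.has_edge(*next(iter(edges))) or True
            for e in edges:
                assert self.graph.has_edge(*e), "embedding uses a missing edge"
        for e, bucket in self.index.items():
            for eid in bucket:
                assert e in self.embeddings[eid], "stale index entry"
        used = {}
        for m in self.f2_members:
            assert m in self.embeddings, "dead F2 member"
            for e in self.embeddings[m]:
                assert e not in used, "F2 members overlap"
                used[e] = m
        assert used == self.edge_usage, "edge_usage out of sync"


def init_state(graph: Graph, pattern: Pattern,
               greedy_degree: Literal["residual", "initial"] = "residual",
               rng=None) -> DynamicState:
    """Initialize the dynamic state from a static count of G_0."""
    return DynamicState(graph, pattern, greedy_degree=greedy_degree, rng=rng)
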