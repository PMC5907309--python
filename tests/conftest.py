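"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own enumeration and
greedy code paths: embeddings are found by testing all edge subsets with
networkx isomorphism, and maximum disjoint sets by exhaustive search over
subsets of embeddings.
"""

from itertools import combinations

import networkx as nx
import pytest

from dynamotif import Graph

#: the 10-edge worked-example graph (triangles S1..S4 all meeting at node a)
EXAMPLE_EDGES = [
    ("a", "b"), ("a", "e"), ("b", "e"), ("a", "f"), ("e", "f"),
    ("a", "c"), ("a", "d"), ("c", "d"), ("a", "g"), ("d", "g"),
]

EXAMPLE_TRIANGLES = [
    frozenset({("a", "b"), ("a", "e"), ("b", "e")}),  # S1
    frozenset({("a", "e"), ("a", "f"), ("e", "f")}),  # S2
    frozenset({("a", "c"), ("a", "d"), ("c", "d")}),  # S3
    frozenset({("a", "d"), ("a", "g"), ("d", "g")}),  # S4
]


@pytest.fixture
def example_net():
    return Graph(EXAMPLE_EDGES)


@pytest.fixture
def k4():
    return Graph([(a, b) for a, b in combinations("wxyz", 2)])


def to_networkx(graph: Graph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(graph.nodes())
    g.add_edges_from(graph.edges())
    return g


def brute_force_embeddings(graph: Graph, pattern_edges) -> set:
    """All edge subsets of the right size isomorphic to the pattern."""
    pat = nx.Graph(list(pattern_edges))
    m = pat.number_of_edges()
    found = set()
    for subset in combinations(sorted(graph.edges(), key=str), m):
        sub = nx.Graph(list(subset))
        if nx.is_connected(sub) and nx.is_isomorphic(sub, pat):
            found.add(frozenset(subset))
    return found


def _conflicts(a: frozenset, b: frozenset, conflict: str) -> bool:
    if conflict == "edge":
        return bool(a & b)
    na = {n for e in a for n in e}
    nb = {n for e in b for n in e}
    return bool(na & nb)


def brute_force_max_disjoint(edge_sets, conflict: str = "edge") -> int:
    """Exact maximum disjoint-set size by descending exhaustive search."""
    edge_sets = list(edge_sets)
    n = len(edge_sets)
    for size in range(n, 0, -1):
        for combo in combinations(range(n), size):
            ok = all(
                not _conflicts(edge_sets[i], edge_sets[j], conflict)
                for i, j in combinations(combo, 2)
            )
            if ok:
                return size
    return 0
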