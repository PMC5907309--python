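"""Random-network generation and degree-preserving shuffle scripts.

Three standard generative models are supported, parameterized by node
count (*size*) and target average degree:

* **ER** — Erdős–Rényi G(n, p) with p = degree / (size − 1);
* **WS** — Watts–Strogatz ring lattice with nearest-neighbor parameter
  rounded to the nearest even value of the degree and configurable
  rewiring probability (default 0.1, the conventional small-world regime);
* **BA** — Barabási–Albert preferential attachment with m = round(degree/2).

Topology perturbations are degree-preserving edge shuffles: two
node-disjoint edges (a,b) and (u,v) are replaced by (a,v) and (u,b)
(orientation chosen at random), rejecting candidates whose replacement
edges already exist.  Each shuffle is compiled into 2 deletions + 2
insertions emitted in a random order; because the old and new edge pairs
are disjoint, every order keeps the script valid.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx

from .graph_core import DELETE, INSERT, EditOp, EditScript, Graph


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic network."""

    model: str  # "ER", "WS" or "BA"
    size: int
    degree: float
    seed: int
    ws_rewire: float = 0.1
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.model = self.model.upper()
        if self.model not in ("ER", "WS", "BA"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.size < 4:
            raise ValueError("size must be >= 4")
        if self.degree < 2:
            raise ValueError("degree must be >= 2")


def _from_networkx(g: nx.Graph) -> Graph:
    """Convert to the package graph, relabeling nodes to strings."""
    out = Graph()
    for n in g.nodes:
        out.add_node(str(n))
    for u, v in g.edges:
        if u != v:
            out.add_edge(str(u), str(v))
    return out


def generate(config: GeneratorConfig) -> Graph:
    """Generate a simple undirected random graph per the config (seeded)."""
    n, d, seed = config.size, config.degree, config.seed
    if config.model == "ER":
        g = nx.gnp_random_graph(n, d / (n - 1), seed=seed)
    elif config.model == "WS":
        k = max(2, 2 * round(d / 2))
        if k >= n:
            raise ValueError(f"WS lattice parameter {k} must be < size {n}")
        g = nx.watts_strogatz_graph(n, k, config.ws_rewire, seed=seed)
    else:  # BA
        m = max(1, round(d / 2))
        if m >= n:
            raise ValueError(f"BA attachment parameter {m} must be < size {n}")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    return _from_networkx(g)


def shuffle_script(graph: Graph, n_ops: int, seed: int,
                   max_tries: int = 1000) -> EditScript:
    """Compile ``n_ops // 4`` degree-preserving shuffles into an edit script.

    The input graph is not modified.  Each shuffle samples two edges
    uniformly from the current (evolving) edge list; candidates sharing a
    node, or whose replacement edges already exist, are rejected and
    resampled (at most ``max_tries`` times per shuffle).
    """
    if n_ops % 4 != 0:
        raise ValueError("n_ops must be divisible by 4 (each shuffle is 4 ops)")
    rng = random.Random(seed)
    work = graph.copy()
    edges = list(work.edges())
    pos = {e: i for i, e in enumerate(edges)}
    script = EditScript()

    def remove_edge_entry(e):
        i = pos.pop(e)
        last = edges.pop()
        if last != e:
            edges[i] = last
            pos[last] = i

    def add_edge_entry(e):
        pos[e] = len(edges)
        edges.append(e)

    for _ in range(n_ops // 4):
        for attempt in range(max_tries):
            if len(edges) < 2:
                raise RuntimeError("not enough edges to shuffle")
            e1 = edges[rng.randrange(len(edges))]
            e2 = edges[rng.randrange(len(edges))]
            a, b = e1
            u, v = e2
            if len({a, b, u, v}) < 4:
                continue
            if rng.random() < 0.5:  # random pairing orientation
                u, v = v, u
            # replacements: (a, v) and (u, b)
            if work.has_edge(a, v) or work.has_edge(u, b):
                continue
            ops = [
                EditOp(DELETE, *e1),
                EditOp(DELETE, *e2),
                EditOp(INSERT, a, v),
                EditOp(INSERT, u, b),
            ]
            rng.shuffle(ops)  # any order is valid: old and new pairs are disjoint
            for op in ops:
                if op.kind == DELETE:
                    work.remove_edge(op.u, op.v)
                    remove_edge_entry(op.edge)
                else:
                    work.add_edge(op.u, op.v)
                    add_edge_entry(op.edge)
                script.append(op)
            break
        else:
            raise RuntimeError(
                f"no valid shuffle found after {max_tries} resamples"
            )
    return script
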