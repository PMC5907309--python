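# Methods

## Model and definitions

The host network is an undirected simple graph G = (V, E) with opaque
(string) node labels. Its evolution is an ordered *edit script* of
single-edge operations; G_i denotes the topology after the i-th operation,
so |E_i − E_{i−1}| = 1. Node insertion and deletion reduce to edge
operations: inserting an edge with an unknown endpoint creates that node,
and a node is effectively deleted by deleting all of its incident edges
(isolated nodes are retained — they cannot host embeddings of connected
motifs with at least one edge, so counts are unaffected). Edit scripts
carry explicit insert/delete kinds, and an insert of a present edge or a
delete of an absent edge raises a consistency error rather than silently
toggling the edge: malformed scripts fail loudly. The network may become
disconnected during evolution; nothing in the algorithms requires
connectivity of the host, only of motifs.

A *motif* (pattern) is a small connected unlabeled graph. An *embedding*
of a pattern P in G is an edge subset of G whose subgraph is isomorphic to
P; the edge set is the identity of the embedding, so automorphic
re-mappings of the same subgraph count once. Frequencies:

* F1 = number of embeddings;
* F2 = size of a maximal set of pairwise edge-disjoint embeddings;
* F3 = size of a maximal set of pairwise node-disjoint embeddings.

Patterns are canonicalized by the lexicographically minimal
upper-triangular adjacency encoding over all node permutations. This is
O(n!) and intentionally so: exactness is trivial to audit and the cost is
irrelevant at motif scale (≤ ~8 nodes; larger canonical labeling à la
nauty is out of scope). The pattern's diameter k is cached; it bounds the
search radius for new embeddings after an edge insertion.

The four *basic motifs* — all connected topologies with two or three
edges — are reported in the fixed order: motif 1 = 2-edge path, motif 2 =
3-edge path, motif 3 = triangle, motif 4 = 3-edge star. The numbering is
a convention of this package (no canonical ordering of these four exists);
only the topologies matter.

## Static counting

Enumeration grows connected edge subsets anchored at each edge, keeping
subsets whose canonical form matches the pattern; an index-ordering rule
makes the enumeration duplicate-free. The four basic motifs use direct
combinatorial enumerators instead (pairs/triples of edges at a common
node, common-neighbor triangles, and 3-paths keyed by their unique central
edge); these are exact and roughly an order of magnitude faster, which is
what makes the evaluation experiment tractable in pure Python. Both routes
are cross-checked in the tests against brute-force subset enumeration with
networkx isomorphism testing.

F2/F3 use the min-degree greedy on the overlap graph (conflict = shared
edge, resp. shared node): repeatedly select a minimum-degree node, add its
embedding to S′, and remove it with its neighbors. Two greedy variants are
provided:

* `degree="residual"` (default): degrees are recomputed on the residual
  overlap graph after each removal — the natural reading of an iterative
  min-degree rule. This requires the explicit overlap adjacency, whose
  size is Σ_e |D_e|² in the worst case; fine for fixtures and moderate
  instances, prohibitive for ~10⁵–10⁶ embeddings of high-frequency motifs
  in dense hosts.
* `degree="initial"`: embeddings are ranked once by their initial overlap
  degree and scanned in that order, selecting each embedding whose edges
  are still free. Initial degrees are computed without materializing the
  overlap graph: for patterns with ≤ 3 edges two distinct embeddings share
  at most two edges, so the distinct-neighbor count is exactly
  Σ_e (|D_e|−1) − Σ_{pairs e,f ⊂ X} (|D_e ∩ D_f| − 1) (inclusion–
  exclusion over single edges and edge pairs), a linear-time pass.

Both variants produce *maximal* disjoint sets and are never above the
exact optimum (verified against a brute-force maximum-independent-set
oracle on small instances, where the greedy also attains the optimum on
all worked-example-scale fixtures). The evaluation harness uses
`"initial"` on both the dynamic initialization and the static recounts so
the comparison is internally consistent and scales; the residual variant
remains the library default for static counting, where faithfulness beats
throughput. Tie-breaking among equal-degree candidates is by smallest
embedding id by default (exact reproducibility); a seeded-random mode
breaks ties uniformly instead.

## Dynamic updating

The live state holds the embedding store, the per-edge index D_e (a hash
map from canonical edge to a set of embedding ids — the semantics of an
edge-indexed bitmap with O(1) amortized updates and cheap unions), the F2
membership, and per-edge ownership marks recording which member uses each
edge.

**Deletion of e.** All embeddings in D_e die; F1 decreases by |D_e|. This
is exact by construction. At most one F2 member X contains e (members are
edge-disjoint). If one does, the repair scans the former overlap-graph
neighbors of X — the union of D_{e′} over X's edges, taken on the
pre-deletion index and restricted to surviving embeddings — for a
replacement Y whose edges are all free *after X's edges are released*; the
first qualifying candidate (ascending id, or seeded-random) joins the
membership and F2 is unchanged, otherwise F2 drops by one. Releasing X's
edges before testing candidates is the only reading under which a
replacement overlapping X can ever qualify, which is the entire point of
scanning X's neighbors. Exactly one replacement attempt is made per
destroyed member; the repair never cascades, even if several mutually
disjoint free neighbors exist — the method is deliberately local, and that
locality is precisely the accuracy/speed trade-off the harness measures.

**Insertion of e.** Every new embedding contains e, and every embedding
containing e lies within the k-neighborhood of e (k = pattern diameter).
The implementation enumerates anchored at e directly (per-motif fast
paths, generic growth otherwise), which explores exactly that region
without constructing the neighborhood subgraph; any method that finds
exactly the embeddings containing e is equivalent. New embeddings enter
the store and index; F1 grows by their number (again exact). If some new
embedding has all edges uninvolved in the F2 count, the first such (or a
seeded-random choice) joins the membership and F2 grows by one; since all
new embeddings share e, at most one can join.

Consequences, all enforced by tests: the dynamic store equals fresh static
enumeration after any valid script (F1 exactness, stronger than count
equality); F2 members are pairwise edge-disjoint and live at every step;
dynamic F2 never exceeds the exact optimum; deleting an edge in no
embedding or inserting an edge creating none is a strict no-op.

Dynamic F3 maintenance is not provided (F3 is a static-only measure here).

## Synthetic networks and perturbations

Generators (via networkx, relabeled to string nodes): ER G(n, p) with
p = degree/(n−1); WS with ring-lattice parameter the degree rounded to
even and rewiring probability 0.1 by default (the conventional small-world
regime; the value is a free parameter of the model and configurable); BA
with attachment m = round(degree/2). All are seeded and reproducible.

Perturbations are degree-preserving edge shuffles: two node-disjoint edges
(a,b), (u,v) are replaced by (a,v), (u,b), with the pairing orientation
chosen uniformly; candidates whose replacement edges already exist (or
that would self-loop) are rejected and resampled, the standard rejection
rule that keeps the graph simple. Each shuffle compiles to 2 deletions +
2 insertions in a uniformly random order — valid in any order because the
deleted and inserted pairs are disjoint — and each of the 4 ops is a real
network state: counts are updated after every single op.

## Co-expression networks

Given primary and secondary expression matrices (genes × samples, ≥ 3
samples), genes u, v are connected iff corr_primary(u,v) > stringent
(default 0.95), or corr_secondary(u,v) > stringent while
corr_primary(u,v) > relaxed (default 0.75). Comparisons are strict
("above") and apply to the signed Pearson correlation by default (an
`absolute` flag thresholds |r| — a common alternative convention). Genes
with zero variance (undefined correlation) and genes absent from one
matrix are excluded by default; the `unshared_genes="stringent-only"`
policy instead admits primary-only genes through the stringent condition
alone. A network pathway (start → final) compiles to an edit script with
one delete per edge lost and one insert per edge gained, in a seeded
uniform-random order, since the true order of events is unknown.

The synthetic expression generator is a latent-module model: genes are
partitioned into modules, each module has one standard-normal latent
profile across samples, and a gene is its module profile plus i.i.d.
Gaussian noise of standard deviation σ (default 0.15; within-module
correlations concentrate near 1/(1+σ²) ≈ 0.98, straddling the stringent
cutoff as σ varies; default 19 samples mirror a multi-cell-line
developmental panel). It reproduces the one feature that matters for this
workflow — a controllable block correlation structure yielding motif-rich
networks — and none of the features of real transcription data it does not
model (heavy-tailed expression levels, sample covariance, batch effects,
negative co-regulation). Passing tests therefore demonstrate correctness
of the construction rule and the pipeline, not biological fidelity.

## Evaluation harness

A run generates a network, compiles an n_ops shuffle script (script RNG
seeded at seed + 10007 to separate the streams), maintains F1/F2
dynamically per motif, and at checkpoints (every `checkpoint_every` ops;
the final op always) recounts statically on the same topology. Accuracy =
100 · c_dynamic / c_static, with 0/0 defined as 100 (perfect agreement on
emptiness) and values above 100 recorded as-is (the static greedy is
itself a heuristic, and the dynamic packing occasionally beats it). The
static greedy is treated as ground truth for accuracy to match how such
dynamic methods are conventionally benchmarked; on small instances the
exact optimum is additionally available for diagnostics
(`exact_disjoint_count`). With deterministic tie-breaking on both sides,
step-0 accuracy is exactly 100%, and F1 accuracy is exactly 100% at every
checkpoint.

The shipped experiment uses networks of size 1000 and average degree 10,
1000 edit operations, the four basic motifs, and five seeds per model
(ER, WS, BA) — sizes chosen so the full grid (including the pure-Python
static recounts over ~10⁵–10⁶ embeddings per motif on the BA model) runs
in minutes on one CPU. Note this perturbs a much larger *fraction* of the
network (1000 ops on ~5000 edges, a ~20% edge turnover) than the same op
count on larger hosts would, so it is a deliberately harsher test of F2
drift. Observed final F2 accuracies: mean ≈ 98% over all models, motifs
and seeds; per-motif means ≥ 97% for the two paths and the star; the
triangle is the weakest motif — its packing is most disturbed by
clustered rewiring, and on WS (the most clustered model) per-run triangle
accuracy drops to ~93–95% at this turnover fraction, recovering to ~99%
at a 5000-node host where the same 1000 ops touch only ~3% of edges.
Mean accuracy decays slowly with the number of ops, as expected for a
local repair policy drifting from a global recount.

## Numerical and degenerate-input choices

* Canonical edge orientation: lexicographically smaller endpoint first
  (string comparison), giving deterministic file output and stable ids.
* Empty graphs, empty scripts, edgeless patterns, and absent motifs all
  take defined paths (0 counts, identity application, validation errors).
* Pearson correlations are clipped to [−1, 1] against floating-point
  rounding before thresholding; correlation thresholds outside [0, 1] and
  relaxed > stringent are rejected.
* Shuffle generation aborts with an error after a bounded number of
  rejected resamples (default 1000 per shuffle) rather than looping
  forever on graphs with no valid shuffle.

## Known limitations

* F2/F3 are greedy maximal, not maximum; dynamic F2 additionally drifts
  from the static greedy as edits accumulate. Both gaps are measured, not
  bounded, by the harness.
* Enumeration is designed for small motifs (≲ 4 edges in dense hosts);
  the exhaustive canonical form caps patterns at ~8–10 nodes.
* Undirected simple graphs only: no directed, weighted, or multi-edges,
  and no timestamped temporal semantics beyond the ordered script.
* The residual-degree greedy does not scale to motifs with ~10⁶
  embeddings; use the initial-degree variant there (the harness does).
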