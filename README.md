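# dynamotif

Incremental motif counting in dynamic biological networks.

Biological networks — protein interaction maps, gene co-expression
networks, regulatory circuits — change their topology over time. A network
*motif* is a small subgraph that recurs in such a network, and its
frequency is a basic descriptor of local network structure. Counting
motifs requires solving subgraph-isomorphism-flavored problems, so
recounting from scratch after every topological change is infeasible for
large or fast-evolving networks. `dynamotif` maintains motif counts
*incrementally*: it computes them once on the initial network and then
updates them locally after each edge insertion or deletion.

Two frequency measures are maintained dynamically for a motif P in a host
graph G:

* **F1** — the number of embeddings of P (subgraphs of G isomorphic to P,
  identified by their edge sets; overlaps allowed). The dynamic F1 update
  is **exact**: a per-edge index D_e lists every embedding containing edge
  e, so a deletion removes exactly the bucket D_e, and an insertion adds
  exactly the embeddings found by a local search around the new edge
  (within its k-neighborhood, k = motif diameter).
* **F2** — the size of a maximal set of pairwise edge-disjoint embeddings,
  a greedy heuristic for an NP-complete packing problem (maximum
  independent set on the *overlap graph*, which has one node per
  embedding and an edge between embeddings sharing a host edge). The
  dynamic update repairs the packing locally: a deleted member X is
  replaced, if possible, by a former neighbor Y of X whose edges are all
  free; a new embedding joins the packing iff all of its edges are free.

A static **F3** (node-disjoint) counter is also provided. The package
ships everything needed to evaluate the method end to end: ER/WS/BA
random-network generators, degree-preserving shuffle scripts, a paired
gene co-expression network builder (stringent/relaxed two-condition
Pearson rule), and an accuracy harness comparing dynamic counts to static
recounts (`accuracy = 100 · c_dynamic / c_static`).

## Worked example

The 10-edge example network has seven nodes with four triangles, all
meeting at node `a`:

```python
from dynamotif import Graph, count_static, init_state, motif_by_name

g = Graph([("a","b"), ("a","e"), ("b","e"), ("a","f"), ("e","f"),
           ("a","c"), ("a","d"), ("c","d"), ("a","g"), ("d","g")])
res = count_static(g, motif_by_name("triangle"))
print(res.f1, res.f2, res.f3)          # -> 4 2 1

state = init_state(g, motif_by_name("triangle"))
state.apply_deletion("a", "e")         # destroys 2 of the 4 triangles
print(state.f1, state.f2)              # -> 2 1
state.apply_insertion("a", "e")        # both reappear; the packing repairs
print(state.f1, state.f2)              # -> 4 2
```

F1 = 4: the triangles `{ab,ae,be}`, `{ae,af,ef}`, `{ac,ad,cd}`,
`{ad,ag,dg}`. F2 = 2: at most two of them are pairwise edge-disjoint
(e.g. the first and third). F3 = 1: every triangle uses node `a`. Deleting
edge `(a,e)` kills the two triangles containing it and the packing cannot
be repaired (the two survivors share edge `(a,d)`), so F2 drops to 1;
re-inserting the edge restores both counts.

The same operations are available from the shell:

```sh
dynamotif generate --model er --size 1000 --degree 10 --seed 1 --out g.tsv
dynamotif shuffle --graph g.tsv --ops 1000 --seed 2 --out ops.tsv
dynamotif count-dynamic --graph g.tsv --motif triangle --script ops.tsv \
    --report report.json --checkpoint-every 100
dynamotif evaluate --model er,ws,ba --size 1000 --degree 10 --ops 1000 \
    --checkpoint 1000 --seeds 1..5 --out eval.json
```

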