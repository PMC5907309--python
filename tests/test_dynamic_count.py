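"""Incremental F1/F2 maintenance: worked examples, exactness, repair policy."""

import random

import pytest

from dynamotif import (DELETE, INSERT, DynamicState, EditOp, EditScript, Graph,
                       ScriptConsistencyError, enumerate_embeddings, init_state,
                       motif_by_name)
from dynamotif.netgen import GeneratorConfig, generate, shuffle_script

from conftest import EXAMPLE_TRIANGLES, brute_force_max_disjoint


@pytest.fixture
def tri_state(example_net):
    return init_state(example_net, motif_by_name("triangle"))


class TestInit:
    def test_worked_example(self, tri_state):
        assert (tri_state.f1, tri_state.f2) == (4, 2)
        assert tri_state.embedding_sets() == set(EXAMPLE_TRIANGLES)
        tri_state.check_invariants()

    def test_empty_graph(self):
        st = init_state(Graph(), motif_by_name("triangle"))
        assert (st.f1, st.f2) == (0, 0)

    def test_k4(self, k4):
        st = init_state(k4, motif_by_name("triangle"))
        assert (st.f1, st.f2) == (4, 1)

    def test_index_matches_store(self, tri_state):
        for e, bucket in tri_state.index.items():
            for eid in bucket:
                assert e in tri_state.embeddings[eid]
        n_slots = sum(len(b) for b in tri_state.index.values())
        assert n_slots == 3 * tri_state.f1  # each triangle in 3 buckets


class TestDeletion:
    def test_delete_shared_edge_no_replacement(self, tri_state):
        """Deleting (a,e) kills S1 and S2; S1's only neighbor dies with it."""
        tri_state.apply_deletion("a", "e")
        assert (tri_state.f1, tri_state.f2) == (2, 1)
        tri_state.check_invariants()
        # residual optimum is also 1: S3 and S4 share (a,d)
        assert brute_force_max_disjoint(tri_state.embedding_sets()) == 1

    def test_delete_with_replacement(self, example_net):
        """Deleting (b,e) kills member S1, but surviving S2 takes its place."""
        st = init_state(example_net, motif_by_name("triangle"))
        members_before = {frozenset(st.embeddings[i]) for i in st.f2_members}
        assert EXAMPLE_TRIANGLES[0] in members_before  # S1 is a member
        st.apply_deletion("b", "e")
        assert (st.f1, st.f2) == (3, 2)
        members_after = {frozenset(st.embeddings[i]) for i in st.f2_members}
        assert EXAMPLE_TRIANGLES[1] in members_after  # S2 replaced S1
        st.check_invariants()
        assert brute_force_max_disjoint(st.embedding_sets()) == 2

    def test_delete_edge_outside_embeddings(self, example_net):
        example_net.add_edge("g", "h")  # pendant edge, in no triangle
        st = init_state(example_net, motif_by_name("triangle"))
        f1, f2 = st.f1, st.f2
        st.apply_deletion("g", "h")
        assert (st.f1, st.f2) == (f1, f2)
        st.check_invariants()

    def test_delete_missing_edge_raises(self, tri_state):
        with pytest.raises(ScriptConsistencyError):
            tri_state.apply_deletion("b", "f")


class TestInsertion:
    def test_insert_creating_blocked_embeddings(self, tri_state):
        """(c,g) creates two triangles, both touching edges owned by S3."""
        tri_state.apply_insertion("c", "g")
        assert (tri_state.f1, tri_state.f2) == (6, 2)
        tri_state.check_invariants()
        # the local rule is optimal here too
        assert brute_force_max_disjoint(tri_state.embedding_sets()) == 2

    def test_insert_between_fresh_nodes(self, tri_state):
        tri_state.apply_insertion("new1", "new2")
        assert (tri_state.f1, tri_state.f2) == (4, 2)
        tri_state.check_invariants()

    def test_insert_joining_two_paths(self):
        """Two disjoint edges joined by (b,c): two 2-paths appear, one packs."""
        g = Graph([("a", "b"), ("c", "d")])
        st = init_state(g, motif_by_name("path2"))
        assert (st.f1, st.f2) == (0, 0)
        st.apply_insertion("b", "c")
        assert (st.f1, st.f2) == (2, 1)
        st.check_invariants()
        assert brute_force_max_disjoint(st.embedding_sets()) == 1

    def test_insert_existing_edge_raises(self, tri_state):
        with pytest.raises(ScriptConsistencyError):
            tri_state.apply_insertion("a", "b")


class TestScripts:
    def test_empty_script(self, tri_state):
        assert tri_state.apply_script(EditScript()) == []
        assert (tri_state.f1, tri_state.f2) == (4, 2)

    def test_delete_then_reinsert_restores_counts(self, tri_state):
        tl = tri_state.apply_script(EditScript([
            EditOp(DELETE, "a", "e"), EditOp(INSERT, "a", "e")]))
        assert len(tl) == 2
        assert (tri_state.f1, tri_state.f2) == (4, 2)
        assert tri_state.embedding_sets() == set(EXAMPLE_TRIANGLES)

    def test_timeline_length_contract(self):
        g = generate(GeneratorConfig("ER", 30, 4, seed=0))
        script = shuffle_script(g, 100, seed=1)
        st = init_state(g.copy(), motif_by_name("path2"))
        tl = st.apply_script(script)
        assert len(tl) == 100
        assert [t[0] for t in tl] == list(range(100))

    def test_error_annotated_with_step(self, example_net):
        st = init_state(example_net, motif_by_name("triangle"))
        script = EditScript([EditOp(DELETE, "a", "e"), EditOp(DELETE, "a", "e")])
        with pytest.raises(ScriptConsistencyError, match="op 1"):
            st.apply_script(script)


class TestExactnessAndBounds:
    @pytest.mark.parametrize("motif", ["path2", "path3", "triangle", "star3"])
    @pytest.mark.parametrize("seed", range(4))
    def test_store_equals_static_after_scripts(self, motif, seed):
        """The dynamic store must equal fresh enumeration — F1 is exact."""
        g = generate(GeneratorConfig("ER", 40, 5, seed=seed))
        script = shuffle_script(g, 120, seed=seed + 50)
        st = init_state(g.copy(), motif_by_name(motif))
        st.apply_script(script)
        st.check_invariants()
        static = enumerate_embeddings(st.graph, motif_by_name(motif))
        assert st.f1 == len(static)
        assert st.embedding_sets() == {e.edges for e in static}

    @pytest.mark.parametrize("motif", ["path2", "triangle"])
    @pytest.mark.parametrize("seed", range(3))
    def test_f2_valid_and_bounded_at_every_step(self, motif, seed):
        """Members stay disjoint and below the exact optimum throughout."""
        g = generate(GeneratorConfig("ER", 10, 3, seed=seed))
        script = shuffle_script(g, 40, seed=seed + 7)
        st = init_state(g.copy(), motif_by_name(motif))
        for op in script:
            st.apply_op(op)
            st.check_invariants()
            sets = list(st.embedding_sets())
            if len(sets) <= 18:
                assert st.f2 <= brute_force_max_disjoint(sets)

    def test_seeded_random_mode_reproducible(self, example_net):
        runs = []
        for _ in range(2):
            st = init_state(example_net.copy(), motif_by_name("triangle"),
                            rng=random.Random(11))
            st.apply_script(EditScript([
                EditOp(DELETE, "b", "e"), EditOp(INSERT, "c", "g"),
                EditOp(DELETE, "a", "d")]))
            runs.append((st.f1, st.f2, frozenset(st.f2_members)))
        assert runs[0] == runs[1]
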