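"""Co-expression network construction and pathway diff scripts."""

import numpy as np
import pandas as pd
import pytest

from dynamotif import (Graph, build_coexpression, diff_to_script,
                       pearson_matrix, synthetic_expression)
from dynamotif.coexpress import read_expression, write_expression
from dynamotif.netgen import GeneratorConfig, generate


def vectors_with_correlation(rho: float, n: int = 10, seed: int = 0):
    """Two vectors whose sample Pearson correlation is exactly ``rho``."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonalize against x
    z /= z.std()
    y = rho * x + np.sqrt(1 - rho ** 2) * z
    assert abs(np.corrcoef(x, y)[0, 1] - rho) < 1e-12
    return x, y


def expr_with_pair_correlation(rho: float, seed: int = 0) -> pd.DataFrame:
    x, y = vectors_with_correlation(rho, seed=seed)
    return pd.DataFrame([x, y], index=["u", "v"],
                        columns=[f"s{i}" for i in range(len(x))])


class TestPearson:
    def test_self_correlation_is_one(self):
        df = synthetic_expression(n_genes=5, n_samples=8, seed=1)
        corr = pearson_matrix(df)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_perfect_linear_relation(self):
        df = pd.DataFrame([[1, 2, 3], [2, 4, 6]], index=["u", "v"])
        assert pearson_matrix(df).loc["u", "v"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        df = pd.DataFrame([[1, 2, 3], [3, 2, 1]], index=["u", "v"])
        assert pearson_matrix(df).loc["u", "v"] == pytest.approx(-1.0)

    def test_symmetric_and_bounded(self):
        df = synthetic_expression(n_genes=12, n_samples=9, seed=2)
        corr = pearson_matrix(df).to_numpy()
        assert np.allclose(corr, corr.T)
        assert (corr >= -1).all() and (corr <= 1).all()

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame([[1, 2], [2, 1]], index=["u", "v"])
        with pytest.raises(ValueError, match="3 samples"):
            pearson_matrix(df)

    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame([[1, 2, 3], [4, 5, 6]], index=["u", "u"])
        with pytest.raises(ValueError, match="duplicate"):
            pearson_matrix(df)


class TestTwoConditionRule:
    """Truth table of the stringent/relaxed edge rule (strict comparisons)."""

    def test_stringent_primary_alone_suffices(self):
        primary = expr_with_pair_correlation(0.97)
        secondary = expr_with_pair_correlation(0.10, seed=5)
        net = build_coexpression(primary, secondary)
        assert net.has_edge("u", "v")

    def test_relaxed_primary_with_stringent_secondary(self):
        primary = expr_with_pair_correlation(0.80)
        secondary = expr_with_pair_correlation(0.96, seed=5)
        net = build_coexpression(primary, secondary)
        assert net.has_edge("u", "v")

    def test_below_relaxed_primary_never_edges(self):
        primary = expr_with_pair_correlation(0.70)
        secondary = expr_with_pair_correlation(0.99, seed=5)
        net = build_coexpression(primary, secondary)
        assert not net.has_edge("u", "v")

    def test_secondary_equal_to_primary_reduces_to_stringent(self):
        df = synthetic_expression(n_genes=30, n_samples=12, n_modules=5,
                                  noise_sd=0.25, seed=3)
        both = build_coexpression(df, df)
        corr = pearson_matrix(df)
        expected = {
            tuple(sorted((u, v)))
            for i, u in enumerate(df.index) for v in df.index[i + 1:]
            if corr.loc[u, v] > 0.95
        }
        assert both.edge_set() == expected

    def test_negative_correlations_make_no_edges(self):
        primary = expr_with_pair_correlation(-0.99)
        secondary = expr_with_pair_correlation(-0.99, seed=5)
        assert build_coexpression(primary, secondary).n_edges == 0
        # unless thresholds are applied to |r|
        assert build_coexpression(primary, secondary,
                                  absolute=True).has_edge("u", "v")

    def test_threshold_validation(self):
        df = expr_with_pair_correlation(0.5)
        with pytest.raises(ValueError):
            build_coexpression(df, df, stringent=1.5)
        with pytest.raises(ValueError):
            build_coexpression(df, df, stringent=0.8, relaxed=0.9)

    def test_zero_variance_and_unshared_genes_excluded_by_default(self):
        primary = expr_with_pair_correlation(0.99)
        primary.loc["flat"] = 1.0  # zero variance
        primary.loc["only_primary"] = primary.loc["u"] * 2 + 0.5
        secondary = expr_with_pair_correlation(0.99, seed=5)
        net = build_coexpression(primary, secondary)
        assert not net.has_node("flat")
        assert not net.has_node("only_primary")
        net2 = build_coexpression(primary, secondary,
                                  unshared_genes="stringent-only")
        assert net2.has_edge("u", "only_primary")  # perfectly correlated


class TestDiffToScript:
    def test_identical_graphs_empty_script(self, example_net):
        assert len(diff_to_script(example_net, example_net.copy(), seed=0)) == 0

    def test_single_edge_swap(self):
        start = Graph([("a", "b")], nodes=["c"])
        final = Graph([("b", "c")], nodes=["a"])
        script = diff_to_script(start, final, seed=0)
        assert len(script) == 2
        assert {(op.kind, op.edge) for op in script} == {
            ("delete", ("a", "b")), ("insert", ("b", "c"))}

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_on_random_pairs(self, seed):
        start = generate(GeneratorConfig("ER", 40, 4, seed=seed))
        final = generate(GeneratorConfig("ER", 40, 4, seed=seed + 100))
        for n in final.nodes():
            start.add_node(n)
        script = diff_to_script(start, final, seed=seed)
        result = script.apply(start.copy())
        assert result.edge_set() == final.edge_set()

    def test_order_is_seeded_random(self):
        start = generate(GeneratorConfig("ER", 30, 4, seed=0))
        final = generate(GeneratorConfig("ER", 30, 4, seed=1))
        s1 = diff_to_script(start, final, seed=1)
        s2 = diff_to_script(start, final, seed=1)
        s3 = diff_to_script(start, final, seed=2)
        assert [(o.kind, o.edge) for o in s1] == [(o.kind, o.edge) for o in s2]
        assert {(o.kind, o.edge) for o in s1} == {(o.kind, o.edge) for o in s3}


class TestSyntheticExpression:
    def test_module_structure_drives_correlation(self):
        df = synthetic_expression(n_genes=40, n_samples=15, n_modules=4,
                                  noise_sd=0.15, seed=7)
        corr = pearson_matrix(df).to_numpy()
        same = [corr[i, j] for i in range(40) for j in range(i + 1, 40)
                if i % 4 == j % 4]
        diff = [corr[i, j] for i in range(40) for j in range(i + 1, 40)
                if i % 4 != j % 4]
        assert np.mean(same) > 0.9
        assert abs(np.mean(diff)) < 0.5

    def test_round_trip_io(self, tmp_path):
        df = synthetic_expression(n_genes=6, n_samples=5, seed=0)
        p = tmp_path / "expr.tsv"
        write_expression(df, p)
        back = read_expression(p)
        assert np.allclose(back.to_numpy(), df.to_numpy())
        assert list(back.index) == list(df.index)

    def test_workflow_end_to_end(self):
        """Synthetic matrices -> paired networks -> edit script -> final net."""
        primary = synthetic_expression(n_genes=30, n_samples=12, n_modules=5,
                                       noise_sd=0.12, seed=11)
        secondary = synthetic_expression(n_genes=30, n_samples=12, n_modules=5,
                                         noise_sd=0.30, seed=12)
        net_a = build_coexpression(primary, secondary)
        net_b = build_coexpression(secondary, primary)
        script = diff_to_script(net_a, net_b, seed=3)
        for n in net_b.nodes():
            net_a.add_node(n)
        assert script.apply(net_a.copy()).edge_set() == net_b.edge_set()
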