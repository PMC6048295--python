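"""RPKM/ddCt unit behaviour, threshold flags, responder sets, and the PCC
network with its hub rule."""

import numpy as np
import pandas as pd
import pytest

from mybkit.expression_network import (
    build_network,
    ddct,
    expression_groups,
    find_hubs,
    pcc,
    responder_sets,
    rpkm,
    venn_counts,
)
from mybkit.io_formats import ExpressionMatrix
from mybkit.synthetic_data import (
    ExprSimConfig,
    simulate_expression,
    true_module_edges,
)


def _mat(data, genes, samples):
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples))


class TestRpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s": [1000.0]}, index=["g"])
        out = rpkm(counts, pd.Series({"g": 1000}), pd.Series({"s": 1e6}))
        assert out.values.loc["g", "s"] == pytest.approx(1000.0)

    def test_zero_count_zero_rpkm(self):
        counts = pd.DataFrame({"s": [0.0]}, index=["g"])
        out = rpkm(counts, pd.Series({"g": 500}), pd.Series({"s": 2e6}))
        assert out.values.loc["g", "s"] == 0.0

    def test_depth_scale_invariance(self):
        counts = pd.DataFrame({"s": [100.0, 300.0]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000, "g2": 2500})
        a = rpkm(counts, lengths, pd.Series({"s": 1e6}))
        b = rpkm(counts * 2, lengths, pd.Series({"s": 2e6}))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_linearity_in_counts(self):
        counts = pd.DataFrame({"s": [100.0]}, index=["g"])
        lengths = pd.Series({"g": 1000})
        depth = pd.Series({"s": 1e6})
        a = rpkm(counts, lengths, depth)
        b = rpkm(counts * 3, lengths, depth)
        assert b.values.loc["g", "s"] == pytest.approx(3 * a.values.loc["g", "s"])

    def test_bad_length_rejected(self):
        counts = pd.DataFrame({"s": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            rpkm(counts, pd.Series({"g": 0}), pd.Series({"s": 1e6}))


class TestExpressionGroups:
    def test_constant_high_row_flags(self):
        m = _mat([[50.0] * 4, [5.0] * 4], ["hi", "mid"], list("abcd"))
        flags = expression_groups(m)
        assert flags.loc["hi", "high_any"] and not flags.loc["hi", "low_most"]
        assert not flags.loc["mid", "high_any"]

    def test_low_in_three_of_four_stages(self):
        m = _mat([[0.5, 0.5, 0.5, 2.0], [0.5, 0.5, 2.0, 2.0]],
                 ["low3", "low2"], list("abcd"))
        flags = expression_groups(m)
        assert flags.loc["low3", "low_most"]
        assert not flags.loc["low2", "low_most"]  # exactly two stages is not enough

    def test_four_archetypes_clustered_to_truth(self):
        """Four planted profile shapes at low noise land in four clusters
        matching the truth partition (ARI = 1)."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        shapes = {
            0: np.array([1.0, 2.0, 4.0, 8.0]),
            1: np.array([8.0, 4.0, 2.0, 1.0]),
            2: np.array([1.0, 8.0, 8.0, 1.0]),
            3: np.array([8.0, 1.0, 1.0, 8.0]),
        }
        rows, truth = [], []
        for shape_id, base in shapes.items():
            for _ in range(5):
                rows.append(base * np.exp(rng.normal(scale=0.02, size=4)))
                truth.append(shape_id)
        m = _mat(rows, [f"g{i}" for i in range(20)], list("abcd"))
        flags = expression_groups(m)
        labels = flags["group"].tolist()
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)


class TestDdct:
    def _table(self):
        rows = []
        for sample, ref_ct, target_ct in [("t0", 20, 24), ("t1", 20, 23)]:
            for rep, jitter in ((1, 0.0), (2, 0.2), (3, -0.2)):
                rows.append(("TIP41", sample, rep, ref_ct + jitter))
                rows.append(("gA", sample, rep, target_ct + jitter))
        return pd.DataFrame(
            rows, columns=["gene_id", "sample_id", "replicate", "ct"]
        )

    def test_calibrator_fold_exactly_one(self):
        res = ddct(self._table(), "TIP41", "t0")
        cal = res[(res["sample_id"] == "t0") & (res["gene_id"] == "gA")]
        assert cal["fold_change"].iloc[0] == 1.0

    def test_ddct_minus_one_doubles(self):
        res = ddct(self._table(), "TIP41", "t0")
        t1 = res[(res["sample_id"] == "t1") & (res["gene_id"] == "gA")]
        assert t1["delta_delta_ct"].iloc[0] == pytest.approx(-1.0)
        assert t1["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_missing_reference_sample_named(self):
        table = self._table()
        table = table[~((table["gene_id"] == "TIP41") & (table["sample_id"] == "t1"))]
        with pytest.raises(ValueError, match="t1"):
            ddct(table, "TIP41", "t0")

    def test_log2_fold_additive_over_ddct(self):
        res = ddct(self._table(), "TIP41", "t0")
        for _, r in res.iterrows():
            assert np.log2(r["fold_change"]) == pytest.approx(-r["delta_delta_ct"])


class TestResponders:
    def test_up_call_from_any_timepoint(self):
        folds = {"cold": pd.DataFrame({"t1": [1.1], "t3": [2.5]}, index=["g"])}
        (rs,) = responder_sets(folds)
        assert rs.up == {"g"} and rs.down == set()

    def test_down_uses_reciprocal_bound(self):
        folds = {"salt": pd.DataFrame({"t1": [0.6], "t3": [0.4]}, index=["g"])}
        (rs,) = responder_sets(folds)
        assert rs.down == {"g"}

    def test_venn_partitions_the_union(self):
        sets = {"cold": {"a", "b", "c"}, "drought": {"b", "c", "d"},
                "salt": {"c", "e"}}
        table = venn_counts(sets)
        assert len(table) == 7
        assert table["count"].sum() == len(set.union(*sets.values()))

    def test_planted_responders_recovered_exactly(self):
        cfg = ExprSimConfig(responder_fraction=0.3, log2fc_effect=3.0,
                            noise_sd=0.0, within_module_rho=0.0,
                            n_modules=0, module_size=0, seed=11)
        mat0, truth = simulate_expression(
            ExprSimConfig(**{**vars(cfg), "log2fc_effect": 0.0})
        )
        mat1, _ = simulate_expression(cfg)
        # fold change of each gene relative to the same-seed null simulation
        folds = {"treat": (mat1.values / mat0.values)}
        (rs,) = responder_sets(folds)
        want = set(truth[truth["responder"]]["gene_id"])
        assert rs.up == want and rs.down == set()


class TestPcc:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pcc(x, 2 * x + 1) == pytest.approx(1.0)
        assert pcc(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self, rng):
        for _ in range(10):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            direct = ((x - x.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum())
                * np.sqrt(((y - y.mean()) ** 2).sum())
            )
            assert pcc(x, y) == pytest.approx(direct, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNetwork:
    def test_tight_module_forms_clique_without_cross_edges(self):
        cfg = ExprSimConfig(within_module_rho=1.0, noise_sd=1e-6,
                            n_modules=2, module_size=5, n_genes=14, seed=3)
        mat, truth = simulate_expression(cfg)
        net = build_network(mat)
        got = {frozenset(e[:2]) for e in net.edges}
        want = true_module_edges(truth)
        assert want <= got
        cross = {
            e for e in got
            if len({truth.set_index("gene_id").loc[g, "module"] for g in e}) > 1
        }
        assert not cross

    def test_edge_recovery_f1_at_published_cutoff(self):
        """Pooled over replicate datasets at the study conditions
        (rho=0.95, noise 0.1, 12 samples), edge F1 >= 0.9 at cutoff 0.85."""
        tp = fp = fn = 0
        for seed in range(5):
            mat, truth = simulate_expression(ExprSimConfig(seed=seed))
            net = build_network(mat, cutoff=0.85)
            got = {frozenset(e[:2]) for e in net.edges}
            want = true_module_edges(truth)
            tp += len(got & want)
            fp += len(got - want)
            fn += len(want - got)
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.9

    def test_hub_rule_strictly_greater_than_k(self):
        import networkx as nx

        from mybkit.expression_network import CoexpressionNetwork

        g = nx.Graph()
        g.add_edges_from(("hub13", f"x{i}") for i in range(13))
        g.add_edges_from(("deg12", f"y{i}") for i in range(12))
        net = CoexpressionNetwork(g, cutoff=0.85)
        assert find_hubs(net, 12) == {"hub13"}

    def test_impossible_cutoff_empty_edges(self):
        mat, _ = simulate_expression(ExprSimConfig(seed=1))
        net = build_network(mat, cutoff=1.01)
        assert net.graph.number_of_edges() == 0

    def test_zero_variance_gene_dropped_with_warning(self):
        df = pd.DataFrame(
            {"s1": [1.0, 5.0, 1.0], "s2": [2.0, 5.0, 2.0], "s3": [3.0, 5.0, 3.0]},
            index=["a", "flat", "b"],
        )
        with pytest.warns(UserWarning, match="flat"):
            net = build_network(ExpressionMatrix(df), cutoff=0.9)
        assert "flat" not in net.graph.nodes

    def test_edge_relation_symmetric_irreflexive(self):
        mat, _ = simulate_expression(ExprSimConfig(seed=2))
        net = build_network(mat)
        for u, v, _w in net.edges:
            assert u != v
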