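"""Condition graphs, node metrics, conditional enrichment, FFN reduction."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from fmcm import network, simulate
from fmcm.io import ExpressionMatrix, Ontology, PPINetwork
from conftest import paired_matrix


def matrix_from(rows: dict[str, list[float]], condition: str = "case") -> ExpressionMatrix:
    genes = list(rows)
    n = len(next(iter(rows.values())))
    cols = [f"s{i}" for i in range(n)]
    values = pd.DataFrame([rows[g] for g in genes], index=genes, columns=cols, dtype=float)
    cond = pd.Series({c: condition for c in cols})
    # add two dummy other-condition samples so validation passes
    other = "control" if condition == "case" else "case"
    for extra in ("x0", "x1"):
        values[extra] = 0.0
        cond[extra] = other
    return ExpressionMatrix(values, cond)


def ppi_of(*pairs) -> PPINetwork:
    return PPINetwork(frozenset(frozenset(p) for p in pairs))


class TestPearson:
    def test_identical_profiles(self):
        m = matrix_from({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]})
        stats = network.pearson_edge_stats(m, ppi_of(("a", "b")), "case")
        assert stats["r"].iloc[0] == pytest.approx(1.0)
        assert stats["p"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_correlation(self):
        # duplicating the 3-point profile (1,2,3)/(1,2,4) leaves r unchanged
        m3 = matrix_from({"a": [1, 2, 3, 1, 2, 3], "b": [1, 2, 4, 1, 2, 4]})
        stats = network.pearson_edge_stats(m3, ppi_of(("a", "b")), "case")
        assert stats["r"].iloc[0] == pytest.approx(9 / np.sqrt(84), abs=1e-6)

    def test_anticorrelation(self):
        m = matrix_from({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        stats = network.pearson_edge_stats(m, ppi_of(("a", "b")), "case")
        assert stats["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_pair_skipped(self):
        m = matrix_from({"a": [1, 1, 1, 1], "b": [1, 2, 3, 4]})
        stats = network.pearson_edge_stats(m, ppi_of(("a", "b")), "case")
        assert stats.empty

    def test_needs_four_samples(self):
        m = matrix_from({"a": [1, 2, 3], "b": [1, 2, 3]})
        with pytest.raises(ValueError, match=">=4"):
            network.pearson_edge_stats(m, ppi_of(("a", "b")), "case")

    def test_permutation_p_close_to_t_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        y = x + rng.normal(0, 1.0, size=12)
        m = matrix_from({"a": list(x), "b": list(y)})
        t_p = network.pearson_edge_stats(m, ppi_of(("a", "b")), "case")["p"].iloc[0]
        perm_p = network.pearson_edge_stats(
            m, ppi_of(("a", "b")), "case", n_perm=2000, seed=0
        )["p"].iloc[0]
        assert perm_p == pytest.approx(t_p, abs=0.03)


class TestBuildGGIN:
    def stats(self, ps):
        return pd.DataFrame(
            {
                "gene_a": [f"a{i}" for i in range(len(ps))],
                "gene_b": [f"b{i}" for i in range(len(ps))],
                "r": [0.9] * len(ps),
                "p": ps,
            }
        )

    def test_threshold_count(self):
        g = network.build_ggin(self.stats([1e-4, 5e-4, 0.01]), p0=0.001)
        assert g.n_edges == 2

    def test_no_filter_at_one(self):
        g = network.build_ggin(self.stats([1e-4, 5e-4, 0.01]), p0=1.0)
        assert g.n_edges == 3

    def test_empty_graph_allowed(self):
        g = network.build_ggin(self.stats([0.5, 0.9]), p0=0.001)
        assert g.n_edges == 0 and not g.nodes


class TestNodeMetrics:
    def build(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        cg = network.CondGraph("case", g)
        network.node_metrics(cg)
        return cg

    def test_triangle(self):
        cg = self.build([("a", "b"), ("b", "c"), ("a", "c")])
        assert cg.metrics("a") == (2, 1.0)

    def test_star_center(self):
        cg = self.build([("c", "l1"), ("c", "l2"), ("c", "l3")])
        assert cg.metrics("c") == (3, 0.0)
        assert cg.metrics("l1") == (1, 0.0)  # degree<2 -> C defined as 0

    def test_partial_neighborhood(self):
        cg = self.build([("x", "a"), ("x", "b"), ("x", "c"), ("a", "b")])
        k, c = cg.metrics("x")
        assert (k, c) == (3, pytest.approx(1 / 3))

    def test_matches_networkx(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(30, 0.15, seed=4)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(30)})
        g.remove_nodes_from(list(nx.isolates(g)))
        cg = network.CondGraph("case", g)
        network.node_metrics(cg)
        expected = nx.clustering(g)
        for node in g.nodes:
            assert cg.metrics(node)[1] == pytest.approx(expected[node])


class TestConditionalEnrichment:
    def test_hand_hypergeometric(self):
        universe = {f"g{i}" for i in range(10)}
        onto = Ontology({"T": {f"g{i}" for i in range(5)}}, {}, {})
        res = network.conditional_go_enrichment({"g0", "g1", "g2", "g3"}, onto, universe, alpha=0.05)
        row = res.set_index("term").loc["T"]
        assert row["p"] == pytest.approx(5 / 210, abs=1e-9)
        assert row["significant"]

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        onto = Ontology({"T": {"g8", "g9"}}, {}, {})
        res = network.conditional_go_enrichment({"g0", "g1"}, onto, universe, 0.05)
        assert res.set_index("term").loc["T", "p"] == pytest.approx(1.0)

    def test_parent_conditioned_away_by_significant_child(self):
        # child explains all overlap; parent adds nothing beyond it
        child_genes = {f"c{i}" for i in range(5)}
        background = {f"b{i}" for i in range(40)}
        universe = child_genes | background
        onto = Ontology(
            {"child": set(child_genes), "parent": set()},
            {"child": {"parent"}},
            {},
        )
        res = network.conditional_go_enrichment(child_genes, onto, universe, alpha=0.01).set_index("term")
        assert res.loc["child", "significant"]
        assert not res.loc["parent", "significant"]
        # without conditioning the parent would inherit the child's signal
        flat = Ontology({"parent_alone": set(child_genes)}, {}, {})
        res2 = network.conditional_go_enrichment(child_genes, flat, universe, 0.01)
        assert res2["significant"].iloc[0]

    def test_selected_outside_universe_rejected(self):
        onto = Ontology({"T": {"g0"}}, {}, {})
        with pytest.raises(ValueError):
            network.conditional_go_enrichment({"zz"}, onto, {"g0"}, 0.05)


class TestFFNReduction:
    def graph(self, edges):
        g = nx.Graph()
        g.add_edges_from(edges)
        cg = network.CondGraph("case", g)
        network.node_metrics(cg)
        return cg

    def onto_two_terms(self):
        return Ontology(
            {"A": {"a1", "a2", "a3"}, "B": {"b1", "b2", "b3"}}, {}, {}
        )

    def test_intra_per_gene_all_inside(self):
        cg = self.graph([("a1", "a2"), ("a2", "a3"), ("a1", "a3")])
        ffn = network.reduce_to_ffn(cg, ["A", "B"], self.onto_two_terms())
        assert ffn.intra_per_gene("A") == pytest.approx(1.0)
        assert ffn.inter_edges == {}

    def test_single_inter_edge(self):
        cg = self.graph([("a1", "a2"), ("a1", "b1"), ("b1", "b2")])
        ffn = network.reduce_to_ffn(cg, ["A", "B"], self.onto_two_terms())
        assert ffn.inter_edges[("A", "B")] == 1

    def test_single_gene_term_has_no_intra(self):
        onto = Ontology({"A": {"a1"}, "B": {"b1", "b2"}}, {}, {})
        cg = self.graph([("a1", "b1"), ("b1", "b2")])
        ffn = network.reduce_to_ffn(cg, ["A", "B"], onto)
        assert ffn.intra_edges["A"] == 0

    def test_shared_gene_counts_intra_only(self):
        onto = Ontology({"A": {"s", "a1"}, "B": {"s", "b1"}}, {}, {})
        cg = self.graph([("s", "a1"), ("s", "b1")])
        ffn = network.reduce_to_ffn(cg, ["A", "B"], onto)
        assert ffn.intra_edges == {"A": 1, "B": 1}
        assert ffn.inter_edges == {}

    def test_partition_conserves_edge_total(self):
        rng = np.random.default_rng(6)
        g = nx.gnp_random_graph(40, 0.12, seed=9)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in range(40)})
        g.remove_nodes_from(list(nx.isolates(g)))
        nodes = sorted(g.nodes)
        half = len(nodes) // 2
        onto = Ontology({"P1": set(nodes[:half]), "P2": set(nodes[half:])}, {}, {})
        cg = network.CondGraph("case", g)
        network.node_metrics(cg)
        ffn = network.reduce_to_ffn(cg, ["P1", "P2"], onto)
        total = sum(ffn.intra_edges.values()) + sum(ffn.inter_edges.values())
        assert total == g.number_of_edges()


class TestConditionContrast:
    def test_ggin_edges_subset_of_ppi_and_case_denser(self):
        # all modules dysregulated upward: co-expression denser in the case arm
        mods = tuple(
            simulate.ModuleSpec(t, t, size=20, direction="up")
            for t in ("M1", "M2", "M3")
        )
        cfg = simulate.ScenarioConfig(
            n_genes=200, n_subjects=16, modules=mods,
            n_drugs=4, instances_per_drug=1, n_reverse=1, n_mimic=1, seed=3,
        )
        m, _ = simulate.gen_cohort(cfg)
        ppi, _ = simulate.gen_ppi_and_ontology(cfg)
        graphs = {}
        for cond in ("control", "case"):
            stats = network.pearson_edge_stats(m, ppi, cond)
            graphs[cond] = network.build_ggin(stats, p0=0.001, condition=cond)
        ppi_edges = set(ppi.pairs())
        for cg in graphs.values():
            for u, v in cg.graph.edges:
                assert (min(u, v), max(u, v)) in ppi_edges
        assert graphs["case"].n_edges > graphs["control"].n_edges
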