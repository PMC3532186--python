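from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest
from scipy.stats import spearmanr

from cappic import (
    InteractionNetwork,
    bin_scores,
    build_reference_sets,
    cappic,
    goldberg_roth_score,
    rewire_fraction,
    roc_analysis,
)


def exact_upper_tail(k, N, K, n):
    """Exact rational P(X >= k) for the common-neighbour null."""
    num = sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    )
    return Fraction(num, comb(N, n))


class TestReferenceSets:
    def test_all_high_evidence(self, planted):
        net, _ = planted
        inst = rewire_fraction(net, 0.03, seed=1)
        pos, neg = build_reference_sets(inst, net.evidence_map())
        assert pos == inst.surviving_original_edges()
        assert neg == inst.rewired_edges
        assert not pos & neg

    def test_destroyed_edges_excluded(self, planted):
        net, _ = planted
        inst = rewire_fraction(net, 0.03, seed=2)
        pos, _ = build_reference_sets(inst, net.evidence_map())
        assert not pos & inst.removed_edges

    def test_no_evidence_errors(self, planted):
        net, _ = planted
        inst = rewire_fraction(net, 0.03, seed=1)
        evidence = {e: 1 for e in net.edges}
        with pytest.raises(ValueError, match="positive"):
            build_reference_sets(inst, evidence)


class TestRocAnalysis:
    def test_oracle_scorer_auc_one(self, planted):
        net, _ = planted
        oracle = lambda network, inst: {
            e: (0.0 if e in inst.rewired_edges else 1.0)
            for e in network.edges
        }
        roc = roc_analysis(net, scorer=oracle, n_runs=3, seed=0)
        assert roc.mean_auc == pytest.approx(1.0, abs=1e-9)

    def test_anti_oracle_auc_zero(self, planted):
        net, _ = planted
        anti = lambda network, inst: {
            e: (1.0 if e in inst.rewired_edges else 0.0)
            for e in network.edges
        }
        roc = roc_analysis(net, scorer=anti, n_runs=3, seed=0)
        # the terminal jump of the curve costs at most half a grid cell
        assert roc.mean_auc <= 0.005 + 1e-9

    def test_constant_scorer_auc_half(self, planted):
        net, _ = planted
        roc = roc_analysis(net, scorer="constant", n_runs=3, seed=0)
        assert roc.mean_auc == pytest.approx(0.5, abs=1e-9)

    def test_curve_invariants(self, planted):
        net, _ = planted
        roc = roc_analysis(net, scorer="goldberg_roth", n_runs=5, seed=0)
        assert np.all(np.diff(roc.mean_tpr) >= -1e-12)
        assert roc.mean_auc == pytest.approx(
            float(np.trapezoid(roc.mean_tpr, roc.fpr_grid)), abs=1e-9
        )
        assert np.all(roc.stderr_tpr >= 0)
        assert roc.n_runs == 5


class TestGoldbergRoth:
    def test_triangle_in_sparse_network(self):
        # degree-2 endpoints with one common neighbour among 6000 genes:
        # P(X>=1) = 1 - C(5998,2)/C(6000,2)
        edges = [("u", "v"), ("u", "w"), ("v", "w")]
        # pad with disconnected edges so the triangle stays deg-2
        edges += [(f"x{i}", f"y{i}") for i in range(3)]
        net = InteractionNetwork.from_edges(edges)
        scores = goldberg_roth_score(net, n_genes=6000)
        p = 1 - Fraction(comb(5998, 2), comb(6000, 2))
        assert scores[("u", "v")] == pytest.approx(
            -np.log10(float(p)), abs=1e-9
        )
        assert scores[("u", "v")] == pytest.approx(3.18, abs=0.01)

    def test_no_common_neighbour_scores_zero(self, path3):
        scores = goldberg_roth_score(path3, n_genes=100)
        assert all(s == 0.0 for s in scores.values())

    def test_k4_matches_enumeration(self):
        net = InteractionNetwork.from_edges(
            [("A", "B"), ("A", "C"), ("A", "D"),
             ("B", "C"), ("B", "D"), ("C", "D")]
        )
        scores = goldberg_roth_score(net, n_genes=50)
        want = exact_upper_tail(2, 50, 3, 3)
        for e in net.edges:
            assert scores[e] == pytest.approx(
                -np.log10(float(want)), abs=1e-9
            )

    def test_matches_exact_enumeration_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            g = nx.gnp_random_graph(8, 0.45, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            net = InteractionNetwork.from_edges(g.edges)
            N = 30
            scores = goldberg_roth_score(net, n_genes=N)
            for u, v in net.edges:
                k = len(net.neighbors(u) & net.neighbors(v))
                if k == 0:
                    assert scores[(u, v)] == 0.0
                    continue
                want = exact_upper_tail(k, N, net.degree(u), net.degree(v))
                got = 10.0 ** (-scores[(u, v)])
                assert abs(got - float(want)) < 1e-10

    def test_population_smaller_than_nodes_rejected(self, planted):
        net, _ = planted
        with pytest.raises(ValueError, match="n_genes"):
            goldberg_roth_score(net, n_genes=10)


class TestBinScores:
    def test_arithmetic_example(self):
        edges = [(f"a{i}", f"b{i}") for i in range(10)]
        scores = {e: float(i + 1) for i, e in enumerate(edges)}
        bins = bin_scores(scores, scores, n_bins=5)
        assert [m for _, m in bins] == [1.5, 3.5, 5.5, 7.5, 9.5]

    def test_constant_values_equal_means(self):
        edges = [(f"a{i}", f"b{i}") for i in range(12)]
        scores = {e: float(i) for i, e in enumerate(edges)}
        values = {e: 2.0 for e in edges}
        assert all(m == 2.0 for _, m in bin_scores(scores, values))

    def test_bin_sizes_differ_by_at_most_one(self):
        edges = [(f"a{i}", f"b{i}") for i in range(13)]
        scores = {e: float(i) for i, e in enumerate(edges)}
        values = {e: 1.0 for e in edges}
        bins = bin_scores(scores, values, n_bins=5)
        # 13 = 3+3+3+2+2: remainder goes to the first bins
        assert len(bins) == 5

    def test_mismatched_edge_sets_rejected(self):
        with pytest.raises(ValueError, match="same edges"):
            bin_scores({("a", "b"): 1.0}, {("c", "d"): 1.0})

    def test_planted_indicator_rises_with_confidence(self, planted):
        net, truth = planted
        result = cappic(net, seed=1, inflation_override=1.4)
        values = {
            e: (1.0 if truth[e[0]] == truth[e[1]] else 0.0)
            for e in net.edges
        }
        means = [m for _, m in bin_scores(result.scores, values)]
        assert means[-1] > means[0]


def test_scores_correlate_with_experimental_weight(planted):
    """Stochastic analogue of the reported rank correlation between
    confidence and experimental evidence weight."""
    net, _ = planted
    inst = rewire_fraction(net, 0.03, seed=3)
    result = cappic(inst.network, seed=3, inflation_override=1.4)
    rng = np.random.default_rng(3)
    edges = sorted(inst.network.edges)
    weight = [
        (0.2 if e in inst.rewired_edges else 1.0) + rng.normal(0, 0.05)
        for e in edges
    ]
    rho, _ = spearmanr([result.scores[e] for e in edges], weight)
    assert rho > 0
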