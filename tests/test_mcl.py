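import networkx as nx
import numpy as np
import pytest

import cappic.mcl as mcl_mod
from cappic import (
    InteractionNetwork,
    MclParams,
    build_line_graph,
    cluster_interactions,
    mcl_cluster,
)
from cappic.line_graph import LineGraph


def lg_from_nx(g, labels=None):
    """Wrap an arbitrary graph as a LineGraph for direct clustering."""
    nodes = sorted(g.nodes)
    if labels is None:
        labels = {n: ("n", f"{i:03d}") for i, n in enumerate(nodes)}
    index = {n: i for i, n in enumerate(nodes)}
    links = {}
    for u, v in g.edges:
        i, j = index[u], index[v]
        links[(min(i, j), max(i, j))] = "shared"
    return LineGraph(
        nodes=[labels[n] for n in nodes],
        links=links,
        link_weight={k: 1.0 for k in links},
    )


def cluster_sets(clustering, lg=None):
    return {frozenset(c) for c in clustering.clusters}


class TestParams:
    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError, match="inflation"):
            MclParams(inflation=1.0)
        with pytest.raises(ValueError, match="inflation"):
            MclParams(inflation=0.5)

    def test_defaults_mirror_canonical_tool(self):
        p = MclParams()
        assert p.expansion == 2
        assert p.self_loop_weight == 1.0


class TestMclCluster:
    def test_two_disjoint_triangles_two_clusters(self):
        g = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
        cl = mcl_cluster(lg_from_nx(g), MclParams(inflation=2.0))
        assert cl.n_clusters == 2
        assert sorted(cl.sizes()) == [3, 3]

    def test_single_isolated_node(self):
        g = nx.empty_graph(1)
        cl = mcl_cluster(lg_from_nx(g), MclParams(inflation=2.0))
        assert cl.n_clusters == 1
        assert cl.sizes() == [1]

    def test_two_cliques_split_at_bridge(self):
        """Two 5-cliques joined by one link must split into the cliques
        (verified by inspecting the limit matrix attractor structure:
        the bridge carries vanishing flow after inflation)."""
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        labels = {n: ("n", f"{n:03d}") for n in g.nodes}
        cl = mcl_cluster(lg_from_nx(g, labels), MclParams(inflation=2.0))
        assert cl.n_clusters == 2
        expected = {
            frozenset(labels[n] for n in range(5)),
            frozenset(labels[n] for n in range(5, 10)),
        }
        assert cluster_sets(cl) == expected

    def test_partition_is_exact(self):
        g = nx.gnp_random_graph(25, 0.2, seed=3)
        lg = lg_from_nx(g)
        cl = mcl_cluster(lg, MclParams(inflation=1.8))
        all_members = [e for c in cl.clusters for e in c]
        assert len(all_members) == lg.n_nodes  # disjoint + covering
        assert set(all_members) == set(lg.nodes)
        assert all(len(c) > 0 for c in cl.clusters)
        assert all(
            e in cl.clusters[i] for e, i in cl.assignment.items()
        )

    def test_determinism(self):
        g = nx.gnp_random_graph(20, 0.25, seed=11)
        lg = lg_from_nx(g)
        a = mcl_cluster(lg, MclParams(inflation=1.7))
        b = mcl_cluster(lg, MclParams(inflation=1.7))
        assert a.clusters == b.clusters

    def test_permutation_invariance(self):
        g = nx.gnp_random_graph(18, 0.25, seed=5)
        lg = lg_from_nx(g)
        rng = np.random.default_rng(0)
        perm = rng.permutation(sorted(g.nodes))
        g2 = nx.relabel_nodes(g, dict(zip(sorted(g.nodes), perm)))
        # same identifier for the same original node
        labels = {n: ("n", f"{n:03d}") for n in g.nodes}
        labels2 = {
            new: labels[old] for old, new in zip(sorted(g.nodes), perm)
        }
        cl1 = mcl_cluster(lg_from_nx(g, labels), MclParams(inflation=1.8))
        cl2 = mcl_cluster(lg_from_nx(g2, labels2), MclParams(inflation=1.8))
        assert cluster_sets(cl1) == cluster_sets(cl2)

    def test_disconnected_components_never_share_cluster(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            g1 = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1e6)))
            g2 = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1e6)))
            g = nx.disjoint_union(g1, g2)
            lg = lg_from_nx(g)
            cl = mcl_cluster(lg, MclParams(inflation=1.5))
            comp_of = {}
            for ci, comp in enumerate(nx.connected_components(g)):
                for n in comp:
                    comp_of[lg.nodes[sorted(g.nodes).index(n)]] = ci
            for cluster in cl.clusters:
                assert len({comp_of[e] for e in cluster}) == 1

    def test_columns_stay_stochastic_during_iteration(self, monkeypatch):
        checked = []
        orig = mcl_mod._column_normalize

        def checking(m):
            out = orig(m)
            cols = out.sum(axis=0)
            checked.append(np.abs(cols[cols > 0] - 1.0).max())
            return out

        monkeypatch.setattr(mcl_mod, "_column_normalize", checking)
        g = nx.gnp_random_graph(15, 0.3, seed=9)
        mcl_cluster(lg_from_nx(g), MclParams(inflation=1.6))
        assert checked and max(checked) <= 1e-9

    def test_higher_inflation_never_fewer_clusters(self):
        rng = np.random.default_rng(21)
        for _ in range(8):
            g = nx.gnp_random_graph(14, 0.3, seed=int(rng.integers(1e6)))
            lg = lg_from_nx(g)
            counts = [
                mcl_cluster(lg, MclParams(inflation=i)).n_clusters
                for i in (1.3, 1.8, 2.5, 4.0)
            ]
            assert counts == sorted(counts)


class TestClusterInteractions:
    def test_triangle_single_cluster(self, triangle):
        for inflation in (1.2, 1.6, 2.0):
            cl = cluster_interactions(triangle, inflation)
            assert cl.n_clusters == 1
            assert cl.clusters[0] == triangle.edges

    def test_two_disjoint_triangles(self, two_triangles):
        cl = cluster_interactions(two_triangles, 1.5)
        assert cl.n_clusters == 2
        assert cluster_sets(cl) == {
            frozenset({("A", "B"), ("A", "C"), ("B", "C")}),
            frozenset({("X", "Y"), ("X", "Z"), ("Y", "Z")}),
        }

    def test_two_module_toy_splits_into_modules(self):
        # two dense modules sharing the cut protein D: the interactions
        # of each module should end up in different clusters
        net = InteractionNetwork.from_edges(
            [("A", "B"), ("A", "C"), ("B", "C"), ("A", "D"), ("B", "D"),
             ("D", "E"), ("E", "F"), ("E", "G"), ("F", "G"), ("D", "F")]
        )
        cl = cluster_interactions(net, 2.0)
        assert cl.n_clusters >= 2
        mod1 = {("A", "B"), ("A", "C"), ("B", "C")}
        mod2 = {("E", "F"), ("E", "G"), ("F", "G")}
        c1 = {cl.assignment[e] for e in mod1}
        c2 = {cl.assignment[e] for e in mod2}
        assert len(c1) == 1 and len(c2) == 1 and c1 != c2

    def test_every_interaction_assigned_once(self, planted):
        net, _ = planted
        cl = cluster_interactions(net, 1.4)
        assert set(cl.assignment) == net.edges
        assert sum(cl.sizes()) == net.n_edges
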