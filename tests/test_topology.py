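"""Hubs, path lengths, clustering, betweenness — with brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from rxnnet import topology as topo


class TestHubsTotal:
    def test_star_center_is_sole_hub(self):
        g = nx.star_graph(200)  # center 0, 200 leaves
        hubs = topo.find_hubs_total(g, multiplier=100.0)
        assert [m for m, _ in hubs.members] == [0]
        assert hubs.criterion.threshold == pytest.approx(100.0 * 2 * 200 / 201)

    def test_regular_ring_has_no_hubs(self):
        g = nx.cycle_graph(50)
        assert topo.find_hubs_total(g, multiplier=100.0).members == []

    def test_threshold_identity(self, pa_molgraph):
        hubs = topo.find_hubs_total(pa_molgraph, multiplier=100.0)
        assert hubs.criterion.threshold / hubs.criterion.d_avg == pytest.approx(100.0)

    def test_preferential_attachment_hub_regime(self, pa_molgraph):
        """Reuse-dominated growth concentrates a tiny hub fraction."""
        hubs = topo.find_hubs_total(pa_molgraph, multiplier=100.0)
        assert 0.00005 <= hubs.proportion <= 0.005  # 0.005% .. 0.5% of molecules

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            topo.find_hubs_total(nx.Graph())


class TestHubsInDegree:
    def test_dominant_sink_ranked_first(self):
        g = nx.DiGraph()
        for i in range(50):
            g.add_edge(f"r{i}", "P")
        g.add_edge("a", "b")
        hubs = topo.rank_hubs_in_degree(g, multiplier=10.0, top_n=3)
        assert hubs.top_ranked[0][0] == "P"
        assert [m for m, _ in hubs.members] == ["P"]

    def test_ties_break_lexicographically(self):
        g = nx.DiGraph([("x", "B"), ("y", "B"), ("x", "A"), ("y", "A")])
        hubs = topo.rank_hubs_in_degree(g, multiplier=0.5, top_n=4)
        assert hubs.top_ranked[0][0] == "A"
        assert hubs.top_ranked[1][0] == "B"

    def test_ranking_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            g = nx.gnp_random_graph(rng.integers(5, 40), 0.2, seed=int(rng.integers(1 << 30)), directed=True)
            hubs = topo.rank_hubs_in_degree(g, multiplier=0.0, top_n=g.number_of_nodes())
            oracle = sorted(dict(g.in_degree()).items(), key=lambda nd: (-nd[1], str(nd[0])))
            assert hubs.top_ranked == oracle


class TestPathLengths:
    def test_path_graph_hand_enumeration(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        dist = topo.path_length_distribution(g)
        assert dist.exact
        assert dist.histogram == {1: pytest.approx(3 / 6), 2: pytest.approx(2 / 6), 3: pytest.approx(1 / 6)}
        assert dist.mean == pytest.approx(10 / 6)

    def test_complete_graph_all_distance_one(self):
        dist = topo.path_length_distribution(nx.complete_graph(5))
        assert dist.histogram == {1: 1.0}

    def test_directed_mode_respects_orientation(self):
        g = nx.DiGraph([("a", "b"), ("a", "c")])  # fork: b,c mutually unreachable
        directed = topo.path_length_distribution(g, directed=True)
        undirected = topo.path_length_distribution(g, directed=False)
        assert directed.histogram == {1: 1.0}
        assert undirected.histogram == {1: pytest.approx(4 / 6), 2: pytest.approx(2 / 6)}

    def test_sampled_mode_tracks_exact_mean(self, skeleton_5k):
        exact = topo.path_length_distribution(skeleton_5k, exact_threshold=10_000)
        sampled = topo.path_length_distribution(skeleton_5k, n_sources=500, seed=2, exact_threshold=1)
        assert not sampled.exact
        assert abs(sampled.mean - exact.mean) / exact.mean < 0.05


class TestClustering:
    def test_bipartite_graph_is_exactly_zero(self, clean_net):
        prof = topo.clustering(clean_net.graph)
        assert prof.global_coefficient == 0.0

    def test_triangle_graph(self):
        prof = topo.clustering(nx.complete_graph(3))
        assert prof.global_coefficient == pytest.approx(1.0)
        assert prof.local_by_degree == {2: pytest.approx(1.0)}

    def test_matches_brute_force_enumeration(self):
        g = nx.gnp_random_graph(200, 0.05, seed=5)
        prof = topo.clustering(g)
        adj = {v: set(g[v]) for v in g}
        triangles_at = {v: sum(1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]) for v in g}
        triples = sum(len(adj[v]) * (len(adj[v]) - 1) // 2 for v in g)
        assert prof.global_coefficient == pytest.approx(sum(triangles_at.values()) / triples)
        local = nx.clustering(g)
        for k, mean_c in prof.local_by_degree.items():
            vals = [local[v] for v in g if g.degree(v) == k]
            assert mean_c == pytest.approx(np.mean(vals))

    def test_hierarchical_decay_on_preferential_attachment_graph(self, pa_molgraph):
        prof = topo.clustering(pa_molgraph)
        assert -1.5 <= prof.loglog_slope <= -0.5

    def test_jackknife_se_positive_on_clustered_graph(self):
        g = nx.gnp_random_graph(150, 0.08, seed=2)
        prof = topo.clustering(g)
        assert prof.global_se > 0


class TestBetweenness:
    def test_path_middle_node_dominates(self):
        prof = topo.betweenness_by_degree(nx.path_graph(["a", "b", "c"]))
        assert prof.per_node["b"] > prof.per_node["a"] == prof.per_node["c"] == 0.0

    def test_star_center_is_maximal(self):
        prof = topo.betweenness_by_degree(nx.star_graph(20))
        assert prof.per_node[0] == max(prof.per_node.values())

    def test_exact_matches_independent_brandes(self):
        g = nx.gnp_random_graph(120, 0.06, seed=3)
        prof = topo.betweenness_by_degree(g)
        oracle = nx.betweenness_centrality(g, normalized=False)
        for v in g:
            assert prof.per_node[v] == pytest.approx(oracle[v], abs=1e-8)

    def test_pivot_sampling_tracks_exact(self, skeleton_2k):
        exact = topo.betweenness_by_degree(skeleton_2k, exact_threshold=10_000)
        sampled = topo.betweenness_by_degree(skeleton_2k, n_pivots=1500, seed=4, exact_threshold=1)
        nodes = sorted(skeleton_2k.nodes())
        ve = np.array([exact.per_node[v] for v in nodes])
        vs = np.array([sampled.per_node[v] for v in nodes])
        big = ve >= np.percentile(ve[ve > 0], 90)
        rel = np.abs(vs[big] - ve[big]) / ve[big]
        assert rel.mean() < 0.10

    def test_hierarchy_slope_positive_on_preferential_attachment_graph(self, pa_molgraph):
        prof = topo.betweenness_by_degree(pa_molgraph, n_pivots=1000, seed=1)
        assert prof.loglog_slope > 0


class TestRelabelingInvariance:
    def test_degree_profiles_invariant_to_node_names(self):
        g = nx.gnp_random_graph(80, 0.1, seed=9)
        mapping = {v: f"node_{v:03d}" for v in g}
        h = nx.relabel_nodes(g, mapping)
        pg = topo.clustering(g)
        ph = topo.clustering(h)
        assert pg.local_by_degree == ph.local_by_degree
        assert pg.global_coefficient == ph.global_coefficient
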