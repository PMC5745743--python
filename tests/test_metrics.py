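"""Graph statistics against closed forms and exhaustive oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.sparse.csgraph import shortest_path as dense_shortest_path

from netpharm.exceptions import DomainError, FitError
from netpharm.metrics import (
    betweenness_centrality,
    centrality_outliers,
    closeness_centrality,
    clustering_coefficient,
    compute_metrics,
    degree_centrality,
    degree_statistics,
    geodesic_summary,
    mean_clustering,
    path_statistics,
    powerlaw_fit,
    rank_nodes,
    smallworld_compare,
)
from netpharm.synthetic_data import DegreeTable, graph_from_degree_table

from conftest import random_connected_graph


# ---------------------------------------------------------------------------
# independent oracles (exhaustive; test-only)
# ---------------------------------------------------------------------------

def brute_betweenness(graph):
    """Raw betweenness by explicit enumeration of every geodesic."""
    result = {v: 0.0 for v in graph}
    for j, k in itertools.combinations(list(graph), 2):
        try:
            paths = list(nx.all_shortest_paths(graph, j, k))
        except nx.NetworkXNoPath:
            continue
        g_jk = len(paths)
        for v in graph:
            if v in (j, k):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                result[v] += through / g_jk
    return result


def dense_distance_matrix(graph):
    nodes = list(graph)
    adjacency = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    return nodes, dense_shortest_path(adjacency, method="FW", unweighted=True)


def oracle_path_stats(graph):
    _, dist = dense_distance_matrix(graph)
    finite = dist[np.isfinite(dist) & (dist > 0)]
    return finite.mean(), int(finite.max())


def oracle_closeness(graph):
    nodes, dist = dense_distance_matrix(graph)
    out = {}
    for i, v in enumerate(nodes):
        row = dist[i]
        reachable = np.isfinite(row) & (row > 0)
        total = row[reachable].sum()
        out[v] = (reachable.sum() / total) if total > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# degree statistics
# ---------------------------------------------------------------------------

class TestDegreeStatistics:
    def test_complete_graph(self):
        degrees, mean, table, pk = degree_statistics(nx.complete_graph(3))
        assert set(degrees.values()) == {2}
        assert mean == 2.0
        assert table.rows == ((2, 3),)
        assert pk == {2: 1.0}

    def test_study_tripartite_mean_degree(self):
        # 305 nodes / 879 edges: <k> = 5.76 at printed precision
        graph = nx.gnm_random_graph(305, 879, seed=1)
        _, mean, _, _ = degree_statistics(graph)
        assert round(mean, 2) == 5.76

    def test_realized_table_mean_degree(self, table1):
        graph = graph_from_degree_table(table1, seed=2)
        _, mean, _, _ = degree_statistics(graph)
        assert round(mean, 2) == 29.61

    def test_empty_graph_nulls(self):
        degrees, mean, table, pk = degree_statistics(nx.Graph())
        assert degrees == {} and mean is None and table is None and pk == {}

    @given(st.integers(3, 40), st.integers(0, 10 ** 6))
    def test_mean_degree_identity_and_pk_sums_to_one(self, n, seed):
        graph = nx.gnp_random_graph(n, 0.3, seed=seed)
        _, mean, _, pk = degree_statistics(graph)
        assert mean == pytest.approx(2 * graph.number_of_edges() / n, abs=1e-12)
        assert sum(pk.values()) == pytest.approx(1.0, abs=1e-12)


class TestClustering:
    def test_triangle_all_one(self):
        triangle = nx.complete_graph(3)
        assert clustering_coefficient(triangle, 0) == 1.0

    def test_star_center_zero(self):
        star = nx.star_graph(5)
        assert clustering_coefficient(star, 0) == 0.0

    def test_one_edge_among_three_neighbors(self):
        # k=3 with exactly one neighbor edge: C = 2*1/(3*2) = 1/3
        graph = nx.Graph([("x", "a"), ("x", "b"), ("x", "c"), ("a", "b")])
        assert clustering_coefficient(graph, "x") == pytest.approx(1 / 3)

    def test_degree_below_two_is_zero(self):
        graph = nx.path_graph(3)
        assert clustering_coefficient(graph, 0) == 0.0

    def test_unknown_node(self):
        with pytest.raises(LookupError):
            clustering_coefficient(nx.path_graph(3), "missing")

    def test_mean_variants(self):
        # triangle with a pendant: C = (1,1,1/3... ) check both means
        graph = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3)])
        all_mean, k2_mean = mean_clustering(graph)
        values = nx.clustering(graph)
        assert all_mean == pytest.approx(sum(values.values()) / 4)
        assert k2_mean == pytest.approx(
            (values[0] + values[1] + values[2]) / 3)


class TestPathStatistics:
    def test_path_graph(self):
        length, diameter, connected = path_statistics(nx.path_graph(3))
        assert length == pytest.approx(4 / 3)
        assert diameter == 2 and connected

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph(self, n):
        length, diameter, connected = path_statistics(nx.complete_graph(n))
        assert length == 1.0 and diameter == 1 and connected

    def test_disconnected_flagged(self):
        graph = nx.Graph([(0, 1), (2, 3)])
        length, diameter, connected = path_statistics(graph)
        assert not connected
        assert length == 1.0 and diameter == 1  # over connected pairs only

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_floyd_warshall_oracle(self, seed):
        graph = random_connected_graph(50, 0.08, seed)
        length, diameter, _ = path_statistics(graph)
        oracle_length, oracle_diameter = oracle_path_stats(graph)
        assert length == pytest.approx(oracle_length, rel=1e-12)
        assert diameter == oracle_diameter


class TestGeodesicSummary:
    def test_counts_and_pass_through(self):
        # square: two geodesics between opposite corners, one through each side
        square = nx.cycle_graph(4)
        summary = geodesic_summary(square)
        assert summary.sigma[0][2] == 2
        assert summary.g_through(0, 2, 1) == 1
        assert summary.g_through(0, 2, 3) == 1
        assert summary.g_through(0, 1, 2) == 0
        assert summary.distances[0][2] == 2


class TestCentralities:
    def test_degree_centrality_printed_values(self):
        # k=58 and k=57 among 142 nodes: Cd = 0.411 and 0.404 at 3 d.p.
        assert round(58 / 141, 3) == 0.411
        graph = nx.star_graph(141)  # 142 nodes, center degree 141
        cd = degree_centrality(graph)
        assert cd[0] == 1.0
        assert round(58 * cd[1] / 1, 5) == round(58 / 141, 5)

    def test_isolated_node_zero(self):
        graph = nx.Graph()
        graph.add_nodes_from([0, 1, 2])
        graph.add_edge(0, 1)
        assert degree_centrality(graph)[2] == 0.0

    def test_too_small_graph_rejected(self):
        graph = nx.Graph()
        graph.add_node(0)
        with pytest.raises(DomainError):
            degree_centrality(graph)

    def test_star_betweenness(self):
        star = nx.star_graph(5)
        raw = betweenness_centrality(star, normalized=False)
        assert raw[0] == 10.0  # C(5,2) pairs all route through the center
        assert all(raw[leaf] == 0.0 for leaf in range(1, 6))
        norm = betweenness_centrality(star, normalized=True)
        assert norm[0] == 1.0

    def test_tree_leaves_zero(self):
        tree = nx.random_labeled_tree(12, seed=3)
        raw = betweenness_centrality(tree, normalized=False)
        for leaf in (v for v in tree if tree.degree(v) == 1):
            assert raw[leaf] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_betweenness_matches_brute_force(self, seed):
        graph = random_connected_graph(22, 0.18, seed)
        raw = betweenness_centrality(graph, normalized=False)
        oracle = brute_betweenness(graph)
        for v in graph:
            assert raw[v] == pytest.approx(oracle[v], abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_tree_betweenness_sum_identity(self, seed):
        # on a tree each pair (j,k) contributes d_jk - 1 interior nodes
        tree = nx.random_labeled_tree(20, seed=seed)
        raw = betweenness_centrality(tree, normalized=False)
        _, dist = dense_distance_matrix(tree)
        upper = dist[np.triu_indices_from(dist, k=1)]
        assert sum(raw.values()) == pytest.approx((upper - 1).sum(), abs=1e-9)

    def test_closeness_closed_forms(self):
        assert all(v == 1.0 for v in
                   closeness_centrality(nx.complete_graph(5)).values())
        path = nx.path_graph(3)
        cc = closeness_centrality(path)
        assert cc[1] == 1.0
        assert cc[0] == pytest.approx(2 / 3)

    def test_closeness_per_component(self):
        graph = nx.Graph([(0, 1), (2, 3), (3, 4)])
        graph.add_node(5)
        cc = closeness_centrality(graph)
        assert cc[0] == 1.0           # K2 component
        assert cc[3] == 1.0           # middle of the path component
        assert cc[2] == pytest.approx(2 / 3)
        assert cc[5] == 0.0           # singleton

    @pytest.mark.parametrize("seed", range(3))
    def test_closeness_matches_dense_oracle(self, seed):
        graph = random_connected_graph(50, 0.08, seed)
        ours = closeness_centrality(graph)
        oracle = oracle_closeness(graph)
        for v in graph:
            assert ours[v] == pytest.approx(oracle[v], rel=1e-12)


class TestPowerlawFit:
    def test_exact_power_law_recovered(self):
        ks = range(1, 11)
        norm = sum(k ** -2.0 for k in ks)
        pk = {k: k ** -2.0 / norm for k in ks}
        gamma, r_squared = powerlaw_fit(pk)
        assert gamma == pytest.approx(2.0, abs=1e-12)
        assert r_squared == pytest.approx(1.0, abs=1e-12)

    def test_uniform_distribution_gamma_zero(self):
        pk = {k: 0.2 for k in range(1, 6)}
        gamma, r_squared = powerlaw_fit(pk)
        assert gamma == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            powerlaw_fit({1: 0.5, 2: 0.5})

    def test_zero_probability_entries_ignored(self):
        pk = {1: 0.5, 2: 0.25, 3: 0.25, 4: 0.0}
        gamma, _ = powerlaw_fit(pk)
        assert math.isfinite(gamma)


class TestSmallWorld:
    def test_er_graph_sigma_near_one(self):
        graph = random_connected_graph(120, 0.06, seed=5)
        result = smallworld_compare(graph, n_random=20, seed=1)
        assert 0.4 < result["sigma"] < 2.5

    def test_clustered_graph_sigma_above_one(self):
        graph = nx.connected_caveman_graph(12, 6)
        result = smallworld_compare(graph, n_random=20, seed=1)
        assert result["sigma"] > 1.5
        assert result["clustering_ratio"] > 2.0

    def test_replicate_means_stable_across_seeds(self):
        graph = nx.connected_caveman_graph(8, 5)
        a = smallworld_compare(graph, n_random=60, seed=1)
        b = smallworld_compare(graph, n_random=60, seed=2)
        assert a["clustering_random"] == pytest.approx(
            b["clustering_random"], rel=0.15)
        assert a["path_length_random"] == pytest.approx(
            b["path_length_random"], rel=0.15)


class TestRanking:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["node", "k", "Cd", "Cb", "Cc"])

    def test_planted_hubs_first(self):
        rows = [(f"n{i}", 5 + i % 3, 0.1, 0.1, 0.1) for i in range(20)]
        rows += [("eugenol", 106, 0.9, 0.5, 0.6), ("geraniol", 96, 0.8, 0.4, 0.5)]
        ranked = rank_nodes(self.table(rows), by="k", top_n=2)
        assert list(ranked["node"]) == ["eugenol", "geraniol"]

    def test_ties_broken_by_node_id(self):
        rows = [("b", 3, 0, 0, 0), ("a", 3, 0, 0, 0), ("c", 3, 0, 0, 0)]
        ranked = rank_nodes(self.table(rows), by="k")
        assert list(ranked["node"]) == ["a", "b", "c"]

    def test_matches_independent_sort(self, rng):
        rows = [(f"n{i:02d}", int(rng.integers(1, 9)),
                 float(rng.random()), float(rng.random()), float(rng.random()))
                for i in range(30)]
        table = self.table(rows)
        ranked = rank_nodes(table, by="Cb")
        expected = [n for _, n in sorted(
            ((-row[3], row[0]) for row in rows))]
        assert list(ranked["node"]) == expected

    def test_unknown_metric_rejected(self):
        with pytest.raises(DomainError):
            rank_nodes(self.table([("a", 1, 0, 0, 0)]), by="pagerank")


class TestOutliers:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["node", "Cd", "Cb", "Cc"])

    def test_extreme_node_flagged(self, rng):
        rows = [(f"n{i}", 0.3 + rng.normal(0, 0.01), 0.1, 0.4)
                for i in range(30)]
        rows.append(("whale", 0.3, 3.0, 0.4))  # hundreds of MADs out on Cb
        flagged = centrality_outliers(self.table(rows), z_threshold=10.0)
        assert flagged == ["whale"]

    def test_homogeneous_table_no_flags(self):
        rows = [(f"n{i}", 0.5, 0.1, 0.5) for i in range(10)]
        assert centrality_outliers(self.table(rows)) == []

    def test_planted_five_outliers_recovered(self, rng):
        rows = [(f"n{i:03d}", float(0.3 + rng.normal(0, 0.02)),
                 float(0.05 + rng.normal(0, 0.01)),
                 float(0.45 + rng.normal(0, 0.02))) for i in range(95)]
        planted = [("KPCA", 0.45, 0.093, 0.500), ("EGFR", 0.411, 0.069, 0.447),
                   ("PP2BA", 0.42, 0.109, 0.496), ("MAPK1", 0.43, 0.082, 0.496),
                   ("MAPK3", 0.44, 0.082, 0.496)]
        flagged = centrality_outliers(self.table(rows + planted), z_threshold=3.0)
        assert flagged == sorted(p[0] for p in planted)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(DomainError):
            centrality_outliers(self.table([("a", 1, 1, 1), ("b", 1, 1, 1)]))


class TestComputeMetrics:
    def test_assembled_report_consistency(self):
        graph = nx.karate_club_graph()
        report = compute_metrics(graph, smallworld_replicates=5, seed=0)
        assert report.n_nodes == 34 and report.n_edges == 78
        assert report.mean_degree == pytest.approx(2 * 78 / 34)
        assert len(report.per_node) == 34
        # Cd * (N-1) recovers k exactly
        assert all(
            row.Cd * 33 == pytest.approx(row.k, abs=1e-9)
            for row in report.per_node.itertuples())
        assert report.smallworld is not None

    def test_degree_table_realization_full_cycle(self, table1):
        graph = graph_from_degree_table(table1, seed=5)
        report = compute_metrics(graph, include_centralities=False)
        assert report.degree_table.rows == tuple(sorted(table1.rows, reverse=True))
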