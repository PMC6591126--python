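"""Network construction, centralities, topology, and random baselines."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet import network


def brute_force_centralities(g: nx.Graph):
    """Exhaustive shortest-path enumeration oracle for small graphs.

    Enumerates every simple path between every node pair to find all
    geodesics, then computes degree, within-component closeness (1 / mean
    geodesic length), betweenness (per-component normalization), and local
    clustering directly from the definitions.
    """
    out = {}
    comps = list(nx.connected_components(g))
    comp_of = {n: c for c in map(frozenset, comps) for n in c}
    # all geodesics per pair, by exhaustive simple-path enumeration
    geodesics = {}
    for u, v in itertools.combinations(g.nodes, 2):
        if comp_of[u] is not comp_of[v]:
            continue
        paths = list(nx.all_simple_paths(g, u, v))
        shortest = min(map(len, paths))
        geodesics[(u, v)] = [p for p in paths if len(p) == shortest]
    for node in g.nodes:
        comp = comp_of[node]
        n_c = len(comp)
        deg = g.degree[node]
        # closeness
        dists = [
            len(geodesics[tuple(sorted((node, v), key=str))][0]) - 1
            for v in comp
            if v != node
        ]
        close = 1.0 / np.mean(dists) if dists else 0.0
        # betweenness
        btw = 0.0
        for (u, v), paths in geodesics.items():
            if node in (u, v) or comp_of[u] is not comp:
                continue
            btw += sum(node in p for p in paths) / len(paths)
        norm = (n_c - 1) * (n_c - 2) / 2
        btw = btw / norm if norm > 0 else 0.0
        # local clustering
        nbrs = list(g.neighbors(node))
        if deg >= 2:
            links = sum(g.has_edge(a, b) for a, b in itertools.combinations(nbrs, 2))
            clus = 2 * links / (deg * (deg - 1))
        else:
            clus = 0.0
        out[node] = (deg, close, btw, clus)
    return out


class TestBuildNetwork:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["otu_a", "otu_b", "q_value"])

    def test_all_insignificant_gives_empty_graph(self):
        assoc = self._assoc([("a", "b", 1.0), ("b", "c", 0.9)])
        net = network.build_network(assoc, 0.05)
        assert net.number_of_nodes() == 0

    def test_three_significant_pairs(self):
        assoc = self._assoc(
            [("a", "b", 0.01), ("b", "c", 0.01), ("c", "d", 0.01), ("a", "d", 0.9)]
        )
        net = network.build_network(assoc, 0.05)
        assert net.number_of_edges() == 3
        assert net.number_of_nodes() == 4

    def test_missing_q_rejected(self):
        with pytest.raises(ValueError):
            network.build_network(pd.DataFrame({"otu_a": [], "otu_b": []}))

    def test_taxonomy_annotation(self):
        assoc = self._assoc([("a", "b", 0.01)])
        tax = pd.DataFrame({"order": ["Glomerales", ""]}, index=["a", "b"])
        net = network.build_network(assoc, 0.05, tax)
        assert net.nodes["a"]["order"] == "Glomerales"
        assert net.nodes["b"]["order"] == "Unclassified"


class TestNodeCentralities:
    def test_star_center_closed_form(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        attrs = network.node_centralities(g)
        assert attrs.loc[0, "degree"] == 5
        assert attrs.loc[0, "closeness"] == pytest.approx(1.0)
        assert attrs.loc[0, "betweenness"] == pytest.approx(1.0)
        assert attrs.loc[1, "closeness"] == pytest.approx(1 / 1.8)

    def test_cycle_symmetry(self):
        g = nx.cycle_graph(5)
        attrs = network.node_centralities(g)
        assert attrs["betweenness"].nunique() == 1
        assert attrs["closeness"].nunique() == 1

    def test_seven_node_graph_matches_exhaustive_oracle(self):
        g = nx.Graph(
            [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (4, 5), (3, 5), (5, 6)]
        )
        attrs = network.node_centralities(g)
        oracle = brute_force_centralities(g)
        for node, (deg, close, btw, clus) in oracle.items():
            assert attrs.loc[node, "degree"] == deg
            assert attrs.loc[node, "closeness"] == pytest.approx(close)
            assert attrs.loc[node, "betweenness"] == pytest.approx(btw)
            assert attrs.loc[node, "local_clustering"] == pytest.approx(clus)

    def test_random_graphs_match_oracle(self, rng):
        """Property check on random graphs with <= 8 nodes, including
        disconnected ones."""
        for trial in range(60):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)),
                                    seed=int(rng.integers(2**31)))
            if g.number_of_nodes() == 0:
                continue
            attrs = network.node_centralities(g)
            oracle = brute_force_centralities(g)
            for node, (deg, close, btw, clus) in oracle.items():
                assert attrs.loc[node, "degree"] == deg
                assert attrs.loc[node, "closeness"] == pytest.approx(close)
                assert attrs.loc[node, "betweenness"] == pytest.approx(btw)
                assert attrs.loc[node, "local_clustering"] == pytest.approx(clus)

    def test_degree_sum_is_twice_edges(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=3)
        attrs = network.node_centralities(g)
        assert attrs["degree"].sum() == 2 * g.number_of_edges()


class TestTopologySummary:
    def test_complete_graph(self):
        ts = network.topology_summary(nx.complete_graph(4))
        assert ts.clustering_coefficient == pytest.approx(1.0)
        assert ts.diameter == 1
        assert ts.avg_neighbors == pytest.approx(3.0)

    def test_path_graph(self):
        ts = network.topology_summary(nx.path_graph(4))
        assert ts.clustering_coefficient == pytest.approx(0.0)
        assert ts.diameter == 3
        assert ts.avg_neighbors == pytest.approx(1.5)

    def test_matches_adjacency_power_oracle(self, rng):
        """Diameter and mean shortest path recomputed from boolean powers
        of the adjacency matrix."""
        g = nx.erdos_renyi_graph(30, 0.15, seed=7)
        ts = network.topology_summary(g)
        A = nx.to_numpy_array(g, dtype=bool)
        n = A.shape[0]
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0)
        reach = np.eye(n, dtype=bool)
        power = np.eye(n, dtype=bool)
        for d in range(1, n):
            power = power @ A
            newly = power & ~reach
            dist[newly] = d
            reach |= newly
        finite = dist[np.isfinite(dist) & (dist > 0)]
        assert ts.diameter == finite.max()
        assert ts.mean_shortest_path == pytest.approx(finite.mean())

    def test_invariant_under_relabeling(self, rng):
        g = nx.erdos_renyi_graph(15, 0.3, seed=1)
        mapping = dict(zip(g.nodes, rng.permutation(list(g.nodes))))
        h = nx.relabel_nodes(g, {k: f"n{v}" for k, v in mapping.items()})
        a, b = network.topology_summary(g), network.topology_summary(h)
        assert a.diameter == b.diameter
        assert a.clustering_coefficient == pytest.approx(b.clustering_coefficient)
        assert a.mean_shortest_path == pytest.approx(b.mean_shortest_path)


class TestPowerlawFit:
    def test_exact_power_law_recovered(self):
        ks = np.arange(1, 11)
        pk = ks**-2.0
        pk = pk / pk.sum()
        counts = np.round(pk * 10000).astype(int)
        seq = np.repeat(ks, counts)
        gamma, r2 = network.powerlaw_fit(seq)
        assert gamma == pytest.approx(2.0, abs=0.05)
        assert r2 > 0.999

    def test_uniform_degrees_undefined(self):
        gamma, r2 = network.powerlaw_fit([4, 4, 4, 4])
        assert np.isnan(gamma) and np.isnan(r2)


class TestBarabasiAlbert:
    def test_edge_count_forced_by_construction(self):
        g = network.barabasi_albert(10, 2, seed=0)
        assert g.number_of_edges() == 3 + 7 * 2
        assert g.number_of_nodes() == 10

    def test_hub_emergence(self):
        maxima, medians = [], []
        for seed in range(5):
            g = network.barabasi_albert(500, 2, seed=seed)
            degs = np.array([d for _, d in g.degree()])
            maxima.append(degs.max())
            medians.append(np.median(degs))
        assert np.mean(maxima) > 4 * np.mean(medians)

    def test_matched_m_approximates_edge_count(self):
        ref_n, ref_e = 120, 460
        m = max(1, round(ref_e / ref_n))
        g = network.barabasi_albert(ref_n, m, seed=1)
        assert abs(g.number_of_edges() - ref_e) / ref_e < 0.10

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            network.barabasi_albert(5, 5)


class TestCompareToRandom:
    def test_er_against_er_null_is_central(self):
        g = nx.erdos_renyi_graph(40, 0.12, seed=11)
        report = network.compare_to_random(g, n_rand=100, seed=0)
        assert 2.5 < report["er_clustering_percentile"] < 97.5

    def test_clique_rich_network_exceeds_null(self):
        cliques = [nx.complete_graph(range(6 * i, 6 * i + 6)) for i in range(5)]
        g = nx.union_all(cliques)
        for i in range(4):  # sparse links between cliques
            g.add_edge(6 * i, 6 * i + 6)
        report = network.compare_to_random(g, n_rand=100, seed=0)
        assert report["er_clustering_percentile"] > 99
        assert report["ba_clustering_percentile"] > 99

    def test_empty_comparison_set_rejected(self):
        with pytest.raises(ValueError):
            network.compare_to_random(nx.complete_graph(4), n_rand=0)


class TestExport:
    def test_sif_one_line_per_edge(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a", "b", relationship="positive")
        g.add_edge("b", "c", relationship="nonlinear")
        path = tmp_path / "net.sif"
        network.write_sif(g, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert any("positive" in ln for ln in lines)

    def test_graphml_roundtrip(self, tmp_path):
        g = nx.path_graph(4)
        path = tmp_path / "net.graphml"
        network.write_graphml(g, path)
        back = nx.read_graphml(path)
        assert back.number_of_edges() == 3
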