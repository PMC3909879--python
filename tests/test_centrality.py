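"""Centrality measures against closed forms and brute-force oracles."""

import math
import random

import networkx as nx
import numpy as np
import pytest

from netintegrity.centrality import (
    LOWER_IS_CRITICAL,
    degree_centrality,
    edge_betweenness,
    eigenvector_centrality,
    node_betweenness,
    normalized_laplacian_matrix,
    normalized_laplacian_spectrum,
    spectral_gap_centrality,
)
from netintegrity.graph import EmptyGraphError, build_graph

from conftest import brute_force_betweenness, random_small_graph


class TestDegree:
    def test_star(self, star4):
        values = degree_centrality(star4).values
        assert values["X"] == 4
        assert all(values[f"L{i}"] == 1 for i in range(1, 5))

    def test_path_and_isolated(self):
        g = build_graph([("A", "B"), ("B", "C")], extra_nodes={"Z"})
        values = degree_centrality(g).values
        assert values == {"A": 1, "B": 2, "C": 1, "Z": 0}

    def test_handshake_sum(self):
        rng = random.Random(7)
        for _ in range(20):
            g = random_small_graph(rng)
            assert sum(degree_centrality(g).values.values()) == 2 * g.number_of_edges()


class TestBetweenness:
    def test_path_p3(self):
        g = build_graph([("A", "B"), ("B", "C")])
        values = node_betweenness(g).values
        assert values == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_closed_form(self):
        n = 6
        g = build_graph([("X", f"L{i}") for i in range(n)])
        values = node_betweenness(g).values
        assert values["X"] == n * (n - 1) / 2

    def test_path_p4_interior(self, path4):
        values = node_betweenness(path4).values
        assert values["B"] == 2.0 and values["C"] == 2.0

    def test_complete_graph_all_zero(self):
        g = build_graph([(a, b) for a in "ABCDE" for b in "ABCDE" if a < b])
        assert all(v == 0 for v in node_betweenness(g).values.values())

    def test_edge_betweenness_path(self):
        g = build_graph([("A", "B"), ("B", "C")])
        values = edge_betweenness(g).values
        assert values[("A", "B")] == 2.0
        assert values[("B", "C")] == 2.0

    def test_single_edge(self):
        g = build_graph([("A", "B")])
        assert edge_betweenness(g).values[("A", "B")] == 1.0

    def test_barbell_bridge_dominates(self):
        g = build_graph(
            [("A", "B"), ("B", "C"), ("A", "C"),
             ("D", "E"), ("E", "F"), ("D", "F"),
             ("C", "D")]
        )
        values = edge_betweenness(g).values
        bridge = values[("C", "D")]
        assert all(v < bridge for e, v in values.items() if e != ("C", "D"))

    def test_matches_brute_force_on_random_graphs(self):
        rng = random.Random(20240917)
        for _ in range(60):
            g = random_small_graph(rng)
            oracle_nodes, oracle_edges = brute_force_betweenness(g)
            got_nodes = node_betweenness(g).values
            got_edges = edge_betweenness(g).values
            for n in g.nodes:
                assert got_nodes[n] == pytest.approx(oracle_nodes[n], abs=1e-9)
            for e in oracle_edges:
                assert got_edges[e] == pytest.approx(oracle_edges[e], abs=1e-9)

    def test_edge_betweenness_sums_to_total_distance(self):
        rng = random.Random(3)
        for _ in range(20):
            g = random_small_graph(rng)
            total = sum(edge_betweenness(g).values.values())
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            dist_sum = sum(
                lengths[u][v]
                for u in g.nodes
                for v in lengths[u]
                if u < v
            )
            assert total == pytest.approx(dist_sum, abs=1e-9)


class TestEigenvector:
    def test_complete_graph_uniform(self):
        n = 5
        g = build_graph([(a, b) for a in "ABCDE" for b in "ABCDE" if a < b])
        values = eigenvector_centrality(g).values
        assert all(v == pytest.approx(1 / math.sqrt(n), abs=1e-10) for v in values.values())

    def test_star_hub_leaf_ratio(self, star4):
        values = eigenvector_centrality(star4).values
        assert values["X"] / values["L1"] == pytest.approx(2.0, abs=1e-10)

    def test_eigen_equation_residual(self):
        rng = random.Random(11)
        for _ in range(25):
            g = random_small_graph(rng)
            if g.number_of_edges() == 0:
                continue
            result = eigenvector_centrality(g)
            nodes = sorted(g.nodes)
            a = nx.to_numpy_array(g, nodelist=nodes)
            v = np.array([result.values[n] for n in nodes])
            lam = float(v @ a @ v)
            assert np.max(np.abs(a @ v - lam * v)) < 1e-8

    def test_agrees_with_networkx_on_connected_graphs(self):
        g = build_graph(
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("A", "C"), ("D", "E")]
        )
        ours = eigenvector_centrality(g).values
        ref = nx.eigenvector_centrality_numpy(g)
        for n in g.nodes:
            assert ours[n] == pytest.approx(abs(ref[n]), abs=1e-8)

    def test_edgeless_graph_rejected(self):
        g = build_graph([], extra_nodes={"A", "B"})
        with pytest.raises(EmptyGraphError):
            eigenvector_centrality(g)

    def test_degenerate_components_warn_but_stay_valid(self, caplog):
        g = build_graph([("A", "B"), ("C", "D")])
        with caplog.at_level("WARNING"):
            result = eigenvector_centrality(g)
        assert "degenerate" in caplog.text
        v = np.array(sorted(result.values.values()))
        assert np.all(v >= 0)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-10)


class TestNormalizedLaplacian:
    def test_path_p3_spectrum(self):
        g = build_graph([("A", "B"), ("B", "C")])
        summary = normalized_laplacian_spectrum(g)
        assert summary.eigenvalues == pytest.approx([0.0, 1.0, 2.0], abs=1e-10)
        assert summary.spectral_gap == pytest.approx(1.0, abs=1e-10)

    def test_complete_k3_spectrum(self, triangle):
        summary = normalized_laplacian_spectrum(triangle)
        assert summary.eigenvalues == pytest.approx([0.0, 1.5, 1.5], abs=1e-10)
        assert summary.spectral_gap == pytest.approx(1.5, abs=1e-10)

    @pytest.mark.parametrize("n", range(3, 11))
    def test_complete_graph_gap_closed_form(self, n):
        names = [f"V{i}" for i in range(n)]
        g = build_graph([(a, b) for a in names for b in names if a < b])
        gap = normalized_laplacian_spectrum(g).spectral_gap
        assert gap == pytest.approx(n / (n - 1), abs=1e-10)

    def test_disconnected_gap_is_zero(self):
        g = build_graph([("A", "B"), ("C", "D")])
        summary = normalized_laplacian_spectrum(g)
        assert summary.eigenvalues == pytest.approx([0.0, 0.0, 2.0, 2.0], abs=1e-10)
        assert summary.spectral_gap == pytest.approx(0.0, abs=1e-10)

    def test_matches_networkx_matrix(self):
        rng = random.Random(5)
        for _ in range(10):
            g = random_small_graph(rng)
            if any(d == 0 for _, d in g.degree()):
                continue  # conventions for isolated nodes differ
            ours = normalized_laplacian_matrix(g)
            ref = nx.normalized_laplacian_matrix(g, nodelist=sorted(g.nodes)).toarray()
            assert np.allclose(ours, ref, atol=1e-12)

    def test_bounds_and_zero_multiplicity(self):
        rng = random.Random(99)
        for _ in range(50):
            g = random_small_graph(rng)
            eig = normalized_laplacian_spectrum(g).eigenvalues
            assert eig[0] >= -1e-8
            assert eig[-1] <= 2 + 1e-8
            n_zero = int(np.sum(np.abs(eig) < 1e-8))
            assert n_zero == nx.number_connected_components(g)


class TestSpectralGapCentrality:
    def test_leaves_and_isolates_are_infinite(self):
        g = build_graph([("A", "B"), ("B", "C")], extra_nodes={"Z"})
        values = spectral_gap_centrality(g, h=1).values
        assert math.isinf(values["A"])
        assert math.isinf(values["C"])
        assert math.isinf(values["Z"])
        assert math.isfinite(values["B"])

    def test_star_hub_value(self, star4):
        result = spectral_gap_centrality(star4, h=1)
        assert result.orientation == LOWER_IS_CRITICAL
        assert result.values["X"] == pytest.approx(0.5, abs=1e-10)

    def test_complete_k4_value(self):
        g = build_graph([(a, b) for a in "ABCD" for b in "ABCD" if a < b])
        values = spectral_gap_centrality(g, h=1).values
        expected = (4 / 3) / math.log2(3)
        assert all(v == pytest.approx(expected, abs=1e-10) for v in values.values())

    def test_invalid_radius_rejected(self, star4):
        with pytest.raises(ValueError):
            spectral_gap_centrality(star4, h=0)


class TestRelabelingEquivariance:
    """All measures commute with node relabeling."""

    def test_permutation_equivariance(self):
        rng = random.Random(42)
        for _ in range(10):
            g = random_small_graph(rng)
            names = sorted(g.nodes)
            shuffled = names[:]
            rng.shuffle(shuffled)
            mapping = dict(zip(names, shuffled))
            g2 = nx.relabel_nodes(g, mapping)
            for fn in (
                degree_centrality,
                node_betweenness,
                lambda x: spectral_gap_centrality(x, h=2),
            ):
                v1 = fn(g).values
                v2 = fn(g2).values
                for n in names:
                    if math.isinf(v1[n]):
                        assert math.isinf(v2[mapping[n]])
                    else:
                        assert v2[mapping[n]] == pytest.approx(v1[n], abs=1e-9)

    def test_serialization_roundtrip_formats(self, star4):
        result = spectral_gap_centrality(star4, h=1)
        tsv = result.to_tsv()
        assert "inf" in tsv and tsv.startswith("node\tvalue")
        assert '"h": 1' in result.to_json()
        etsv = edge_betweenness(star4).to_tsv()
        assert etsv.splitlines()[1].split("\t")[:2] == ["L1", "X"]
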