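"""Graph-topological features against closed forms and networkx oracles."""

import numpy as np
import pytest

from eegdynet.metrics import (FEATURE_NAMES, avg_path_length,
                              avg_vertex_strength, small_world_index,
                              static_features, transitivity, weighted_diameter)
from eegdynet.network import BrainGraph

from oracles import all_pairs_hop_and_weighted


def graph(weights):
    w = np.asarray(weights, dtype=float)
    return BrainGraph(w, [f"n{i}" for i in range(w.shape[0])])


def triangle(w1=0.5, w2=0.5, w3=0.5):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w1
    w[1, 2] = w[2, 1] = w2
    w[0, 2] = w[2, 0] = w3
    return graph(w)


def star_k14():
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    return graph(w)


def random_graph(n, p, rng, weighted=True):
    w = np.triu(rng.uniform(0, 1, (n, n)) * (rng.uniform(0, 1, (n, n)) < p), 1)
    if not weighted:
        w = (w > 0).astype(float)
    return graph(w + w.T)


class TestStrength:
    def test_triangle_half_weights(self):
        assert avg_vertex_strength(triangle()) == pytest.approx(1.0)

    def test_star(self):
        assert avg_vertex_strength(star_k14()) == pytest.approx(1.6)

    def test_handshake_identity(self, rng):
        g = random_graph(12, 0.4, rng)
        iu = np.triu_indices(12, 1)
        total = g.weights[iu].sum()
        assert avg_vertex_strength(g) == pytest.approx(2 * total / 12)

    def test_empty(self):
        assert avg_vertex_strength(graph(np.zeros((4, 4)))) == 0.0


class TestPathLength:
    def test_complete_graph(self):
        n = 19
        w = (np.ones((n, n)) - np.eye(n)) * 0.3
        assert avg_path_length(graph(w)) == pytest.approx(1.0)

    def test_path_graph(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[1, 2] = w[2, 1] = 0.1
        assert avg_path_length(graph(w)) == pytest.approx(4 / 3)

    def test_two_minus_density_on_diameter_two_graphs(self, rng):
        # any graph where all non-adjacent pairs sit at hop distance 2
        for seed in range(5):
            r = np.random.default_rng(seed)
            g = random_graph(10, 0.6, r)
            hop, _ = all_pairs_hop_and_weighted(g.weights)
            iu = np.triu_indices(10, 1)
            if np.isinf(hop[iu]).any() or hop[iu].max() > 2:
                continue
            density = (g.weights[iu] > 0).mean()
            assert avg_path_length(g) == pytest.approx(2 - density)


class TestDiameter:
    def test_single_edge(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.22
        assert weighted_diameter(graph(w)) == pytest.approx(0.22)

    def test_heavy_edge_bypassed(self):
        g = triangle(0.1, 0.1, 0.5)
        assert weighted_diameter(g) == pytest.approx(0.2)


class TestAllPairsOracle:
    def test_brute_force_small_graphs(self):
        # exhaustive path enumeration on 200 random graphs of <= 6 nodes
        r = np.random.default_rng(99)
        done = 0
        while done < 200:
            n = int(r.integers(3, 7))
            g = random_graph(n, float(r.uniform(0.3, 0.9)), r)
            hop, wd = all_pairs_hop_and_weighted(g.weights)
            # path metrics are defined on the largest connected component
            reach = ~np.isinf(hop)
            comp_sizes = reach.sum(axis=1)
            members = np.where(comp_sizes == comp_sizes.max())[0]
            comp = np.where(reach[members[0]])[0]
            if len(comp) < 2:
                continue
            sub_hop = hop[np.ix_(comp, comp)]
            sub_wd = wd[np.ix_(comp, comp)]
            iu = np.triu_indices(len(comp), 1)
            assert avg_path_length(g) == pytest.approx(sub_hop[iu].mean())
            assert weighted_diameter(g) == pytest.approx(sub_wd[iu].max())
            done += 1

    def test_matches_networkx(self, rng):
        import networkx as nx
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = random_graph(10, 0.5, r)
            nxg = g.to_networkx()
            if not nx.is_connected(nxg):
                continue
            assert avg_path_length(g) == pytest.approx(
                nx.average_shortest_path_length(nxg))
            assert transitivity(g) == pytest.approx(nx.transitivity(nxg))
            wd = max(max(d.values()) for _, d in
                     nx.shortest_path_length(nxg, weight="weight"))
            assert weighted_diameter(g) == pytest.approx(wd)


class TestTransitivity:
    def test_triangle(self):
        assert transitivity(triangle()) == pytest.approx(1.0)

    def test_star_no_triangles(self):
        assert transitivity(star_k14()) == pytest.approx(0.0)

    def test_gnp_expectation(self):
        # E[transitivity] = p for Erdos-Renyi G(n, p)
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals.append(transitivity(random_graph(19, 0.36, r, weighted=False)))
        assert np.mean(vals) == pytest.approx(0.36, abs=0.02)


class TestSmallWorld:
    def test_gnm_self_comparison_near_one(self):
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            g = random_graph(19, 0.4, r)
            vals.append(small_world_index(g, n_random=10, seed=seed))
        assert abs(np.mean(vals) - 1.0) < 0.1

    def test_rewired_ring_lattice_small_world(self):
        import networkx as nx
        nxg = nx.connected_watts_strogatz_graph(19, 4, 0.1, seed=3)
        w = nx.to_numpy_array(nxg)
        s = small_world_index(graph(w), n_random=20, seed=0)
        assert s > 1.0

    def test_complete_graph_is_unity(self):
        n = 10
        w = np.ones((n, n)) - np.eye(n)
        assert small_world_index(graph(w), n_random=3, seed=1) == pytest.approx(1.0)

    def test_deterministic(self):
        r = np.random.default_rng(5)
        g = random_graph(19, 0.4, r)
        assert small_world_index(g, 5, seed=9) == small_world_index(g, 5, seed=9)


class TestBundleAndInvariances:
    def test_unit_triangle_bundle(self):
        feats = static_features(triangle(1, 1, 1), n_random=3, seed=0)
        assert feats.strength == pytest.approx(2.0)
        assert feats.path_length == pytest.approx(1.0)
        assert feats.transitivity == pytest.approx(1.0)
        assert feats.diameter == pytest.approx(1.0)
        assert feats.small_world == pytest.approx(1.0)
        assert list(feats.as_dict()) == FEATURE_NAMES

    def test_all_finite_on_thresholded_synthetic(self):
        from eegdynet.connectivity import connectivity_matrix
        from eegdynet.io import BandSpec, bandpass
        from eegdynet.network import apply_threshold
        from eegdynet.synthetic import CohortConfig, generate_record
        band = BandSpec("a", 8.0, 12.0)
        cfg = CohortConfig(duration=20.0, seed=8)
        rec = generate_record(cfg, "PE", 8)
        mat = connectivity_matrix(bandpass(rec, band), "MSC", band)
        g = apply_threshold(mat, 0.64)
        feats = static_features(g, n_random=5, seed=0)
        assert np.all(np.isfinite(feats.as_array()))

    def test_scale_covariance(self, rng):
        g = random_graph(12, 0.5, rng)
        a = 3.7
        scaled = graph(a * g.weights)
        assert avg_vertex_strength(scaled) == pytest.approx(
            a * avg_vertex_strength(g))
        assert weighted_diameter(scaled) == pytest.approx(
            a * weighted_diameter(g))
        assert avg_path_length(scaled) == pytest.approx(avg_path_length(g))
        assert transitivity(scaled) == pytest.approx(transitivity(g))
        assert small_world_index(scaled, 5, seed=2) == pytest.approx(
            small_world_index(g, 5, seed=2))

    def test_disconnected_uses_largest_component(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        w[3, 4] = w[4, 3] = 0.5
        with pytest.warns(UserWarning, match="component"):
            apl = avg_path_length(graph(w))
        assert apl == pytest.approx(4 / 3)
        feats = static_features(graph(w), n_random=3, seed=0)
        assert feats.n_components == 2
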