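"""MIC statistic, co-occurrence network construction, topology and nulls."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyllonet import (
    CommunityError,
    build_network,
    mic,
    mic_brute_force,
    mic_pvalue,
    random_network,
    random_topology,
    rewired_null,
    topology,
)

from conftest import make_table


class TestMic:
    def test_perfect_monotone_relation_is_one(self):
        x = np.arange(10.0)
        assert mic(x, x) == pytest.approx(1.0)
        assert mic(x, np.exp(x)) == pytest.approx(1.0)

    def test_constant_vector_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert mic(np.arange(8.0), np.full(8, 2.0)) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=10), rng.normal(size=10)
            assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-12)

    def test_invariant_under_increasing_transforms(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            x, y = rng.normal(size=12), rng.normal(size=12)
            base = mic(x, y)
            assert mic(np.exp(x), y) == pytest.approx(base, abs=1e-12)
            assert mic(x, y**3) == pytest.approx(base, abs=1e-12)

    def test_matches_exhaustive_grid_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            x, y = rng.normal(size=8), rng.normal(size=8)
            assert mic(x, y) == pytest.approx(mic_brute_force(x, y), abs=1e-9)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 25:
            x = rng.poisson(1.5, size=9).astype(float)
            y = rng.poisson(1.5, size=9).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            assert mic(x, y) == pytest.approx(mic_brute_force(x, y), abs=1e-9)
            checked += 1

    def test_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            score = mic(rng.normal(size=9), rng.normal(size=9))
            assert 0.0 <= score <= 1.0

    def test_input_validation(self):
        with pytest.raises(CommunityError):
            mic(np.arange(6.0), np.arange(7.0))
        with pytest.raises(CommunityError):
            mic(np.arange(4.0), np.arange(4.0))


class TestMicPvalue:
    def test_perfect_relation_minimal_p(self):
        x = np.arange(15.0)
        assert mic_pvalue(x, x, n_perm=999, seed=0) == pytest.approx(1 / 1000)

    def test_p_in_half_open_interval(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            p = mic_pvalue(rng.normal(size=8), rng.normal(size=8), n_perm=99, seed=seed)
            assert 0 < p <= 1

    def test_too_few_permutations_rejected(self):
        with pytest.raises(CommunityError):
            mic_pvalue(np.arange(8.0), np.arange(8.0), n_perm=10)

    def test_null_p_values_valid_and_spread(self):
        # independent vectors: permutation p-values must be valid
        # (super-uniform: P(p <= t) does not exceed t beyond Monte-Carlo
        # error; the MIC null is discrete at small n, so exact uniformity
        # cannot hold) and must spread over the unit interval
        rng = np.random.default_rng(7)
        ps = np.array(
            [
                mic_pvalue(rng.normal(size=10), rng.normal(size=10), n_perm=99, seed=i)
                for i in range(100)
            ]
        )
        for t in (0.05, 0.2, 0.5):
            se = np.sqrt(t * (1 - t) / len(ps))
            assert (ps <= t).mean() <= t + 3 * se
        assert np.median(ps) < 0.9
        assert (ps <= 0.2).any()


class TestBuildNetwork:
    def test_identical_profiles_complete_graph(self):
        profile = np.array([1, 5, 2, 9, 4, 7])
        counts = np.vstack([profile, profile * 2, profile * 3])
        g = build_network(make_table(counts), mic_threshold=0.5)
        assert g.number_of_edges() == 3  # K3

    def test_exclusive_threshold_one_empty(self):
        profile = np.array([1, 5, 2, 9, 4, 7])
        counts = np.vstack([profile, profile * 2])
        g = build_network(make_table(counts), mic_threshold=1.0)
        assert g.number_of_edges() == 0

    def test_negative_association_excluded(self):
        up = np.array([1.0, 2, 3, 4, 5, 6])
        counts = np.vstack([up, up[::-1]]).astype(int)
        g = build_network(make_table(counts), mic_threshold=0.5)
        assert g.number_of_edges() == 0  # MIC = 1 but rank correlation < 0

    def test_too_few_samples_rejected(self):
        counts = np.array([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(CommunityError, match="5"):
            build_network(make_table(counts))

    def test_planted_block_denser_than_noise(self):
        rng = np.random.default_rng(0)
        shared = rng.integers(1, 50, size=9)
        block = np.vstack([shared + rng.integers(0, 3, size=9) for _ in range(6)])
        noise = rng.integers(0, 50, size=(6, 9))
        g_block = build_network(make_table(block))
        g_noise = build_network(make_table(noise), keep_isolated=True)
        assert g_block.number_of_edges() > g_noise.number_of_edges()


class TestTopology:
    def test_complete_graph_identities(self):
        rep = topology(nx.complete_graph(4))
        assert rep.density == 1.0
        assert rep.clustering_coefficient == 1.0
        assert rep.diameter == 1.0
        assert rep.heterogeneity == 0.0
        assert rep.shortest_paths == 12  # ordered pairs

    def test_printed_size_identities(self):
        # density and mean degree depend only on N and E
        rep = topology(random_network(13, 20, seed=0))
        assert round(rep.density, 3) == 0.256
        assert round(rep.avg_neighbors, 3) == 3.077
        rep = topology(random_network(43, 142, seed=0))
        assert round(rep.density, 3) == 0.157
        assert round(rep.avg_neighbors, 3) == 6.605

    def test_star_centralization_is_one(self):
        rep = topology(nx.star_graph(5))  # 6 nodes
        assert rep.centralization == pytest.approx(1.0)

    def test_small_graph_centralization_missing(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        assert topology(g).centralization is None

    def test_matches_brute_force_shortest_paths(self):
        # oracle: Floyd-Warshall by hand on random graphs with <= 8 nodes
        rng = np.random.default_rng(1)
        for trial in range(60):
            n = int(rng.integers(3, 9))
            m = int(rng.integers(0, n * (n - 1) // 2 + 1))
            g = random_network(n, m, seed=trial)
            rep = topology(g)
            inf = float("inf")
            nodes = list(g.nodes)
            idx = {v: i for i, v in enumerate(nodes)}
            dist = np.full((n, n), inf)
            np.fill_diagonal(dist, 0)
            for u, v in g.edges:
                dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1
            for k in range(n):
                for i in range(n):
                    for j in range(n):
                        dist[i, j] = min(dist[i, j], dist[i, k] + dist[k, j])
            finite = dist[(dist > 0) & (dist < inf)]
            assert rep.shortest_paths == finite.size
            if finite.size:
                assert rep.characteristic_path_length == pytest.approx(finite.mean())

    def test_radius_diameter_inequality(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            g = random_network(10, int(rng.integers(9, 30)), seed=trial)
            rep = topology(g)
            if rep.connected_components == 1:
                assert rep.radius <= rep.diameter <= 2 * rep.radius


class TestRandomNetwork:
    def test_three_nodes_three_edges_is_triangle(self):
        g = random_network(3, 3, seed=0)
        assert nx.is_isomorphic(g, nx.complete_graph(3))

    def test_empty_graph(self):
        g = random_network(5, 0, seed=0)
        assert topology(g).connected_components == 5

    def test_handshake_identity(self):
        for seed in range(10):
            g = random_network(12, 20, seed=seed)
            assert sum(d for _, d in g.degree()) == 40

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(CommunityError):
            random_network(4, 7)

    def test_replicate_mode_reports_mean_sd(self):
        rep = random_topology(13, 20, n_replicates=10, seed=0)
        assert rep.loc["density", "mean"] == pytest.approx(0.256, abs=1e-3)
        assert rep.loc["density", "sd"] == pytest.approx(0.0, abs=1e-12)
        assert rep.loc["clustering_coefficient", "sd"] >= 0

    def test_rewired_null_preserves_degrees(self):
        g = random_network(12, 24, seed=3)
        h = rewired_null(g, seed=0)
        assert sorted(d for _, d in g.degree()) == sorted(d for _, d in h.degree())
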