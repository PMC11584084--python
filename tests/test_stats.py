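"""Group statistics: one-sample t, TFCE against a brute-force oracle, and
the sign-flip permutation test with max-null correction."""

import networkx as nx
import numpy as np
import pytest

from eegrsa.errors import InvalidConfigError, InvalidInputError
from eegrsa.searchlight import build_clusters
from eegrsa.simulate import generate_montage
from eegrsa.stats import (
    AdjacencyGraph,
    build_adjacency,
    one_sample_t,
    paired_difference_test,
    sign_flip_permutation_test,
    subgraph,
    tfce,
)


def tfce_bruteforce(t, adj, E=0.5, H=2.0, dh=0.1):
    """Independent oracle: explicit threshold loop + networkx components."""
    out = np.zeros_like(t)
    g = nx.Graph()
    g.add_nodes_from(range(len(t)))
    g.add_edges_from(map(tuple, adj.edges))
    h = dh
    while h <= t.max(initial=0.0) + 1e-12:
        nodes = [u for u in range(len(t)) if t[u] >= h]
        for comp in nx.connected_components(g.subgraph(nodes)):
            for u in comp:
                out[u] += len(comp) ** E * h**H * dh
        h += dh
    return out


class TestOneSampleT:
    def test_zero_scores_give_zero_t(self):
        np.testing.assert_array_equal(one_sample_t(np.zeros((5, 3))), 0.0)

    def test_zero_variance_unit_warned_and_zeroed(self):
        scores = np.ones((4, 1))
        with pytest.warns(UserWarning, match="zero variance"):
            t = one_sample_t(scores)
        assert t[0] == 0.0

    def test_hand_computed_t(self):
        t = one_sample_t(np.array([[0.1], [0.2], [0.3]]))
        assert t[0] == pytest.approx(0.2 / (0.1 / np.sqrt(3)))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidInputError):
            one_sample_t(np.zeros((2, 4)))


class TestTfce:
    def test_zero_map_enhances_to_zero(self):
        adj = build_adjacency("temporal_chain", n_times=6)
        np.testing.assert_array_equal(tfce(np.zeros(6), adj), 0.0)

    def test_isolated_unit_two_threshold_hand_sum(self):
        adj = AdjacencyGraph(1, np.empty((0, 2)))
        # h in {0.5, 1.0}: 1**0.5 * 0.25 * 0.5  +  1**0.5 * 1 * 0.5
        assert tfce(np.array([1.0]), adj, dh=0.5)[0] == pytest.approx(0.625)

    def test_negative_t_contributes_nothing(self):
        adj = build_adjacency("temporal_chain", n_times=3)
        out = tfce(np.array([-2.0, 1.0, -0.5]), adj)
        assert out[0] == 0.0 and out[2] == 0.0 and out[1] > 0.0

    def test_agrees_with_bruteforce_on_random_graphs(self, rng):
        for _ in range(15):
            n = 20
            edges = [
                (a, b)
                for a in range(n)
                for b in range(a + 1, n)
                if rng.random() < 0.15
            ]
            adj = AdjacencyGraph(n, np.asarray(edges).reshape(-1, 2))
            t = rng.normal(0, 1.5, size=n)
            np.testing.assert_allclose(
                tfce(t, adj), tfce_bruteforce(t, adj), atol=1e-9
            )

    def test_monotone_in_t(self, rng):
        adj = build_adjacency("temporal_chain", n_times=12)
        t = np.abs(rng.normal(size=12))
        base = tfce(t, adj)
        for u in range(12):
            t2 = t.copy()
            t2[u] *= 2
            assert (tfce(t2, adj) >= base - 1e-12).all()

    def test_nonpositive_dh_rejected(self):
        adj = build_adjacency("temporal_chain", n_times=3)
        with pytest.raises(InvalidConfigError):
            tfce(np.ones(3), adj, dh=0.0)


class TestBuildAdjacency:
    def test_temporal_chain_edge_count(self):
        adj = build_adjacency("temporal_chain", n_times=5)
        assert adj.n_nodes == 5 and len(adj.edges) == 4

    def test_searchlight_same_window_neighbors_and_window_chain(self):
        montage = generate_montage(16)
        clusters = build_clusters(montage, analysis_window_ms=(0, 200))
        adj = build_adjacency(
            "searchlight_spatiotemporal",
            clusters=clusters,
            montage=montage,
            neighbor_distance_mm=40.0,
        )
        dist = montage.distance_matrix()
        cidx = {n: i for i, n in enumerate(montage.channel_names)}
        edge_set = {tuple(e) for e in adj.edges} | {
            tuple(e[::-1]) for e in adj.edges
        }
        for a in range(len(clusters)):
            for b in range(len(clusters)):
                if a >= b:
                    continue
                ca, cb = clusters[a], clusters[b]
                same_window = ca.window_ms == cb.window_ms
                d = dist[cidx[ca.center_channel], cidx[cb.center_channel]]
                consecutive = (
                    ca.center_channel == cb.center_channel
                    and abs(ca.window_ms[0] - cb.window_ms[0]) == 100.0
                )
                expected = (same_window and d <= 40.0) or consecutive
                assert ((a, b) in edge_set) == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidConfigError):
            build_adjacency("banana")


class TestSubgraph:
    def test_keeps_edges_between_kept_nodes(self):
        adj = build_adjacency("temporal_chain", n_times=5)
        sub = subgraph(adj, np.array([True, True, False, True, True]))
        assert sub.n_nodes == 4
        assert {tuple(e) for e in sub.edges} == {(0, 1), (2, 3)}


class TestSignFlipPermutation:
    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(15, 10))
        adj = build_adjacency("temporal_chain", n_times=10)
        a = sign_flip_permutation_test(x, adj, n_permutations=256, seed=3)
        b = sign_flip_permutation_test(x, adj, n_permutations=256, seed=3)
        np.testing.assert_array_equal(a.p, b.p)

    def test_p_values_in_half_open_unit_interval(self, rng):
        x = rng.normal(size=(14, 8))
        adj = build_adjacency("temporal_chain", n_times=8)
        res = sign_flip_permutation_test(x, adj, n_permutations=128, seed=0)
        assert (res.p > 0).all() and (res.p <= 1).all()

    def test_exhaustive_enumeration_for_few_subjects(self, rng):
        x = rng.normal(size=(8, 5))
        adj = build_adjacency("temporal_chain", n_times=5)
        res = sign_flip_permutation_test(x, adj, n_permutations=100, seed=0)
        assert res.n_permutations == 2**8

    def test_strong_uniform_signal_all_significant(self, rng):
        x = 0.5 + 0.1 * rng.normal(size=(30, 10))
        adj = build_adjacency("temporal_chain", n_times=10)
        res = sign_flip_permutation_test(x, adj, n_permutations=1024, seed=0)
        assert res.significant.all()

    def test_too_few_subjects_or_permutations_rejected(self, rng):
        adj = build_adjacency("temporal_chain", n_times=4)
        with pytest.raises(InvalidInputError):
            sign_flip_permutation_test(rng.normal(size=(2, 4)), adj)
        with pytest.raises(InvalidConfigError):
            sign_flip_permutation_test(
                rng.normal(size=(10, 4)), adj, n_permutations=50
            )

    def test_familywise_calibration_under_null(self, rng):
        """Fraction of null simulations with any corrected p < alpha stays
        near or below alpha (binomial tolerance)."""
        adj = build_adjacency("temporal_chain", n_times=20)
        hits = 0
        n_sim = 150
        for k in range(n_sim):
            x = rng.normal(size=(10, 20))
            res = sign_flip_permutation_test(x, adj, n_permutations=256, seed=k)
            hits += bool((res.p < 0.05).any())
        assert hits / n_sim <= 0.05 + 1.645 * np.sqrt(0.05 * 0.95 / n_sim)


class TestPairedDifference:
    def test_equal_models_show_nothing(self, rng):
        a = rng.normal(size=(20, 6))
        adj = build_adjacency("temporal_chain", n_times=6)
        res = paired_difference_test(a, a.copy(), adj, n_permutations=256, seed=0)
        np.testing.assert_array_equal(res.t, 0.0)
        assert not res.significant.any()

    def test_uniform_advantage_flags_widespread(self, rng):
        b = rng.normal(scale=0.1, size=(30, 8))
        a = b + 0.3 + 0.1 * rng.normal(size=(30, 8))
        adj = build_adjacency("temporal_chain", n_times=8)
        res = paired_difference_test(a, b, adj, n_permutations=512, seed=0)
        assert res.significant.mean() >= 0.9

    def test_one_tailed_antisymmetry(self, rng):
        b = rng.normal(scale=0.1, size=(25, 6))
        a = b + 0.4
        adj = build_adjacency("temporal_chain", n_times=6)
        res = paired_difference_test(b, a, adj, n_permutations=256, seed=0)
        assert not res.significant.any()

    def test_shape_mismatch_rejected(self, rng):
        adj = build_adjacency("temporal_chain", n_times=4)
        with pytest.raises(InvalidInputError):
            paired_difference_test(
                rng.normal(size=(10, 4)), rng.normal(size=(10, 5)), adj
            )
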