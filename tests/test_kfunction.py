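"""Network K-functions, CSR simulation, Monte Carlo envelopes, labels."""

import numpy as np
import pytest
from conftest import make_grid, oracle_distance_matrix, random_points
from scipy import stats

from netpatterns import (
    NetworkPointSet,
    auto_k,
    build_network,
    classify_pattern,
    cross_k,
    envelope,
    simulate_csr,
)


class TestAutoK:
    def test_two_points_on_square_jump_at_separation(self, square_net):
        # points at network distance 150 m; rho = 1/400
        pts = NetworkPointSet(square_net, [0, 1], [20.0, 70.0])
        t = np.array([0.0, 100.0, 149.9, 150.0, 300.0])
        res = auto_k(square_net, pts, t)
        np.testing.assert_allclose(res.k, [0, 0, 0, 400.0, 400.0])

    def test_saturates_at_total_length(self, grid5):
        rng = np.random.default_rng(2)
        pts = random_points(grid5, 9, rng)
        t = np.array([10.0, grid5.diameter() + grid5.edge_lengths.max()])
        res = auto_k(grid5, pts, t)
        assert res.k[-1] == pytest.approx(grid5.total_length)

    def test_nondecreasing_and_bounded(self, grid5):
        rng = np.random.default_rng(4)
        pts = random_points(grid5, 20, rng)
        res = auto_k(grid5, pts, np.linspace(0, 900, 40))
        assert np.all(np.diff(res.k) >= 0)
        assert np.all(res.k <= grid5.total_length + 1e-9)

    def test_matches_pair_counting_oracle(self, grid5):
        rng = np.random.default_rng(6)
        pts = random_points(grid5, 6, rng)
        t = np.linspace(0, 800, 17)
        res = auto_k(grid5, pts, t)
        dmat = oracle_distance_matrix(grid5, pts, pts)
        np.fill_diagonal(dmat, np.inf)
        n = len(pts)
        rho = (n - 1) / grid5.total_length
        expected = [(dmat <= ti).sum() / n / rho for ti in t]
        np.testing.assert_allclose(res.k, expected, rtol=1e-9)

    def test_coincident_points_counted_at_t_zero(self, square_net):
        pts = NetworkPointSet(square_net, [0, 0, 1], [30.0, 30.0, 50.0])
        res = auto_k(square_net, pts, np.array([0.0, 10.0]))
        assert res.k[0] > 0

    def test_needs_two_points(self, square_net):
        with pytest.raises(ValueError):
            auto_k(square_net, NetworkPointSet(square_net, [0], [10.0]))


class TestCrossK:
    def test_single_pair_jump(self, square_net):
        base = NetworkPointSet(square_net, [0], [20.0])
        target = NetworkPointSet(square_net, [1], [70.0])  # 150 m away
        t = np.array([100.0, 150.0, 200.0])
        res = cross_k(square_net, base, target, t)
        np.testing.assert_allclose(res.k, [0.0, 400.0, 400.0])

    def test_self_pairs_counted_in_cross_mode(self, square_net):
        pts = NetworkPointSet(square_net, [0, 1], [20.0, 70.0])
        res = cross_k(square_net, pts, pts, np.array([0.0, 1.0]))
        # both base points coincide with one target each: K(0) = S * (1/2)
        assert res.k[0] == pytest.approx(400.0 * 0.5)

    def test_matches_pair_counting_oracle(self, grid5):
        rng = np.random.default_rng(8)
        base = random_points(grid5, 5, rng)
        target = random_points(grid5, 8, rng)
        t = np.linspace(0, 700, 15)
        res = cross_k(grid5, base, target, t)
        dmat = oracle_distance_matrix(grid5, base, target)
        rho = len(target) / grid5.total_length
        expected = [(dmat <= ti).sum() / len(base) / rho for ti in t]
        np.testing.assert_allclose(res.k, expected, rtol=1e-9)

    def test_empty_sets_rejected(self, square_net):
        pts = NetworkPointSet(square_net, [0], [1.0])
        empty = NetworkPointSet(square_net, [], [])
        with pytest.raises(ValueError):
            cross_k(square_net, empty, pts)
        with pytest.raises(ValueError):
            cross_k(square_net, pts, empty)


class TestSimulateCSR:
    def test_same_seed_identical(self, grid5):
        a = simulate_csr(grid5, 30, rng=123)
        b = simulate_csr(grid5, 30, rng=123)
        np.testing.assert_array_equal(a.edge_ids, b.edge_ids)
        np.testing.assert_array_equal(a.offsets, b.offsets)

    def test_zero_points(self, grid5):
        assert len(simulate_csr(grid5, 0, rng=1)) == 0

    def test_counts_proportional_to_edge_length(self):
        net = build_network(
            [[(0, 0), (100, 0)], [(100, 0), (300, 0)], [(300, 0), (1000, 0)]]
        )
        pts = simulate_csr(net, 10_000, rng=99)
        observed = np.bincount(pts.edge_ids, minlength=3)
        expected = 10_000 * net.edge_lengths / net.total_length
        assert stats.chisquare(observed, expected).pvalue > 0.01

    def test_offsets_within_edges(self, grid5):
        pts = simulate_csr(grid5, 200, rng=5)
        assert np.all(pts.offsets >= 0)
        assert np.all(pts.offsets <= grid5.edge_lengths[pts.edge_ids])


class TestEnvelope:
    def test_bounds_ordered_and_contain_mean(self, grid5):
        t = np.linspace(0, 800, 20)
        env = envelope(grid5, 15, t, n_sims=50, alpha=0.05, rng=7)
        assert np.all(env.lower <= env.mean + 1e-12)
        assert np.all(env.mean <= env.upper + 1e-12)

    def test_csr_mean_monotone_and_saturates(self, grid5):
        """E[K] under CSR rises from ~0 and saturates at the total length."""
        t = np.linspace(0, 900, 20)
        env = envelope(grid5, 25, t, n_sims=100, alpha=0.05, rng=1)
        assert np.all(np.diff(env.mean) >= -1e-9)
        assert env.mean[0] < 0.05 * grid5.total_length
        assert env.mean[-1] == pytest.approx(grid5.total_length, rel=0.01)

    def test_quantile_variance_shrinks_with_more_sims(self, grid5):
        """The envelope bounds stabilize as the simulation count grows."""
        t = np.array([200.0, 400.0])
        spread = {}
        for n_sims in (30, 300):
            uppers = [
                envelope(grid5, 20, t, n_sims=n_sims, alpha=0.05, rng=seed).upper[0]
                for seed in range(8)
            ]
            spread[n_sims] = np.std(uppers)
        assert spread[300] < spread[30]

    def test_mode_argument_validation(self, grid5):
        t = np.linspace(0, 500, 5)
        base = random_points(grid5, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            envelope(grid5, 10, t, 20, 0.05, 1, mode="cross")
        with pytest.raises(ValueError):
            envelope(grid5, 10, t, 20, 0.05, 1, mode="auto", base=base)
        with pytest.raises(ValueError):
            envelope(grid5, 10, t, 10, 0.05, 1)  # too few sims


class TestClassifyPattern:
    @staticmethod
    def _env(t):
        from netpatterns import KEnvelope

        return KEnvelope(
            t_grid=t,
            lower=np.full(len(t), 10.0),
            upper=np.full(len(t), 20.0),
            mean=np.full(len(t), 15.0),
            n_sims=99,
            alpha=0.05,
            mode="auto",
        )

    @staticmethod
    def _obs(t, k):
        from netpatterns import KResult

        return KResult(t_grid=t, k=np.full(len(t), k), n=10, rho=0.01,
                       mode="auto", total_length=1000.0)

    @pytest.mark.parametrize(
        "k,expected", [(25.0, "clustered"), (15.0, "random"), (5.0, "dispersed")]
    )
    def test_three_way_rule(self, k, expected):
        t = np.linspace(0, 100, 11)
        lab = classify_pattern(self._obs(t, k), self._env(t))
        assert set(lab.labels) == {expected}
        assert lab.summary == expected

    def test_grid_mismatch_rejected(self):
        t = np.linspace(0, 100, 11)
        with pytest.raises(ValueError):
            classify_pattern(self._obs(t, 15.0), self._env(t + 1.0))

    def test_csr_pattern_labeled_random_mostly(self, grid5):
        t = np.linspace(0, 800, 25)
        env = envelope(grid5, 40, t, n_sims=200, alpha=0.05, rng=31)
        obs = auto_k(grid5, simulate_csr(grid5, 40, rng=12345), t)
        lab = classify_pattern(obs, env)
        assert np.mean(lab.labels == "random") >= 0.9

    def test_tight_cluster_labeled_clustered_at_small_t(self, grid5):
        # all points within one 200 m neighborhood on two adjacent edges
        rng = np.random.default_rng(3)
        edges = rng.choice([0, 1], size=25)
        offsets = rng.uniform(0, 100, 25)
        pts = NetworkPointSet(grid5, edges, offsets)
        t = np.linspace(0, 800, 25)
        env = envelope(grid5, 25, t, n_sims=99, alpha=0.05, rng=77)
        lab = classify_pattern(auto_k(grid5, pts, t), env)
        small_t = t <= 250
        assert np.all(lab.labels[small_t][1:] == "clustered")
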