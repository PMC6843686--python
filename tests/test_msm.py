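"""Markov state model estimation, clustering, and CK validation."""

import numpy as np
import pytest

from channelgate.errors import InputError
from channelgate.msm import (ck_test, cluster_states, estimate_msm,
                             pairwise_rmsd, representative_ensemble,
                             stationary_from_transition)
from channelgate.synthetic import basin_centroids, generate_jump_labels
from oracles import (brute_force_min_rmsd, power_iteration_pi,
                     second_order_labels)


class TestPairwiseRmsd:
    def test_identity_and_rigid_motion(self, rng):
        pts = rng.normal(size=(10, 3)) * 4
        assert pairwise_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-9)
        from channelgate.geometry import rotation_about_axis
        moved = pts @ rotation_about_axis([1, 2, 3], 75.0).T + 8.0
        assert pairwise_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom(self, rng):
        pts = rng.normal(size=(25, 3)) * 6
        moved = pts.copy()
        moved[0] += [3.0, 0.0, 0.0]
        # before refitting, one atom displaced by 3 gives 3/sqrt(N)
        raw = np.sqrt(np.mean(np.sum((pts - moved) ** 2, axis=1)))
        assert raw == pytest.approx(3 / np.sqrt(25))
        fitted = pairwise_rmsd(pts, moved)
        assert fitted <= raw
        assert fitted == pytest.approx(brute_force_min_rmsd(pts, moved), abs=0.01)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(3):
            a = rng.normal(size=(10, 3)) * 3
            b = a + rng.normal(0, 0.8, size=a.shape)
            assert pairwise_rmsd(a, b) == pytest.approx(
                brute_force_min_rmsd(a, b), abs=0.01)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            pairwise_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestClusterStates:
    def test_two_well_separated_basins_exact(self, compact_base, topology, rng):
        centroids = basin_centroids(compact_base, topology, [0.0, 30.0])
        truth = rng.integers(2, size=400)
        coords = centroids[truth] + rng.normal(0, 0.2, size=(400,) + centroids.shape[1:])
        result = cluster_states(coords, n_states=2, seed=1)
        # oracle: brute-force nearest-medoid assignment must agree
        agree = max(np.mean(result.labels == truth),
                    np.mean(result.labels == 1 - truth))
        assert agree == 1.0

    def test_six_basins_recovered(self, compact_base, topology, rng):
        from sklearn.metrics import adjusted_rand_score
        centroids = basin_centroids(
            compact_base, topology, [0, 9, 18, 27, 36, 45])
        truth = rng.integers(6, size=900)
        coords = (centroids[truth]
                  + rng.normal(0, 0.25, size=(900,) + centroids.shape[1:]))
        result = cluster_states(coords, n_states=6, seed=3, max_landmarks=300)
        assert adjusted_rand_score(truth, result.labels) > 0.95

    def test_identical_frames_rejected(self, compact_base):
        coords = np.repeat(compact_base.coords[None], 20, axis=0)
        with pytest.raises(InputError):
            cluster_states(coords, n_states=3, seed=0)

    def test_fewer_frames_than_states_rejected(self, compact_base):
        coords = np.repeat(compact_base.coords[None], 3, axis=0)
        with pytest.raises(InputError):
            cluster_states(coords, n_states=6, seed=0)


class TestEstimateMsm:
    def test_symmetric_two_state_uniform_stationary(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        labels = generate_jump_labels(T, 100_000, seed=4)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        np.testing.assert_allclose(model.stationary_distribution, [0.5, 0.5],
                                   atol=0.02)

    def test_three_state_recovery_against_power_iteration(self):
        T = np.array([[0.80, 0.15, 0.05],
                      [0.10, 0.70, 0.20],
                      [0.25, 0.25, 0.50]])
        labels = generate_jump_labels(T, 100_000, seed=5)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        np.testing.assert_allclose(model.transition_matrix, T, atol=0.02)
        # pi compared against the TRUE chain's power-iteration fixed point
        np.testing.assert_allclose(model.stationary_distribution,
                                   power_iteration_pi(T), atol=0.01)

    def test_row_stochastic_and_stationary_invariants(self):
        T = np.array([[0.7, 0.2, 0.1], [0.3, 0.6, 0.1], [0.2, 0.2, 0.6]])
        labels = generate_jump_labels(T, 30_000, seed=6)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        np.testing.assert_allclose(model.transition_matrix.sum(axis=1), 1.0,
                                   atol=1e-10)
        pi = model.stationary_distribution
        np.testing.assert_allclose(pi @ model.transition_matrix, pi, atol=1e-10)
        assert pi.min() >= 0 and pi.sum() == pytest.approx(1.0)

    def test_net_flux_antisymmetric(self):
        T = np.array([[0.8, 0.15, 0.05], [0.05, 0.9, 0.05], [0.3, 0.1, 0.6]])
        labels = generate_jump_labels(T, 30_000, seed=7)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        np.testing.assert_allclose(model.net_flux_matrix,
                                   -model.net_flux_matrix.T, atol=1e-12)

    def test_implied_timescale_lag_invariance_for_markov_chain(self):
        T = np.array([[0.95, 0.05], [0.05, 0.95]])
        labels = generate_jump_labels(T, 200_000, seed=8)
        m1 = estimate_msm(labels, 10.0, lag_ns=0.01, n_states=2)
        m2 = estimate_msm(labels, 10.0, lag_ns=0.02, n_states=2)
        t1, t2 = m1.implied_timescales_ns[0], m2.implied_timescales_ns[0]
        assert t2 == pytest.approx(t1, rel=0.1)

    def test_non_multiple_lag_rejected(self):
        with pytest.raises(InputError):
            estimate_msm([0, 1, 0], 10.0, lag_ns=0.015)

    def test_disconnected_states_flagged(self):
        labels = np.array([0, 1] * 500 + [2, 3] * 500)
        with pytest.warns(UserWarning, match="disconnected"):
            model = estimate_msm(labels, 10.0, lag_ns=0.01,
                                 segment_lengths=[1000, 1000])
        assert not model.is_connected
        assert model.stationary_distribution.sum() == pytest.approx(1.0)

    def test_counts_respect_segment_boundaries(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        model = estimate_msm(labels, 10.0, lag_ns=0.01,
                             segment_lengths=[3, 3])
        # no 0 -> 1 transition across the segment boundary
        assert model.count_matrix[0, 1] == 0
        assert model.count_matrix[0, 0] == 2
        assert model.count_matrix[1, 1] == 2


class TestCkTest:
    def test_k_equals_one_is_exact(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        labels = generate_jump_labels(T, 50_000, seed=9)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        report = ck_test(model, ks=[1])
        assert report.max_deviation[1] == pytest.approx(0.0, abs=1e-12)

    def test_markov_chain_passes(self):
        T = np.array([[0.85, 0.1, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        labels = generate_jump_labels(T, 100_000, seed=10)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        report = ck_test(model, ks=[2, 3, 4, 5], tol=0.1)
        assert report.all_passed
        assert max(report.max_deviation.values()) < 0.05

    def test_second_order_process_fails(self):
        labels = second_order_labels(100_000, seed=11)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        report = ck_test(model, ks=[2], tol=0.1)
        assert not report.passed[2]
        assert report.max_deviation[2] > 0.2

    def test_insufficient_frames_skipped(self):
        labels = np.array([0, 1, 0, 1, 0, 1])
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        with pytest.warns(UserWarning, match="skipped"):
            report = ck_test(model, ks=[10])
        assert report.skipped == [10]


class TestRepresentativeEnsemble:
    def _model(self, n=600):
        labels = np.tile([0, 0, 0, 1, 1, 2], n // 6)
        return estimate_msm(labels, 10.0, lag_ns=0.01)

    def test_draws_are_unique_and_reproducible(self):
        model = self._model()
        a = representative_ensemble(model, n=50, seed=42)
        b = representative_ensemble(model, n=50, seed=42)
        for state in range(3):
            assert len(a[state]) == 50
            assert len(np.unique(a[state])) == 50
            np.testing.assert_array_equal(a[state], b[state])
            assert np.all(model.labels[a[state]] == state)

    def test_small_state_exhausted(self):
        labels = np.array([0] * 100 + [1] * 10)
        model = estimate_msm(labels, 10.0, lag_ns=0.01)
        ens = representative_ensemble(model, n=50, seed=0)
        assert len(ens[1]) == 10

    def test_different_seeds_differ(self):
        model = self._model()
        a = representative_ensemble(model, n=50, seed=1)
        b = representative_ensemble(model, n=50, seed=2)
        assert not np.array_equal(a[0], b[0])


class TestStationaryOracle:
    def test_eigenvector_matches_power_iteration(self):
        rng = np.random.default_rng(13)
        T = rng.random((5, 5)) + 0.1
        T /= T.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(stationary_from_transition(T),
                                   power_iteration_pi(T), atol=1e-10)
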