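"""Superposition, twist/lift recovery, termini distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_force_min_rmsd

from channelgate.errors import ConfigurationError, GeometryError
from channelgate.geometry import rotation_about_axis, superpose
from channelgate.kinematics import termini_distances, twist_series
from channelgate.synthetic import (GeneratorSpec, generate_trajectory,
                                   make_preset)
from channelgate.trajectory import Trajectory


class TestSuperpose:
    def test_self_superposition_identity(self, rng):
        pts = rng.normal(size=(12, 3))
        R, t, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_constructed_rotation(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        R_true = rotation_about_axis([0, 0, 1], 30.0)
        moved = pts @ R_true.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = superpose(pts, moved)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R, R_true, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_noisy_copy_matches_brute_force_oracle(self, rng):
        pts = rng.normal(size=(10, 3)) * 4
        noisy = pts @ rotation_about_axis([1, 1, 0], 40.0).T
        noisy = noisy + rng.normal(0, 0.1, size=pts.shape)
        _, _, rmsd = superpose(pts, noisy)
        oracle = brute_force_min_rmsd(pts, noisy)
        assert rmsd == pytest.approx(oracle, abs=0.01)
        assert rmsd < 0.25  # sigma = 0.1 regime

    def test_degenerate_input_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError):
            superpose(line, line)
        with pytest.raises(GeometryError):
            superpose(np.zeros((4, 3)), np.zeros((4, 3)))


class TestTwistSeries:
    @pytest.fixture()
    def noiseless(self, topology, base):
        def run(angles, block="ATD+LBD", lift=None):
            spec = GeneratorSpec(seed=3, n_frames=len(angles),
                                 twist_block=block,
                                 twist_deg=np.asarray(angles, dtype=float),
                                 lift_deg=lift, noise_sigma=0.0)
            traj, _ = generate_trajectory(spec, base, topology)
            return twist_series(traj, topology, block=block, reference_frame=0)
        return run

    def test_reference_frame_is_zero(self, noiseless):
        result = noiseless([0.0, 20.0])
        assert result.twist_deg[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("theta", [-170.0, -45.0, 0.5, 10.0, 45.0, 179.0])
    def test_exact_recovery_of_programmed_rotation(self, noiseless, theta):
        """Noiseless programmed twists recover to < 0.01 degrees."""
        result = noiseless([0.0, theta])
        assert result.twist_deg[1] == pytest.approx(theta, abs=0.01)

    def test_additivity_of_coaxial_rotations(self, noiseless):
        result = noiseless([0.0, 25.0, 70.0])
        ab = result.twist_deg[1]
        ac = result.twist_deg[2]
        bc_direct = noiseless([25.0, 70.0]).twist_deg[1]
        assert ab + bc_direct == pytest.approx(ac, abs=0.02)

    def test_invariant_under_global_rigid_motion(self, topology, base, rng):
        spec = GeneratorSpec(seed=3, n_frames=3,
                             twist_deg=np.array([0.0, 12.0, 30.0]),
                             noise_sigma=0.0)
        traj, _ = generate_trajectory(spec, base, topology)
        moved = traj.coords.copy()
        for f in range(1, 3):
            R = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
            moved[f] = moved[f] @ R.T + rng.uniform(-20, 20, 3)
        traj2 = Trajectory(moved, traj.catalog, traj.frame_interval_ps)
        a = twist_series(traj, topology)
        b = twist_series(traj2, topology)
        np.testing.assert_allclose(a.twist_deg, b.twist_deg, atol=1e-6)
        np.testing.assert_allclose(a.lift_deg, b.lift_deg, atol=1e-6)

    def test_lift_recovery(self, noiseless):
        result = noiseless(np.zeros(3), block="ATD",
                           lift=np.array([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(result.lift_deg, [0.0, 5.0, 10.0], atol=0.05)

    def test_relaxation_schedule_recovered_with_noise(self, topology):
        spec, base, top = make_preset("relaxation", seed=2, n_frames=120)
        traj, truth = generate_trajectory(spec, base, top)
        result = twist_series(traj, top, block="ATD")
        assert result.twist_deg[-1] == pytest.approx(truth["twist_deg"][-1], abs=1.0)
        assert result.lift_deg[-1] == pytest.approx(truth["lift_deg"][-1], abs=1.0)

    def test_block_overlapping_alignment_rejected(self, topology, base):
        spec = GeneratorSpec(seed=3, n_frames=2, noise_sigma=0.0)
        traj, _ = generate_trajectory(spec, base, topology)
        with pytest.raises(ConfigurationError):
            twist_series(traj, topology, block="TMD")


class TestTerminiDistances:
    def test_translation_invariance(self, topology, base):
        spec = GeneratorSpec(seed=6, n_frames=3, noise_sigma=0.0)
        traj, _ = generate_trajectory(spec, base, topology)
        shifted = Trajectory(traj.coords + np.array([5.0, -3.0, 11.0]),
                             traj.catalog, traj.frame_interval_ps)
        a, b = termini_distances(traj, topology), termini_distances(shifted, topology)
        np.testing.assert_allclose(a.d_glun2b_glun2b, b.d_glun2b_glun2b, atol=1e-9)
        np.testing.assert_allclose(a.d_neighbor_ab, b.d_neighbor_ab, atol=1e-9)

    def test_hand_computed_distances(self, topology, base):
        spec = GeneratorSpec(seed=6, n_frames=1, noise_sigma=0.0)
        traj, _ = generate_trajectory(spec, base, topology)
        idx = traj.catalog.resolve_many(topology.terminus_selectors())
        expected_bd = np.linalg.norm(traj.coords[0, idx[1]] - traj.coords[0, idx[3]])
        series = termini_distances(traj, topology)
        assert series.d_glun2b_glun2b[0] == pytest.approx(expected_bd)

    def test_opening_drift_shortens_glun2b_pair(self, topology):
        spec, base, top = make_preset("opening", seed=9, n_frames=250)
        traj, _ = generate_trajectory(spec, base, top)
        series = termini_distances(traj, top)
        shrink_bb = series.d_glun2b_glun2b[0] - series.d_glun2b_glun2b[-1]
        drift_ab = abs(series.d_neighbor_ab[0] - series.d_neighbor_ab[-1])
        assert shrink_bb > 5.0
        assert drift_ab < 0.5 * shrink_bb  # neighbour pairs near-constant
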