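"""Gate distances, mode detection, open probability, hydration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from channelgate.errors import ConfigurationError, InputError
from channelgate.gates import (GateDistanceSeries, asymmetry_index,
                               ca_distance, detect_modes, gate_series,
                               open_probability, pore_hydration)
from channelgate.synthetic import (GateModel, GeneratorSpec,
                                   default_open_gate_model,
                                   generate_trajectory, make_preset,
                                   sample_gate_model)
from channelgate.topology import ResidueSelector
from channelgate.trajectory import AtomCatalog


def _toy_catalog():
    return AtomCatalog(
        chain_role=np.array(["GluN1_A", "GluN1_C"], dtype="<U8"),
        chain_id=np.array(["A", "C"]),
        residue_number=np.array([648, 648]),
        residue_name=np.array(["THR", "THR"]),
        atom_name=np.array(["CA", "CA"]),
    )


class TestCaDistance:
    def test_coincident_points_zero(self):
        frame = np.zeros((2, 3))
        a = ResidueSelector("GluN1_A", 648)
        b = ResidueSelector("GluN1_C", 648)
        assert ca_distance(frame, _toy_catalog(), a, b) == 0.0

    def test_pythagorean_triple(self):
        frame = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        a = ResidueSelector("GluN1_A", 648)
        b = ResidueSelector("GluN1_C", 648)
        assert ca_distance(frame, _toy_catalog(), a, b) == pytest.approx(5.0)
        assert ca_distance(frame, _toy_catalog(), b, a) == pytest.approx(5.0)


class TestGateSeries:
    def test_closed_state_glun2b_below_glun1(self, topology):
        spec, base, top = make_preset("closing", seed=8, n_frames=60)
        traj, _ = generate_trajectory(spec, base, top)
        series = gate_series(traj, top, "TTTT")
        assert np.all(series.d_glun2b < series.d_glun1)
        assert np.all(asymmetry_index(series) > 0)

    def test_open_state_glun2b_elevated(self, topology):
        spec, base, top = make_preset("opening", seed=8, n_frames=200)
        traj, _ = generate_trajectory(spec, base, top)
        series = gate_series(traj, top, "TTTT")
        assert series.d_glun2b.mean() > 12.0  # separated O2 diagonal
        assert series.d_glun1.std() > 1.0     # oscillating bimodal GluN1

    def test_hand_placed_frame(self, topology, base):
        spec = GeneratorSpec(seed=0, n_frames=1, noise_sigma=0.0,
                             gate_models={("TTTT", "GluN1"):
                                          GateModel("normal", mu=9.0, sigma=0.0)})
        traj, _ = generate_trajectory(spec, base, topology)
        series = gate_series(traj, topology, "TTTT")
        assert series.d_glun1[0] == pytest.approx(9.0, abs=1e-9)
        assert series.d_glun2b[0] == pytest.approx(2 * base.pore_radius, abs=1e-9)

    def test_unknown_gate_rejected(self, topology, base):
        spec = GeneratorSpec(seed=0, n_frames=1, noise_sigma=0.0)
        traj, _ = generate_trajectory(spec, base, topology)
        with pytest.raises(ConfigurationError):
            gate_series(traj, topology, "XXXX")


class TestDetectModes:
    def test_bimodal_recovery(self):
        x = sample_gate_model(default_open_gate_model(), 15000, seed=7)
        report = detect_modes(x, bandwidth=0.5)
        assert report.n_modes == 2
        assert report.modes[0] == pytest.approx(8.5, abs=0.2)
        assert report.modes[1] == pytest.approx(11.5, abs=0.2)
        assert report.weights[0] == pytest.approx(0.5, abs=0.05)

    def test_degenerate_constant_series(self):
        report = detect_modes(np.full(500, 9.0))
        assert report.n_modes == 1
        assert report.modes[0] == 9.0
        assert report.weights[0] == 1.0

    def test_unequal_weights_recovered_against_labels(self, rng):
        labels = rng.random(20000) < 0.3
        x = np.where(labels, rng.normal(6.0, 0.4, 20000),
                     rng.normal(12.0, 0.4, 20000))
        report = detect_modes(x, bandwidth=0.4)
        # oracle: component masses from the known labels
        truth = np.array([labels.mean(), 1 - labels.mean()])
        assert report.n_modes == 2
        np.testing.assert_allclose(report.weights, truth, atol=0.05)

    def test_single_gaussian_mode_location(self, rng):
        x = rng.normal(10.0, 0.8, 5000)
        report = detect_modes(x, bandwidth=0.5)
        tol = 5 * 0.8 / np.sqrt(5000) + 0.05  # sampling + grid resolution
        assert abs(report.modes[np.argmax(report.weights)] - 10.0) < tol

    def test_weights_sum_to_one(self, rng):
        x = np.concatenate([rng.normal(7, 0.5, 400), rng.normal(12, 1.5, 700)])
        report = detect_modes(x)
        assert report.weights.sum() == pytest.approx(1.0)
        assert np.all(np.diff(report.modes) > 0)

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            detect_modes([])


class TestOpenProbability:
    def test_threshold_extremes(self, rng):
        x = rng.normal(10, 1, 300)
        assert open_probability(x, 0.0) == 1.0
        assert open_probability(x, x.max() + 1) == 0.0

    def test_equal_mixture_at_intermode_minimum(self):
        x = sample_gate_model(default_open_gate_model(), 15000, seed=7)
        report = detect_modes(x, bandwidth=0.5)
        p = open_probability(x, report.minima[0])
        assert p == pytest.approx(0.5, abs=0.02)

    def test_both_diagonals_required(self):
        series = GateDistanceSeries(
            "TTTT", np.array([11.0, 11.0, 9.0]), np.array([11.0, 9.0, 11.0]),
            np.arange(3.0))
        assert open_probability(series, 10.0) == pytest.approx(1 / 3)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 30.0), min_size=1, max_size=200),
           st.floats(0.0, 30.0), st.floats(0.0, 5.0))
    def test_monotone_nonincreasing_in_threshold(self, values, t, dt):
        assert (open_probability(values, t + dt)
                <= open_probability(values, t))


class TestAsymmetryIndex:
    def test_exact_antisymmetry(self, rng):
        d1 = rng.uniform(5, 15, 50)
        d2 = rng.uniform(5, 15, 50)
        t = np.arange(50.0)
        fwd = asymmetry_index(GateDistanceSeries("TTTT", d1, d2, t))
        rev = asymmetry_index(GateDistanceSeries("TTTT", d2, d1, t))
        np.testing.assert_array_equal(fwd, -rev)

    def test_symmetric_frame_near_zero(self):
        series = GateDistanceSeries("TTTT", np.array([9.0]), np.array([9.0]),
                                    np.array([0.0]))
        assert asymmetry_index(series)[0] == 0.0


class TestPoreHydration:
    def test_waters_below_gate_do_not_count(self, topology, base):
        spec = GeneratorSpec(seed=5, n_frames=4, noise_sigma=0.05,
                             water_mode="below_TTTT_only")
        traj, _ = generate_trajectory(spec, base, topology)
        report = pore_hydration(traj, topology, radius=6.0)
        assert np.all(report.counts == 0)

    def test_water_at_cylinder_midpoint_counts(self, topology, base):
        tttt = base.catalog.resolve_many(topology.gate_selectors("TTTT"))
        lili = base.catalog.resolve_many(topology.gate_selectors("LILI"))
        mid = (base.coords[tttt].mean(axis=0) + base.coords[lili].mean(axis=0)) / 2
        spec = GeneratorSpec(seed=5, n_frames=2, noise_sigma=0.0,
                             water_mode="custom", water_coords=mid[None])
        traj, _ = generate_trajectory(spec, base, topology)
        report = pore_hydration(traj, topology, radius=5.0)
        assert np.all(report.counts == 1)

    def test_matches_exhaustive_scan(self, topology, base, rng):
        waters = rng.uniform([-10, -10, 10], [10, 10, 60], size=(40, 3))
        spec = GeneratorSpec(seed=5, n_frames=3, noise_sigma=0.3,
                             water_mode="custom", water_coords=waters)
        traj, _ = generate_trajectory(spec, base, topology)
        radius = 6.0
        report = pore_hydration(traj, topology, radius=radius)

        # oracle: frame-by-frame, water-by-water re-count
        tttt = traj.catalog.resolve_many(topology.gate_selectors("TTTT"))
        lili = traj.catalog.resolve_many(topology.gate_selectors("LILI"))
        for f in range(traj.n_frames):
            c1 = traj.coords[f, tttt].mean(axis=0)
            c2 = traj.coords[f, lili].mean(axis=0)
            u = (c2 - c1) / np.linalg.norm(c2 - c1)
            count = 0
            for w in traj.water_indices:
                rel = traj.coords[f, w] - c1
                t = float(rel @ u)
                if 0 < t < np.linalg.norm(c2 - c1):
                    if np.linalg.norm(rel - t * u) <= radius:
                        count += 1
            assert report.counts[f] == count

    def test_no_waters_rejected(self, topology, base):
        spec = GeneratorSpec(seed=5, n_frames=2, noise_sigma=0.0)
        traj, _ = generate_trajectory(spec, base, topology)
        with pytest.raises(InputError):
            pore_hydration(traj, topology)
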