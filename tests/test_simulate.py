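"""Simulator: Brownian step statistics, detection model, noise chain, determinism."""

import numpy as np
import pytest

import fccs
from fccs.datatypes import EmissionSpectrum, IntensityTrace
from fccs.simulate import ParticleTrajectories, child_seeds


def minimum_image_steps(path, half_width):
    """Per-axis displacement steps, unwrapped across the periodic boundary."""
    delta = np.diff(path.astype(float), axis=0)
    span = 2.0 * half_width
    return delta - span * np.rint(delta / span)


class TestPositions:
    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="beam_waist"):
            fccs.SimulationConfig(beam_waist=-1.0)
        with pytest.raises(ValueError, match="box_half_width"):
            fccs.SimulationConfig(box_half_width=0.5)
        with pytest.raises(ValueError, match="mean_free_a"):
            fccs.SimulationConfig(mean_free_a=-2.0)

    def test_zero_means_give_empty_system(self):
        cfg = fccs.SimulationConfig(mean_free_a=0, mean_free_b=0, mean_complex=0,
                                    n_frames=10)
        traj = fccs.simulate_positions(cfg)
        assert all(n == 0 for n in traj.counts().values())

    def test_zero_diffusion_freezes_particles(self):
        cfg = fccs.SimulationConfig(diff_a=0.0, mean_free_a=5, n_frames=50, seed=3)
        traj = fccs.simulate_positions(cfg)
        path = traj.positions["free_a"]
        assert path.shape[1] > 0
        assert np.all(path == path[0])

    def test_step_variance_matches_2_d_dt(self):
        # D = 0.5 um^2/s, dt = 1.3 ms -> per-axis step variance 1.3e-3 um^2
        cfg = fccs.SimulationConfig(mean_free_a=10, mean_free_b=0, mean_complex=0,
                                    diff_a=0.5, frame_interval=1.3e-3,
                                    n_frames=1200, seed=11)
        traj = fccs.simulate_positions(cfg)
        steps = minimum_image_steps(traj.positions["free_a"], cfg.box_half_width)
        assert steps.size >= 2e5
        measured = steps.astype(np.float64).var()
        expected = 2.0 * cfg.diff_a * cfg.frame_interval
        assert measured == pytest.approx(expected, rel=0.02)

    def test_positions_stay_in_box(self):
        cfg = fccs.SimulationConfig(n_frames=200, seed=5)
        traj = fccs.simulate_positions(cfg)
        L = cfg.box_half_width
        for path in traj.positions.values():
            if path.size:
                assert path.min() >= -L and path.max() <= L

    def test_poisson_particle_numbers(self):
        cfg = fccs.SimulationConfig(mean_free_a=4.0, mean_free_b=0, mean_complex=0,
                                    n_frames=2)
        lam = cfg.mean_free_a * cfg.area_ratio
        rng = np.random.default_rng(7)
        counts = [fccs.simulate_positions(cfg, rng=rng).counts()["free_a"]
                  for _ in range(220)]
        sem = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * sem


class TestTraces:
    def test_empty_system_gives_zero_traces(self):
        cfg = fccs.SimulationConfig(mean_free_a=0, mean_free_b=0, mean_complex=0,
                                    n_frames=10)
        ta, tb = fccs.traces_from_positions(fccs.simulate_positions(cfg))
        assert np.all(ta.values == 0) and np.all(tb.values == 0)

    def test_immobile_molecule_at_center(self):
        cfg = fccs.SimulationConfig(brightness_a=5.0, n_frames=8)
        pos = {
            "free_a": np.zeros((8, 1, 2), dtype=np.float32),
            "free_b": np.zeros((8, 0, 2), dtype=np.float32),
            "complex": np.zeros((8, 0, 2), dtype=np.float32),
        }
        ta, tb = fccs.traces_from_positions(ParticleTrajectories(pos, cfg))
        np.testing.assert_allclose(ta.values, 5.0, rtol=1e-12)
        assert np.all(tb.values == 0)

    def test_complexes_light_up_both_channels(self):
        cfg = fccs.SimulationConfig(brightness_a=4.0, brightness_b=2.0, n_frames=4)
        pos = {
            "free_a": np.zeros((4, 0, 2), dtype=np.float32),
            "free_b": np.zeros((4, 0, 2), dtype=np.float32),
            "complex": np.zeros((4, 1, 2), dtype=np.float32),
        }
        ta, tb = fccs.traces_from_positions(ParticleTrajectories(pos, cfg))
        np.testing.assert_allclose(ta.values, 4.0)
        np.testing.assert_allclose(tb.values, 2.0)

    def test_frame_count_mismatch_rejected(self):
        cfg = fccs.SimulationConfig(n_frames=6)
        pos = {
            "free_a": np.zeros((4, 1, 2), dtype=np.float32),
            "free_b": np.zeros((6, 0, 2), dtype=np.float32),
            "complex": np.zeros((6, 0, 2), dtype=np.float32),
        }
        with pytest.raises(ValueError, match="frame count"):
            fccs.traces_from_positions(ParticleTrajectories(pos, cfg), cfg)


class TestSpectralFrames:
    def test_linear_mixing_noise_free(self):
        cfg = fccs.SimulationConfig(n_frames=3, n_bins=2, background=0.0)
        spectrum = EmissionSpectrum("A", np.array([0.25, 0.75]))
        trace = IntensityTrace("A", np.full(3, 4.0), cfg.frame_interval)
        scan = fccs.spectral_frames_from_traces([trace], [spectrum], cfg, noise=False)
        np.testing.assert_allclose(scan.counts, np.tile([1.0, 3.0], (3, 1)))

    def test_zero_input_zero_output(self):
        cfg = fccs.SimulationConfig(n_frames=5, background=0.0, read_noise_sd=0.0)
        spectra = fccs.default_spectra(cfg.n_bins)
        traces = [IntensityTrace(s.fluorophore, np.zeros(5), cfg.frame_interval)
                  for s in spectra]
        scan = fccs.spectral_frames_from_traces(traces, spectra, cfg, noise=True)
        assert np.all(scan.counts == 0)

    def test_noise_chain_preserves_means(self):
        cfg = fccs.SimulationConfig(n_frames=12000, n_bins=4, background=0.2,
                                    em_gain=250.0, read_noise_sd=2.0, seed=9)
        spectrum = EmissionSpectrum("A", np.array([0.1, 0.4, 0.4, 0.1]))
        trace = IntensityTrace("A", np.full(cfg.n_frames, 6.0), cfg.frame_interval)
        expected = 6.0 * spectrum.weights + cfg.background
        scan = fccs.spectral_frames_from_traces([trace], [spectrum], cfg, noise=True)
        mean = scan.counts.mean(axis=0) / cfg.em_gain
        var = (cfg.em_gain**2 * expected + cfg.read_noise_sd**2) / cfg.em_gain**2
        sem = np.sqrt(var / cfg.n_frames)
        assert np.all(np.abs(mean - expected) < 3 * sem)

    def test_bin_grid_mismatch_rejected(self):
        cfg = fccs.SimulationConfig(n_frames=3, n_bins=4)
        spectra = [EmissionSpectrum("A", np.ones(4)), EmissionSpectrum("B", np.ones(3))]
        traces = [IntensityTrace(s.fluorophore, np.ones(3), cfg.frame_interval)
                  for s in spectra]
        with pytest.raises(ValueError, match="bin grid"):
            fccs.spectral_frames_from_traces(traces, spectra, cfg)


class TestCondition:
    def test_same_master_seed_is_bitwise_identical(self):
        cfg = fccs.SimulationConfig(n_frames=300)
        a = fccs.simulate_condition(cfg, 3, master_seed=42)
        b = fccs.simulate_condition(cfg, 3, master_seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_different_master_seeds_differ(self):
        cfg = fccs.SimulationConfig(n_frames=300)
        a = fccs.simulate_condition(cfg, 1, master_seed=1)
        b = fccs.simulate_condition(cfg, 1, master_seed=2)
        assert not np.array_equal(a[0].counts, b[0].counts)

    def test_child_seeds_fit_in_31_bits(self):
        seeds = child_seeds(123456789, 50)
        assert len(set(seeds)) == 50
        assert all(0 <= s < 2**31 for s in seeds)
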