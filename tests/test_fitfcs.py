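"""Diffusion-model fitting: exact recovery, identities, fallbacks, SE scaling."""

import numpy as np
import pytest

import fccs
from fccs.correlate import CorrelationCurve, correlate, multitau_lags
from fccs.fitfcs import diffusion_model, fit_correlation, fit_scan


def model_curve(g0=0.5, tau_d=0.010, baseline=0.0, kind="auto", ids=("A", "A"), n=40):
    tau = np.geomspace(1e-4, 1.0, n)
    return CorrelationCurve(lags=tau, g=diffusion_model(tau, g0, tau_d, baseline),
                            kind=kind, ids=ids)


class TestFitCorrelation:
    def test_exact_recovery_on_model_member(self):
        fit = fit_correlation(model_curve(g0=0.5, tau_d=0.010), baseline_mode="fixed0")
        assert fit.converged
        assert fit.g0 == pytest.approx(0.5, abs=1e-6)
        assert fit.tau_d == pytest.approx(0.010, abs=1e-6)

    def test_fixed1_recovers_offset_convention(self):
        fit = fit_correlation(model_curve(g0=0.3, tau_d=0.02, baseline=1.0),
                              baseline_mode="fixed1")
        assert fit.baseline == 1.0
        assert fit.g0 == pytest.approx(0.3, abs=1e-6)
        assert fit.tau_d == pytest.approx(0.02, abs=1e-6)

    def test_free_baseline_recovery(self):
        fit = fit_correlation(model_curve(g0=0.4, tau_d=0.005, baseline=0.07),
                              baseline_mode="free")
        assert fit.baseline == pytest.approx(0.07, abs=1e-5)
        assert fit.g0 == pytest.approx(0.4, abs=1e-5)

    def test_half_decay_identity(self):
        rng = np.random.default_rng(2)
        curve = model_curve(g0=0.6, tau_d=0.015)
        noisy = CorrelationCurve(lags=curve.lags,
                                 g=curve.g + rng.normal(0, 0.01, curve.g.size),
                                 kind="auto", ids=("A", "A"))
        fit = fit_correlation(noisy)
        # at tau = tau_D the fitted model sits exactly halfway down
        assert fit.model(np.array([fit.tau_d]))[0] - fit.baseline == pytest.approx(
            fit.g0 / 2, rel=1e-12)

    def test_pathological_curve_flagged_not_garbage(self):
        tau = np.geomspace(1e-3, 1.0, 12)
        rising = CorrelationCurve(lags=tau, g=np.linspace(0.0, 1.0, 12),
                                  kind="auto", ids=("A", "A"))
        fit = fit_correlation(rising)
        assert isinstance(fit.converged, bool)
        assert np.isfinite(fit.g0) and fit.tau_d > 0

    def test_too_few_points_rejected(self):
        tau = np.array([1e-3, 2e-3, 4e-3])
        curve = CorrelationCurve(lags=tau, g=np.ones(3) * 0.1, kind="auto", ids=("A", "A"))
        with pytest.raises(ValueError, match="lag points"):
            fit_correlation(curve)

    def test_short_overlap_lags_trimmed(self):
        tau = np.geomspace(1e-3, 1.0, 20)
        curve = CorrelationCurve(lags=tau, g=diffusion_model(tau, 0.5, 0.01),
                                 kind="auto", ids=("A", "A"),
                                 n_samples=np.r_[np.full(15, 1000), np.full(5, 10)])
        fit = fit_correlation(curve)
        assert fit.n_points == 15

    def test_standard_errors_shrink_with_trace_length(self):
        # quadrupling the trace length should shrink SE(G0) ~2x (within 1.5x)
        scheme = multitau_lags(16384, 1.0 / 769.0)  # same design for both lengths

        def mean_se(n_frames, seed):
            cfg = fccs.SimulationConfig(mean_free_a=5, mean_free_b=0, mean_complex=0,
                                        diff_a=1.0, n_frames=n_frames, seed=seed)
            ses = []
            for pair in fccs.simulate_condition_traces(cfg, 8, master_seed=seed):
                curve = correlate(pair[0], pair[0], scheme)
                ses.append(fit_correlation(curve).se_g0)
            return np.mean(ses)

        ratio = mean_se(16384, seed=5) / mean_se(65536, seed=6)
        assert 2.0 / 1.5 < ratio < 2.0 * 1.5


class TestFitScan:
    def test_recovers_all_three_model_curves(self):
        curves = [
            model_curve(0.1, 0.015, ids=("A", "A")),
            model_curve(0.2, 0.015, ids=("B", "B")),
            model_curve(0.06, 0.04, kind="cross", ids=("A", "B")),
        ]
        fits = fit_scan(curves)
        assert fits.auto_a.g0 == pytest.approx(0.1, abs=1e-6)
        assert fits.auto_b.g0 == pytest.approx(0.2, abs=1e-6)
        assert fits.cross.g0 == pytest.approx(0.06, abs=1e-6)
        assert fits.cross.tau_d == pytest.approx(0.04, abs=1e-5)

    def test_flat_cross_curve_yields_null_amplitude(self):
        rng = np.random.default_rng(9)
        tau = np.geomspace(1e-3, 1.0, 30)
        flat = CorrelationCurve(lags=tau, g=rng.normal(0, 1e-3, 30),
                                kind="cross", ids=("A", "B"))
        fit = fit_correlation(flat)
        assert abs(fit.g0) < 2 * (fit.se_g0 or np.inf) or abs(fit.g0) < 1e-3

    def test_missing_curve_kind_rejected(self):
        curves = [model_curve(ids=("A", "A")), model_curve(ids=("B", "B"))]
        with pytest.raises(ValueError, match="cross"):
            fit_scan(curves)

    def test_complexes_slow_the_cross_correlation(self, variant_condition):
        # complexes diffuse at 0.4 vs 1.0 um^2/s: the cross dwell time should
        # exceed the channel-A auto dwell time in >= 90% of scans
        results, _ = variant_condition
        usable = [r for r in results if r.usable]
        slower = np.mean([r.tau_d_cross > r.tau_d_auto_a for r in usable])
        assert slower >= 0.9
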