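"""Fitting correlation curves to the 2D Brownian diffusion model.

The model for diffusion of membrane-bound molecules through a Gaussian
spot is the hyperbolic decay

    G_fit(tau) = baseline + G0 / (1 + tau / tau_D),

where ``G0`` is the correlation amplitude (1/N_eff for an
autocorrelation of a single species) and ``tau_D = w**2 / (4 D)`` is
the dwell time. The baseline is fixed at 0 by default, matching the
fluctuation correlation estimator which decays to zero; it can be fixed
at 1 (for correlations reported on a +1 offset convention) or fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import lmfit
import numpy as np

from .correlate import CorrelationCurve

__all__ = ["CorrelationFit", "ScanFits", "diffusion_model", "fit_correlation", "fit_scan"]

MIN_OVERLAP = 64  # lags fitted must have at least this many overlapping samples
BASELINE_MODES = ("fixed0", "fixed1", "free")


def diffusion_model(tau: np.ndarray, g0: float, tau_d: float, baseline: float = 0.0) -> np.ndarray:
    """Hyperbolic 2D-diffusion correlation shape."""
    return baseline + g0 / (1.0 + np.asarray(tau, dtype=float) / tau_d)


@dataclass
class CorrelationFit:
    """Result of fitting one correlation curve."""

    g0: float
    tau_d: float
    baseline: float
    se_g0: Optional[float]
    se_tau_d: Optional[float]
    se_baseline: Optional[float]
    rss: float
    converged: bool
    n_points: int
    kind: str = ""
    ids: tuple[str, str] = ("", "")

    def model(self, tau: np.ndarray) -> np.ndarray:
        return diffusion_model(tau, self.g0, self.tau_d, self.baseline)


@dataclass
class ScanFits:
    """The three per-scan fits, labeled by channel."""

    auto_a: CorrelationFit
    auto_b: CorrelationFit
    cross: CorrelationFit
    id_a: str = "A"
    id_b: str = "B"


def _initial_guess(tau: np.ndarray, g: np.ndarray, baseline: float) -> tuple[float, float]:
    g0 = g[0] - baseline
    if g0 <= 0:
        g0 = max(abs(g0), 1e-6)
    # lag nearest half decay of the (possibly noisy) curve
    half = baseline + 0.5 * (g[0] - baseline)
    below = np.where(g <= half)[0]
    tau_d = tau[below[0]] if below.size else tau[len(tau) // 2]
    if tau_d <= 0:
        tau_d = tau[0]
    return float(g0), float(tau_d)


def _grid_init(tau: np.ndarray, g: np.ndarray, baseline_mode: str) -> tuple[float, float, float]:
    """Grid search over tau_D decades with per-grid linear G0 (and baseline) fit."""
    best = (np.inf, 1e-3, np.median(np.abs(g)) or 1e-6, 0.0)
    for tau_d in np.geomspace(tau[0] / 2.0, tau[-1] * 2.0, 41):
        shape = 1.0 / (1.0 + tau / tau_d)
        if baseline_mode == "free":
            design = np.column_stack([shape, np.ones_like(shape)])
            coef, _, _, _ = np.linalg.lstsq(design, g, rcond=None)
            g0, base = float(coef[0]), float(coef[1])
        else:
            base = 0.0 if baseline_mode == "fixed0" else 1.0
            y = g - base
            g0 = float((shape @ y) / (shape @ shape))
        rss = float(np.sum((g - (base + g0 * shape)) ** 2))
        if rss < best[0]:
            best = (rss, tau_d, g0, base)
    return best[1], best[2], best[3]


def fit_correlation(
    curve: CorrelationCurve,
    baseline_mode: str = "fixed0",
    init: Optional[tuple[float, float]] = None,
    weights: Optional[np.ndarray] = None,
) -> CorrelationFit:
    """Least-squares fit of a correlation curve to the 2D diffusion model.

    Non-convergence is flagged, never silent: the returned fit carries
    ``converged=False`` together with the best parameters found (a grid
    search over tau_D decades backs up the gradient optimizer on
    pathological curves).
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"baseline_mode must be one of {BASELINE_MODES}")
    tau = np.asarray(curve.lags, dtype=float)
    g = np.asarray(curve.g, dtype=float)
    if curve.n_samples is not None:
        keep = np.asarray(curve.n_samples) >= MIN_OVERLAP
        tau, g = tau[keep], g[keep]
        if weights is not None:
            weights = np.asarray(weights)[keep]
    n_free = 3 if baseline_mode == "free" else 2
    if tau.size < max(6, n_free):
        raise ValueError(f"need at least 6 lag points, got {tau.size}")
    if not np.all(np.isfinite(g)):
        raise ValueError("G values must be finite")

    base_fixed = {"fixed0": 0.0, "fixed1": 1.0}.get(baseline_mode)
    if init is not None:
        g0_init, tau_d_init = float(init[0]), float(init[1])
    else:
        g0_init, tau_d_init = _initial_guess(tau, g, base_fixed if base_fixed is not None else g[-1])

    # tau_d is only identifiable inside the sampled lag window; allowing it
    # below the first lag lets pure-noise curves extrapolate absurd amplitudes
    tau_lo, tau_hi = tau[0] / 2.0, tau[-1] * 2.0
    params = lmfit.Parameters()
    params.add("g0", value=g0_init)
    params.add("tau_d", value=min(max(tau_d_init, tau_lo), tau_hi), min=tau_lo, max=tau_hi)
    if baseline_mode == "free":
        params.add("baseline", value=float(g[-1]), vary=True)
    else:
        params.add("baseline", value=base_fixed, vary=False)

    def residual(p):
        r = g - diffusion_model(tau, p["g0"].value, p["tau_d"].value, p["baseline"].value)
        return r if weights is None else r * weights

    result = lmfit.minimize(residual, params, method="leastsq")
    converged = bool(result.success)
    if not converged or not result.errorbars:
        # fall back to grid-search initialization before giving up
        tau_d0, g00, base0 = _grid_init(tau, g, baseline_mode)
        params["g0"].value = g00
        params["tau_d"].value = min(max(tau_d0, params["tau_d"].min), params["tau_d"].max)
        if baseline_mode == "free":
            params["baseline"].value = base0
        retry = lmfit.minimize(residual, params, method="leastsq")
        if retry.success and float(np.sum(np.asarray(retry.residual) ** 2)) <= float(
            np.sum(np.asarray(result.residual) ** 2)
        ):
            result = retry
        converged = bool(result.success)

    p = result.params

    def se(name):
        err = p[name].stderr
        return float(err) if (p[name].vary and err is not None) else None

    return CorrelationFit(
        g0=float(p["g0"].value),
        tau_d=float(p["tau_d"].value),
        baseline=float(p["baseline"].value),
        se_g0=se("g0"),
        se_tau_d=se("tau_d"),
        se_baseline=se("baseline"),
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        converged=converged,
        n_points=int(tau.size),
        kind=curve.kind,
        ids=curve.ids,
    )


def fit_scan(
    curves: Sequence[CorrelationCurve],
    baseline_mode: str = "fixed0",
) -> ScanFits:
    """Fit the per-scan curve triple (two autos, one cross) with shared settings."""
    autos = [c for c in curves if c.kind == "auto"]
    crosses = [c for c in curves if c.kind == "cross"]
    if len(autos) != 2 or len(crosses) != 1:
        raise ValueError(
            f"expected exactly two autocorrelations and one cross-correlation, "
            f"got {len(autos)} auto and {len(crosses)} cross"
        )
    id_a, id_b = sorted(a.ids[0] for a in autos)
    by_id = {a.ids[0]: a for a in autos}
    return ScanFits(
        auto_a=fit_correlation(by_id[id_a], baseline_mode),
        auto_b=fit_correlation(by_id[id_b], baseline_mode),
        cross=fit_correlation(crosses[0], baseline_mode),
        id_a=id_a,
        id_b=id_b,
    )
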