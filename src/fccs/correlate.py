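"""Fluctuation auto- and cross-correlation of intensity traces.

The estimator is the literal normalized fluctuation correlation

    G(tau) = < dI1(t) dI2(t + tau) > / ( <I1> <I2> ),

with ``dI = I - <I>`` the deviation from the scan-global mean and the
time average taken over all overlapping sample pairs at each lag. With
this normalization G decays to zero at large lag, and for a single
diffusing species G(0) extrapolates to 1/N_eff.

Lags are evaluated on a multi-tau-style quasi-logarithmic grid (linear
at short lags, geometric beyond), capped at ``n_frames / 8`` to bound
estimator variance. The evaluation is a vectorized direct sum: it is
numerically identical to the brute-force double loop at every lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datatypes import IntensityTrace

__all__ = ["CorrelationCurve", "LagScheme", "multitau_lags", "correlate", "correlate_scan"]

MAX_LAG_FRACTION = 8  # maximum lag is n_frames / MAX_LAG_FRACTION


@dataclass(frozen=True)
class LagScheme:
    """Quasi-logarithmic lag grid: integer frame lags plus the frame interval."""

    frames: np.ndarray  # strictly increasing positive ints
    frame_interval: float

    @property
    def seconds(self) -> np.ndarray:
        return self.frames * self.frame_interval


@dataclass
class CorrelationCurve:
    """G(tau) on a lag grid, with the identity of the traces correlated."""

    lags: np.ndarray        # seconds, strictly increasing
    g: np.ndarray           # dimensionless
    kind: str               # "auto" | "cross"
    ids: tuple[str, str]
    n_samples: Optional[np.ndarray] = None  # overlapping pairs per lag

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if lags.shape != g.shape:
            raise ValueError("lags and g must have the same shape")
        if lags.size and np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValueError("G values must be finite")
        if self.kind not in ("auto", "cross"):
            raise ValueError("kind must be 'auto' or 'cross'")
        if (self.kind == "auto") != (self.ids[0] == self.ids[1]):
            raise ValueError("kind 'auto' requires equal trace ids and vice versa")
        self.lags = lags
        self.g = g


def multitau_lags(
    n_frames: int,
    frame_interval: float,
    points_per_octave: int = 8,
) -> LagScheme:
    """Quasi-logarithmic lag grid from one frame up to ``n_frames / 8``.

    At most ``points_per_octave`` distinct lags fall in each doubling of
    tau; short lags are covered linearly (every integer lag until the
    geometric spacing exceeds one frame).
    """
    if n_frames < 4:
        raise ValueError("n_frames must be >= 4")
    if points_per_octave < 1:
        raise ValueError("points_per_octave must be >= 1")
    max_lag = n_frames // MAX_LAG_FRACTION
    if max_lag < 1:
        max_lag = 1
    n_oct = np.log2(max_lag) if max_lag > 1 else 0.0
    exponents = np.arange(0.0, n_oct + 1.0 / points_per_octave, 1.0 / points_per_octave)
    lags = np.unique(np.rint(2.0 ** exponents).astype(int))
    lags = lags[(lags >= 1) & (lags <= max_lag)]
    return LagScheme(frames=lags, frame_interval=frame_interval)


def correlate(
    trace1: IntensityTrace,
    trace2: IntensityTrace,
    lags: Optional[LagScheme] = None,
    points_per_octave: int = 8,
) -> CorrelationCurve:
    """Normalized fluctuation correlation of two traces (auto if identical ids)."""
    i1 = trace1.values
    i2 = trace2.values
    if i1.size != i2.size:
        raise ValueError(
            f"trace lengths differ: {i1.size} vs {i2.size}"
        )
    if abs(trace1.frame_interval - trace2.frame_interval) > 1e-12 * trace1.frame_interval:
        raise ValueError("traces have different frame intervals")
    m1 = i1.mean()
    m2 = i2.mean()
    if m1 <= 0 or m2 <= 0:
        raise ValueError(
            "trace mean must be positive for normalized correlation; "
            "supply raw (not mean-subtracted) intensities or check for an "
            "all-dark channel"
        )
    if lags is None:
        lags = multitau_lags(i1.size, trace1.frame_interval, points_per_octave)
    d1 = i1 - m1
    d2 = i2 - m2
    n = i1.size
    g = np.empty(lags.frames.size)
    n_samples = np.empty(lags.frames.size, dtype=int)
    for idx, k in enumerate(lags.frames):
        k = int(k)
        if k >= n:
            raise ValueError(f"lag {k} frames exceeds trace length {n}")
        overlap = n - k
        g[idx] = float(d1[:overlap] @ d2[k:]) / overlap / (m1 * m2)
        n_samples[idx] = overlap
    kind = "auto" if trace1.fluorophore == trace2.fluorophore else "cross"
    return CorrelationCurve(
        lags=lags.seconds,
        g=g,
        kind=kind,
        ids=(trace1.fluorophore, trace2.fluorophore),
        n_samples=n_samples,
    )


def correlate_scan(
    trace_a: IntensityTrace,
    trace_b: IntensityTrace,
    points_per_octave: int = 8,
) -> list[CorrelationCurve]:
    """The three per-scan curves: two autocorrelations and the cross-correlation."""
    scheme = multitau_lags(trace_a.n_frames, trace_a.frame_interval, points_per_octave)
    return [
        correlate(trace_a, trace_a, scheme),
        correlate(trace_b, trace_b, scheme),
        correlate(trace_a, trace_b, scheme),
    ]
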