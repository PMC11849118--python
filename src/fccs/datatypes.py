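"""Core data containers shared across the FCCS pipeline.

The pipeline moves data through three representations: raw spectral
frames from a scan (:class:`ScanFrames`), per-fluorophore intensity
traces extracted by spectral unmixing (:class:`IntensityTrace`), and the
reference emission spectra (:class:`EmissionSpectrum`) that the unmixing
is performed against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["EmissionSpectrum", "ScanFrames", "IntensityTrace"]


@dataclass(frozen=True)
class EmissionSpectrum:
    """Normalized emission spectrum of one fluorophore over spectral bins.

    Parameters
    ----------
    fluorophore:
        Identifier, e.g. ``"A"`` for an mCherry-like label or ``"B"`` for
        a YFP-like label.
    weights:
        Nonnegative weights over the spectral bins. They are normalized
        to sum to one on construction; an all-zero vector is rejected.
    """

    fluorophore: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError("weights must be a non-empty 1-D vector")
        if np.any(w < 0):
            raise ValueError(f"spectrum {self.fluorophore!r} has negative weights")
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError(f"spectrum {self.fluorophore!r} has zero total weight")
        object.__setattr__(self, "weights", w / total)

    @property
    def n_bins(self) -> int:
        return self.weights.size


@dataclass
class ScanFrames:
    """Time-ordered spectral frames from a single scan.

    ``counts`` has shape ``(n_frames, n_bins)``; entry ``[t, b]`` is the
    detected camera counts in spectral bin ``b`` during frame ``t``.
    """

    counts: np.ndarray
    frame_interval: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2:
            raise ValueError("counts must be a (n_frames, n_bins) matrix")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.counts = c

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class IntensityTrace:
    """Intensity versus time for one fluorophore, I(t), on a uniform frame grid."""

    fluorophore: str
    values: np.ndarray
    frame_interval: float
    residuals: Optional[np.ndarray] = None  # per-frame unmixing residual norm

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.values = v

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval
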