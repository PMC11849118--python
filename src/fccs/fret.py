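"""Three-filter (three-cube) sensitized-emission FRET correction.

The three filter sets are donor excitation / donor emission (I_DD),
acceptor excitation / acceptor emission (I_AA), and the FRET cube:
donor excitation / acceptor emission (I_FF). Following the Gordon &
Youvan computation, the net FRET image removes the two contaminations
of the FRET cube pixelwise:

    nFRET = I_FF - alpha * I_DD - beta * I_AA,

with alpha the donor emission bleed-through into the acceptor channel
and beta the direct (cross-)excitation of the acceptor by the donor
line. Both coefficients are slopes measured on single-label control
images. Negative nFRET values are retained -- clipping is a display
choice, not a data operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
import warnings

import numpy as np

__all__ = [
    "ThreeFilterImageSet",
    "CorrectionFactors",
    "estimate_bleedthrough",
    "net_fret",
    "roi_mean",
    "FretSceneParams",
    "synth_fret_scene",
]


@dataclass
class ThreeFilterImageSet:
    """The three equal-shaped nonnegative images of a three-cube acquisition."""

    i_dd: np.ndarray
    i_aa: np.ndarray
    i_ff: np.ndarray

    def __post_init__(self) -> None:
        dd = np.asarray(self.i_dd, dtype=float)
        aa = np.asarray(self.i_aa, dtype=float)
        ff = np.asarray(self.i_ff, dtype=float)
        if not (dd.shape == aa.shape == ff.shape):
            raise ValueError(
                f"image shapes differ: DD {dd.shape}, AA {aa.shape}, FF {ff.shape}"
            )
        for name, img in (("I_DD", dd), ("I_AA", aa), ("I_FF", ff)):
            if np.any(img < 0):
                raise ValueError(f"{name} has negative pixels")
        self.i_dd, self.i_aa, self.i_ff = dd, aa, ff


@dataclass(frozen=True)
class CorrectionFactors:
    """Bleed-through (alpha, donor) and cross-excitation (beta, acceptor) slopes."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta)):
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if not (0.0 <= v < 1.0):
                warnings.warn(
                    f"{name} = {v:.3g} is outside [0, 1); unusual for a sane instrument",
                    stacklevel=3,
                )


def _auto_threshold(reference: np.ndarray) -> float:
    """Background mean + 2 SD, with background taken as the dimmest quartile."""
    flat = np.sort(reference.ravel())
    bg = flat[: max(1, flat.size // 4)]
    return float(bg.mean() + 2.0 * bg.std())


def estimate_bleedthrough(
    control_images: ThreeFilterImageSet,
    which: str,
    threshold: Optional[float] = None,
    min_pixels: int = 50,
) -> float:
    """Bleed-through slope from a single-label control image set.

    For a donor-only control (``which="donor"``) the slope of I_FF on
    I_DD over above-threshold pixels is alpha; for an acceptor-only
    control (``which="acceptor"``) the slope of I_FF on I_AA is beta.
    The slope is the through-origin least-squares estimate; the default
    threshold is background mean + 2 SD of the reference image.
    """
    if which not in ("donor", "acceptor"):
        raise ValueError("which must be 'donor' or 'acceptor'")
    ref = control_images.i_dd if which == "donor" else control_images.i_aa
    if threshold is None:
        threshold = _auto_threshold(ref)
    mask = ref > threshold
    if mask.sum() < min_pixels:
        raise ValueError(
            f"only {int(mask.sum())} pixels above threshold {threshold:.3g}; "
            f"need at least {min_pixels} for a usable slope"
        )
    x = ref[mask]
    y = control_images.i_ff[mask]
    # subtract the sub-threshold background pedestal of both channels so a
    # camera offset does not inflate the slope
    below = ~mask
    if below.any():
        x = x - ref[below].mean()
        y = y - control_images.i_ff[below].mean()
    return float((x @ y) / (x @ x))


def net_fret(images: ThreeFilterImageSet, factors: CorrectionFactors) -> np.ndarray:
    """Pixelwise net FRET: I_FF - alpha*I_DD - beta*I_AA (negatives retained)."""
    return images.i_ff - factors.alpha * images.i_dd - factors.beta * images.i_aa


def roi_mean(image: np.ndarray, roi: np.ndarray) -> float:
    """Mean intensity over a boolean ROI mask of the same shape as the image."""
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi)
    if roi.dtype != bool:
        roi = roi.astype(bool)
    if roi.shape != image.shape:
        raise ValueError(f"ROI shape {roi.shape} does not match image {image.shape}")
    if not roi.any():
        raise ValueError("ROI is empty")
    return float(image[roi].mean())


@dataclass(frozen=True)
class FretSceneParams:
    """Forward-model parameters of a synthetic three-cube scene.

    Donor/acceptor level images set the clean I_DD and I_AA; ``fret``
    is the true sensitized-emission map added to I_FF; Poisson shot
    noise (on each image) plus an additive pedestal model the camera.
    """

    shape: tuple[int, int] = (64, 64)
    donor_level: float = 200.0
    acceptor_level: float = 150.0
    fret_level: float = 40.0
    alpha: float = 0.25
    beta: float = 0.10
    background: float = 5.0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.shape[0] < 4 or self.shape[1] < 4:
            raise ValueError("scene must be at least 4x4 pixels")
        for name in ("donor_level", "acceptor_level", "fret_level", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def synth_fret_scene(
    params: FretSceneParams,
    seed: int = 0,
    cell_mask: Optional[np.ndarray] = None,
) -> tuple[ThreeFilterImageSet, dict]:
    """Generate a synthetic three-cube scene obeying the forward model.

    Returns the image set and the ground truth (clean images, true FRET
    map, factors, cell mask). The default cell is a centered disk
    covering ~1/4 of the field; outside it only background remains.
    """
    rng = np.random.default_rng(seed)
    h, w = params.shape
    if cell_mask is None:
        yy, xx = np.mgrid[0:h, 0:w]
        r = min(h, w) / 3.5
        cell_mask = (yy - h / 2.0) ** 2 + (xx - w / 2.0) ** 2 <= r**2
    else:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != (h, w):
            raise ValueError("cell_mask shape does not match params.shape")
    dd_clean = params.background + params.donor_level * cell_mask
    aa_clean = params.background + params.acceptor_level * cell_mask
    fret_map = params.fret_level * cell_mask.astype(float)
    ff_clean = fret_map + params.alpha * dd_clean + params.beta * aa_clean
    if params.noise:
        i_dd = rng.poisson(dd_clean).astype(float)
        i_aa = rng.poisson(aa_clean).astype(float)
        i_ff = rng.poisson(ff_clean).astype(float)
    else:
        i_dd, i_aa, i_ff = dd_clean, aa_clean, ff_clean
    truth = {
        "dd_clean": dd_clean,
        "aa_clean": aa_clean,
        "ff_clean": ff_clean,
        "fret_map": fret_map,
        "factors": CorrectionFactors(params.alpha, params.beta),
        "cell_mask": cell_mask,
    }
    return ThreeFilterImageSet(i_dd, i_aa, i_ff), truth
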