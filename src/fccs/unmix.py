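"""Spectral unmixing: per-frame least-squares decomposition of spectral
frames into known fluorophore reference spectra.

Each frame is fit as ``frame ~ sum_f c_f * S_f (+ offset)`` where the
``S_f`` are normalized emission spectra. The coefficient time series
``c_f(t)`` are the intensity-versus-time traces I(t) that the
fluctuation correlation consumes. Coefficients are constrained
nonnegative by default (intensities are physical); the unconstrained
ordinary-least-squares branch is available via ``nonnegative=False``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import scipy.optimize

from .datatypes import EmissionSpectrum, IntensityTrace, ScanFrames

__all__ = ["fit_frame", "unmix_scan", "CollinearSpectraError"]

OFFSET = "__offset__"


class CollinearSpectraError(ValueError):
    """Raised when the reference spectra are (near-)linearly dependent."""


def _design_matrix(
    spectra: Sequence[EmissionSpectrum], n_bins: int, offset_term: bool
) -> np.ndarray:
    if len(spectra) < 1:
        raise ValueError("need at least one reference spectrum")
    for s in spectra:
        if s.n_bins != n_bins:
            raise ValueError(
                f"spectrum {s.fluorophore!r} has {s.n_bins} bins, frame has {n_bins}"
            )
    cols = [s.weights for s in spectra]
    if offset_term:
        cols.append(np.ones(n_bins))
    design = np.column_stack(cols)
    _check_rank(design, spectra, offset_term)
    return design


def _check_rank(
    design: np.ndarray, spectra: Sequence[EmissionSpectrum], offset_term: bool
) -> None:
    names = [s.fluorophore for s in spectra] + ([OFFSET] if offset_term else [])
    rank = np.linalg.matrix_rank(design, tol=1e-10 * np.abs(design).max())
    if rank == design.shape[1]:
        return
    # name the most collinear pair for the diagnostic
    unit = design / np.linalg.norm(design, axis=0, keepdims=True)
    gram = np.abs(unit.T @ unit)
    np.fill_diagonal(gram, 0.0)
    i, j = np.unravel_index(np.argmax(gram), gram.shape)
    raise CollinearSpectraError(
        f"reference spectra are rank deficient; most collinear pair: "
        f"{names[i]!r} and {names[j]!r} (|cos| = {gram[i, j]:.6f})"
    )


def fit_frame(
    frame: np.ndarray,
    spectra: Sequence[EmissionSpectrum],
    offset_term: bool = True,
    nonnegative: bool = True,
) -> tuple[np.ndarray, float]:
    """Least-squares coefficients of one spectral frame.

    Returns ``(coefficients, residual_norm)``; coefficients are ordered
    as the spectra, with the constant offset last when ``offset_term``.
    """
    frame = np.asarray(frame, dtype=float)
    design = _design_matrix(spectra, frame.size, offset_term)
    if nonnegative:
        coef, rnorm = scipy.optimize.nnls(design, frame)
    else:
        coef, _, _, _ = np.linalg.lstsq(design, frame, rcond=None)
        rnorm = float(np.linalg.norm(frame - design @ coef))
    return coef, float(rnorm)


def unmix_scan(
    scan: ScanFrames,
    spectra: Sequence[EmissionSpectrum],
    offset_term: bool = True,
    nonnegative: bool = True,
) -> list[IntensityTrace]:
    """Unmix every frame of a scan into per-fluorophore intensity traces.

    The unconstrained solution is computed for all frames in one
    vectorized pass; when ``nonnegative`` is requested, only the frames
    whose unconstrained solution has a negative coefficient are re-solved
    with NNLS (both solutions coincide elsewhere).
    """
    design = _design_matrix(spectra, scan.n_bins, offset_term)
    frames = scan.counts  # (n_frames, n_bins)
    coefs, _, _, _ = np.linalg.lstsq(design, frames.T, rcond=None)
    coefs = coefs.T  # (n_frames, n_terms)
    if nonnegative:
        bad = np.where(np.any(coefs < 0, axis=1))[0]
        for t in bad:
            try:
                coefs[t], _ = scipy.optimize.nnls(design, frames[t])
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(f"unmixing failed at frame {t}: {exc}") from exc
        np.clip(coefs, 0.0, None, out=coefs)
    residuals = np.linalg.norm(frames - coefs @ design.T, axis=1)
    traces = []
    for k, s in enumerate(spectra):
        traces.append(
            IntensityTrace(
                fluorophore=s.fluorophore,
                values=coefs[:, k],
                frame_interval=scan.frame_interval,
                residuals=residuals,
            )
        )
    return traces
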