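"""End-to-end pipeline: simulate -> unmix -> correlate -> fit -> summarize.

Two entry levels:

* in-memory helpers (:func:`analyze_scan`, :func:`analyze_traces`,
  :func:`simulate_and_analyze`) for library use, and
* the file-based stage driver :func:`run_pipeline`, configured by a
  schema-validated :class:`PipelineConfig`, which writes per-stage
  outputs plus a manifest of content digests so a rerun with the same
  config and master seed is verifiably identical.

Randomness derives from a single master seed through deterministic
per-scan child seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import io as fio
from .correlate import correlate_scan
from .datatypes import EmissionSpectrum, IntensityTrace, ScanFrames
from .fitfcs import fit_scan
from .simulate import SimulationConfig, default_spectra, simulate_condition
from .stats import ConditionSummary, ScanResult, scan_result, summarize_condition
from .unmix import unmix_scan

__all__ = [
    "PipelineConfig",
    "analyze_scan",
    "analyze_traces",
    "simulate_and_analyze",
    "run_pipeline",
]

logger = logging.getLogger("fccs")

STAGES = ("simulate", "unmix", "correlate", "fit", "summarize")
CONFIG_SCHEMA_VERSION = 1


class SimulationBlock(BaseModel):
    """Mirror of :class:`fccs.simulate.SimulationConfig` (validated there)."""

    model_config = ConfigDict(extra="forbid")

    mean_free_a: float = 5.5
    mean_free_b: float = 0.9
    mean_complex: float = 4.5
    diff_a: float = 1.0
    diff_b: float = 1.0
    diff_ab: float = 0.4
    beam_waist: float = 0.25
    frame_interval: float = 1.0 / 769.0
    n_frames: int = 25000
    brightness_a: float = 3.0
    brightness_b: float = 3.0
    background: float = 0.1
    em_gain: float = 250.0
    read_noise_sd: float = 2.0
    n_bins: int = 16
    box_half_width: float = 1.0

    def to_config(self, seed: int = 0) -> SimulationConfig:
        return SimulationConfig(seed=seed, **self.model_dump())


class UnmixBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    offset_term: bool = True
    nonnegative: bool = True


class CorrelationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    points_per_octave: int = Field(8, ge=1)


class FitBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline_mode: Literal["fixed0", "fixed1", "free"] = "fixed0"


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = CONFIG_SCHEMA_VERSION
    condition: str = "condition"
    n_scans: int = Field(4, ge=1)
    master_seed: int = 0
    out_dir: str = "fccs_run"
    stages: list[Literal["simulate", "unmix", "correlate", "fit", "summarize"]] = Field(
        default_factory=lambda: list(STAGES)
    )
    log_level: str = "INFO"
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    unmixing: UnmixBlock = Field(default_factory=UnmixBlock)
    correlation: CorrelationBlock = Field(default_factory=CorrelationBlock)
    fitting: FitBlock = Field(default_factory=FitBlock)


# ------------------------------------------------------------- in-memory API

def analyze_traces(
    trace_a: IntensityTrace,
    trace_b: IntensityTrace,
    scan_id: str = "",
    baseline_mode: str = "fixed0",
    points_per_octave: int = 8,
) -> ScanResult:
    """Correlate and fit one pair of channel traces into a scan result."""
    curves = correlate_scan(trace_a, trace_b, points_per_octave)
    fits = fit_scan(curves, baseline_mode)
    return scan_result(fits, scan_id)


def analyze_scan(
    scan: ScanFrames,
    spectra: Sequence[EmissionSpectrum],
    scan_id: str = "",
    baseline_mode: str = "fixed0",
    points_per_octave: int = 8,
    offset_term: bool = True,
    nonnegative: bool = True,
) -> ScanResult:
    """Full per-scan analysis of spectral frames: unmix, correlate, fit."""
    traces = unmix_scan(scan, spectra, offset_term=offset_term, nonnegative=nonnegative)
    if len(traces) != 2:
        raise ValueError(f"scan analysis expects two fluorophores, got {len(traces)}")
    return analyze_traces(traces[0], traces[1], scan_id, baseline_mode, points_per_octave)


def simulate_and_analyze(
    config: SimulationConfig,
    n_scans: int,
    master_seed: int,
    label: str = "condition",
    baseline_mode: str = "fixed0",
) -> tuple[list[ScanResult], ConditionSummary]:
    """Simulate a condition and run the full spectral pipeline on every scan."""
    spectra = default_spectra(config.n_bins)
    scans = simulate_condition(config, n_scans, master_seed, spectra=spectra)
    results = [
        analyze_scan(scan, spectra, scan_id=f"{label}-{i:03d}", baseline_mode=baseline_mode)
        for i, scan in enumerate(scans)
    ]
    return results, summarize_condition(results, label)


# ------------------------------------------------------------ file pipeline

def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _digest_array(arr: np.ndarray) -> str:
    return _digest(np.ascontiguousarray(arr).tobytes())


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stage outputs live under ``config.out_dir``: scan TIFFs
    (``scan_###.tif`` + sidecars), per-scan trace and correlation CSVs,
    a fit CSV, per-scan results and the condition summary. Later stages
    read earlier stages' files, so a stage subset resumes from what is
    on disk. The manifest records the config, the derived child seeds
    and a content digest per output.
    """
    logging.basicConfig()
    logger.setLevel(config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in config.stages]  # canonical order
    if not stages:
        raise ValueError("no stages requested")
    (out / "pipeline_config.json").write_text(config.model_dump_json(indent=1))

    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "stages_run": stages,
        "outputs": {},
    }
    spectra = default_spectra(config.simulation.n_bins)
    fio.write_spectra_csv(spectra, out / "spectra.csv")
    manifest["outputs"]["spectra.csv"] = _digest((out / "spectra.csv").read_bytes())
    n = config.n_scans
    scan_ids = [f"scan_{i:03d}" for i in range(n)]

    if "simulate" in stages:
        logger.info("stage simulate: %d scans, master seed %d", n, config.master_seed)
        scans = simulate_condition(
            config.simulation.to_config(), n, config.master_seed, spectra=spectra
        )
        manifest["child_seeds"] = [int(s.meta["seed"]) for s in scans]
        for sid, scan in zip(scan_ids, scans):
            fio.write_scan_tiff(scan, out / f"{sid}.tif")
            manifest["outputs"][f"{sid}.tif"] = _digest_array(np.rint(scan.counts))

    if "unmix" in stages:
        logger.info("stage unmix")
        for sid in scan_ids:
            tif = out / f"{sid}.tif"
            if not tif.exists():
                raise FileNotFoundError(f"stage 'unmix' needs missing input {tif}")
            scan = fio.read_scan_tiff(tif)
            traces = unmix_scan(
                scan,
                fio.read_spectra_csv(out / "spectra.csv"),
                offset_term=config.unmixing.offset_term,
                nonnegative=config.unmixing.nonnegative,
            )
            fio.write_traces_csv(traces, out / f"{sid}_traces.csv")
            manifest["outputs"][f"{sid}_traces.csv"] = _digest(
                (out / f"{sid}_traces.csv").read_bytes()
            )

    if "correlate" in stages:
        logger.info("stage correlate")
        for sid in scan_ids:
            f = out / f"{sid}_traces.csv"
            if not f.exists():
                raise FileNotFoundError(f"stage 'correlate' needs missing input {f}")
            traces = fio.read_traces_csv(f)
            curves = correlate_scan(
                traces[0], traces[1], config.correlation.points_per_octave
            )
            fio.write_correlations_csv(curves, out / f"{sid}_corr.csv")
            manifest["outputs"][f"{sid}_corr.csv"] = _digest(
                (out / f"{sid}_corr.csv").read_bytes()
            )

    if "fit" in stages:
        logger.info("stage fit")
        all_fits = []
        for sid in scan_ids:
            f = out / f"{sid}_corr.csv"
            if not f.exists():
                raise FileNotFoundError(f"stage 'fit' needs missing input {f}")
            curves = fio.read_correlations_csv(f)
            fits = fit_scan(curves, config.fitting.baseline_mode)
            for fit in (fits.auto_a, fits.auto_b, fits.cross):
                all_fits.append((sid, fit))
        fio.write_fits_csv(all_fits, out / "fits.csv")
        manifest["outputs"]["fits.csv"] = _digest((out / "fits.csv").read_bytes())

    if "summarize" in stages:
        logger.info("stage summarize")
        f = out / "fits.csv"
        if not f.exists():
            raise FileNotFoundError(f"stage 'summarize' needs missing input {f}")
        from .fitfcs import ScanFits

        by_scan: dict[str, dict[str, object]] = {}
        for sid, fit in fio.read_fits_csv(f):
            slot = "cross" if fit.kind == "cross" else f"auto_{fit.ids[0]}"
            by_scan.setdefault(sid, {})[slot] = fit
        results = []
        for sid, fits in by_scan.items():
            autos = sorted(k for k in fits if k.startswith("auto_"))
            if len(autos) != 2 or "cross" not in fits:
                raise fio.ParseError(f"fits.csv: scan {sid} lacks a complete fit triple")
            sf = ScanFits(
                auto_a=fits[autos[0]], auto_b=fits[autos[1]], cross=fits["cross"],
                id_a=autos[0][5:], id_b=autos[1][5:],
            )
            results.append(scan_result(sf, sid))
        fio.write_results_csv(results, out / "results.csv")
        summary = summarize_condition(results, config.condition)
        fio.write_summary_csv(summary, out / "summary.csv")
        manifest["outputs"]["results.csv"] = _digest((out / "results.csv").read_bytes())
        manifest["outputs"]["summary.csv"] = _digest((out / "summary.csv").read_bytes())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
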