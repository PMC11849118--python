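"""File-format adapters: TIFF scans, CSV tables, PDB/XYZ trajectories.

Scans travel as multi-frame TIFF (frames x bins, 16-bit, camera counts
rounded to integers) with a JSON sidecar holding the frame interval and
provenance; tabular data (spectra, traces, correlations, fits, scan
results, condition summaries) travel as CSV written at full float
precision so a read/write round trip is lossless to 1e-12 relative.
Coordinate trajectories are read from multi-model PDB or XYZ files via
MDAnalysis, with a residue-name -> lipid-class mapping CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .contacts import LIPID_CLASSES, LabeledTrajectory
from .correlate import CorrelationCurve
from .datatypes import EmissionSpectrum, IntensityTrace, ScanFrames
from .fitfcs import CorrelationFit
from .stats import METRICS, ConditionSummary, ScanResult, results_frame

__all__ = [
    "ParseError",
    "write_scan_tiff",
    "read_scan_tiff",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_correlations_csv",
    "read_correlations_csv",
    "write_fits_csv",
    "read_fits_csv",
    "write_results_csv",
    "read_results_csv",
    "write_summary_csv",
    "read_class_map_csv",
    "read_trajectory",
]

FLOAT_FMT = "%.17g"
PROTEIN_CLASS = "protein"


class ParseError(ValueError):
    """Malformed input file, with location context in the message."""


# ---------------------------------------------------------------- TIFF scans

def write_scan_tiff(scan: ScanFrames, path: str | Path) -> None:
    """Write a scan as a 16-bit multi-frame TIFF plus a JSON sidecar."""
    path = Path(path)
    counts = np.rint(scan.counts)
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        warnings.warn("counts exceed 16-bit range and will be clipped", stacklevel=2)
        counts = np.clip(counts, 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, counts.astype(np.uint16)[:, np.newaxis, :])
    sidecar = {"frame_interval": scan.frame_interval, "meta": _json_safe(scan.meta)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_scan_tiff(path: str | Path, frame_interval: Optional[float] = None) -> ScanFrames:
    """Read a multi-frame TIFF scan; the frame interval comes from the
    sidecar unless given explicitly."""
    path = Path(path)
    try:
        stack = tifffile.imread(path)
    except Exception as exc:
        raise ParseError(f"cannot read TIFF {path}: {exc}") from exc
    counts = np.asarray(stack, dtype=float)
    if counts.ndim == 3:  # frames x 1 x bins
        counts = counts.reshape(counts.shape[0], -1)
    if counts.ndim != 2:
        raise ParseError(f"{path}: expected a frames x bins stack, got shape {stack.shape}")
    meta: dict = {}
    if frame_interval is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ParseError(
                f"{path}: no frame_interval given and sidecar {sidecar.name} is missing"
            )
        data = json.loads(sidecar.read_text())
        frame_interval = float(data["frame_interval"])
        meta = data.get("meta", {})
    meta["source"] = str(path)
    return ScanFrames(counts=counts, frame_interval=frame_interval, meta=meta)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


# ---------------------------------------------------------------- CSV tables

def write_spectra_csv(spectra: Sequence[EmissionSpectrum], path: str | Path) -> None:
    """Columns: bin, then one column of weights per fluorophore."""
    df = pd.DataFrame({"bin": np.arange(spectra[0].n_bins)})
    for s in spectra:
        df[s.fluorophore] = s.weights
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_spectra_csv(path: str | Path) -> list[EmissionSpectrum]:
    df = _read_csv(path)
    if "bin" not in df.columns or df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns 'bin' plus one per fluorophore")
    return [
        EmissionSpectrum(str(col), df[col].to_numpy(dtype=float))
        for col in df.columns
        if col != "bin"
    ]


def write_traces_csv(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    """Columns: frame, time_s, I_<id> per fluorophore, residual (if any)."""
    n = traces[0].n_frames
    dt = traces[0].frame_interval
    df = pd.DataFrame({"frame": np.arange(n), "time_s": np.arange(n) * dt})
    residual = None
    for t in traces:
        if t.n_frames != n:
            raise ValueError("traces have different lengths")
        df[f"I_{t.fluorophore}"] = t.values
        if t.residuals is not None:
            residual = t.residuals
    if residual is not None:
        df["residual"] = residual
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_traces_csv(path: str | Path) -> list[IntensityTrace]:
    df = _read_csv(path)
    if "time_s" not in df.columns:
        raise ParseError(f"{path}: missing 'time_s' column")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least two frames")
    dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
    residuals = df["residual"].to_numpy(dtype=float) if "residual" in df.columns else None
    traces = []
    for col in df.columns:
        if col.startswith("I_"):
            traces.append(
                IntensityTrace(col[2:], df[col].to_numpy(dtype=float), dt, residuals)
            )
    if not traces:
        raise ParseError(f"{path}: no intensity columns (named I_<fluorophore>)")
    return traces


def write_correlations_csv(curves: Sequence[CorrelationCurve], path: str | Path) -> None:
    """Long format: lag_s, G, n_samples, kind, id1, id2."""
    rows = []
    for c in curves:
        ns = c.n_samples if c.n_samples is not None else np.full(c.lags.size, -1)
        for lag, g, n in zip(c.lags, c.g, ns):
            rows.append(
                {"lag_s": lag, "G": g, "n_samples": int(n), "kind": c.kind,
                 "id1": c.ids[0], "id2": c.ids[1]}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_correlations_csv(path: str | Path) -> list[CorrelationCurve]:
    df = _read_csv(path)
    needed = {"lag_s", "G", "kind", "id1", "id2"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    curves = []
    for (kind, id1, id2), grp in df.groupby(["kind", "id1", "id2"], sort=False):
        ns = grp["n_samples"].to_numpy(dtype=int) if "n_samples" in grp.columns else None
        if ns is not None and np.any(ns < 0):
            ns = None
        curves.append(
            CorrelationCurve(
                lags=grp["lag_s"].to_numpy(dtype=float),
                g=grp["G"].to_numpy(dtype=float),
                kind=str(kind),
                ids=(str(id1), str(id2)),
                n_samples=ns,
            )
        )
    return curves


FIT_COLUMNS = [
    "scan_id", "kind", "id1", "id2", "G0", "tau_d_s", "baseline",
    "se_G0", "se_tau_d", "rss", "converged", "n_points",
]


def write_fits_csv(fits: Sequence[tuple[str, CorrelationFit]], path: str | Path) -> None:
    """Rows of (scan id, fit); NaN marks an unavailable standard error."""
    rows = []
    for scan_id, f in fits:
        rows.append(
            {
                "scan_id": scan_id, "kind": f.kind, "id1": f.ids[0], "id2": f.ids[1],
                "G0": f.g0, "tau_d_s": f.tau_d, "baseline": f.baseline,
                "se_G0": np.nan if f.se_g0 is None else f.se_g0,
                "se_tau_d": np.nan if f.se_tau_d is None else f.se_tau_d,
                "rss": f.rss, "converged": f.converged, "n_points": f.n_points,
            }
        )
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_fits_csv(path: str | Path) -> list[tuple[str, CorrelationFit]]:
    df = _read_csv(path)
    missing = set(FIT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                str(row["scan_id"]),
                CorrelationFit(
                    g0=float(row["G0"]),
                    tau_d=float(row["tau_d_s"]),
                    baseline=float(row["baseline"]),
                    se_g0=None if pd.isna(row["se_G0"]) else float(row["se_G0"]),
                    se_tau_d=None if pd.isna(row["se_tau_d"]) else float(row["se_tau_d"]),
                    se_baseline=None,
                    rss=float(row["rss"]),
                    converged=bool(row["converged"]),
                    n_points=int(row["n_points"]),
                    kind=str(row["kind"]),
                    ids=(str(row["id1"]), str(row["id2"])),
                ),
            )
        )
    return out


def write_results_csv(results: Sequence[ScanResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_results_csv(path: str | Path) -> list[ScanResult]:
    df = _read_csv(path)
    missing = {"scan_id", *METRICS} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        flags = row.get("flags", "")
        flags = () if pd.isna(flags) or flags == "" else tuple(str(flags).split(";"))
        out.append(
            ScanResult(
                scan_id=str(row["scan_id"]),
                flags=flags,
                **{m: float(row[m]) for m in METRICS},
            )
        )
    return out


def write_summary_csv(summary: ConditionSummary, path: str | Path) -> None:
    table = summary.table.copy()
    table.insert(0, "condition", summary.label)
    table.index.name = "metric"
    table.to_csv(path, float_format=FLOAT_FMT)


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse CSV {path}: {exc}") from exc


# ------------------------------------------------------------- trajectories

def read_class_map_csv(path: str | Path) -> dict[str, str]:
    """Residue/atom-name -> class mapping; classes are the lipid classes
    plus 'protein'."""
    df = _read_csv(path)
    if not {"name", "class"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns 'name' and 'class'")
    mapping = {}
    valid = set(LIPID_CLASSES) | {PROTEIN_CLASS}
    for i, row in df.iterrows():
        cls = str(row["class"])
        if cls not in valid:
            raise ParseError(
                f"{path} line {i + 2}: unknown class {cls!r} (valid: {sorted(valid)})"
            )
        mapping[str(row["name"])] = cls
    return mapping


def _validate_multimodel_pdb(path: Path) -> None:
    """Reject truncated multi-model PDBs, naming the offending model."""
    model_index = None
    n_models = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                if model_index is not None:
                    raise ParseError(
                        f"{path}: model {model_index} is not terminated "
                        f"(MODEL {n_models + 1} starts before ENDMDL)"
                    )
                n_models += 1
                model_index = n_models
            elif rec == "ENDMDL":
                if model_index is None:
                    raise ParseError(f"{path}: ENDMDL without a matching MODEL record")
                model_index = None
    if model_index is not None:
        raise ParseError(f"{path}: model {model_index} is truncated (missing ENDMDL)")


def read_trajectory(path: str | Path, class_map: dict[str, str]) -> LabeledTrajectory:
    """Read a multi-model PDB or XYZ trajectory into a labeled trajectory.

    For PDB files the class map is keyed on residue names; for XYZ files
    on the per-atom name column. Particles mapping to 'protein' receive
    contiguous residue indices (PDB: by resid; XYZ: one per particle).
    Names absent from the map raise a parse error.
    """
    import MDAnalysis as mda

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        _validate_multimodel_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(str(path))
        except Exception as exc:
            raise ParseError(f"cannot read trajectory {path}: {exc}") from exc
        keys = (
            [str(r) for r in universe.atoms.resnames]
            if suffix == ".pdb"
            else [str(n) for n in universe.atoms.names]
        )
        missing = sorted(set(keys) - set(class_map))
        if missing:
            raise ParseError(f"{path}: names not in class map: {missing}")
        classes = [class_map[k] for k in keys]
        prot = np.asarray([c == PROTEIN_CLASS for c in classes])
        residue_index = -np.ones(len(classes), dtype=int)
        if prot.any():
            if suffix == ".pdb":
                resids = universe.atoms.resids[prot]
                _, residue_index[prot] = np.unique(resids, return_inverse=True)
            else:
                residue_index[prot] = np.arange(int(prot.sum()))
        lipid_class = np.asarray(
            ["" if c == PROTEIN_CLASS else c for c in classes], dtype=object
        )
        frames = [universe.atoms.positions.copy() for _ in universe.trajectory]
    return LabeledTrajectory(
        coords=np.asarray(frames, dtype=float),
        residue_index=residue_index,
        lipid_class=lipid_class,
    )
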