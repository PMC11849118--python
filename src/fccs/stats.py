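"""Condition-level codiffusion statistics.

From the three fitted amplitudes of each scan the cross-correlated
fraction is

    Fc = 2 * G0_cross / (G0_auto,A + G0_auto,B),

which under the ideal amplitude model (G0_auto = 1/N, G0_cross =
N_complex / (N_A * N_B)) equals 2 * N_complex / (N_A + N_B): the share
of all diffusers that are two-color complexes. The per-species
codiffusing fraction of species i is G0_cross / G0_auto,j (j the other
species), which equals N_complex / N_i.

Per-scan values are stored unclipped: fit noise can push individual
scans outside [0, 1], and condition means are taken over the raw
values. Conditions are compared with a two-tailed unequal-variance
(Welch) t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .fitfcs import ScanFits

__all__ = [
    "ScanResult",
    "ConditionSummary",
    "cross_correlated_fraction",
    "codiffusing_fraction",
    "scan_result",
    "summarize_condition",
    "welch_ttest",
]

METRICS = (
    "fc",
    "frac_a_codiffusing",
    "frac_b_codiffusing",
    "g0_auto_a",
    "g0_auto_b",
    "g0_cross",
    "tau_d_auto_a",
    "tau_d_auto_b",
    "tau_d_cross",
)


@dataclass
class ScanResult:
    """Amplitudes, dwell times and codiffusion statistics of one scan."""

    scan_id: str
    g0_auto_a: float
    g0_auto_b: float
    g0_cross: float
    tau_d_auto_a: float
    tau_d_auto_b: float
    tau_d_cross: float
    fc: float
    frac_a_codiffusing: float
    frac_b_codiffusing: float
    flags: tuple[str, ...] = ()

    @property
    def usable(self) -> bool:
        return not self.flags


@dataclass
class ConditionSummary:
    """Per-metric n/mean/SEM/median/extent over the usable scans of a condition."""

    label: str
    table: pd.DataFrame  # index: metric; columns: n, mean, sem, median, min, max
    scan_ids: tuple[str, ...]

    def __getitem__(self, metric: str) -> pd.Series:
        return self.table.loc[metric]


def cross_correlated_fraction(g0_cross: float, g0_auto_a: float, g0_auto_b: float) -> float:
    """Fc = 2 * G0_cross / (G0_auto,A + G0_auto,B), unclipped."""
    denom = g0_auto_a + g0_auto_b
    if denom <= 0:
        raise ValueError(
            f"sum of autocorrelation amplitudes must be positive, got {denom}"
        )
    return 2.0 * g0_cross / denom


def codiffusing_fraction(g0_cross: float, g0_auto_other: float) -> float:
    """Fraction of species i in complexes: G0_cross / G0_auto,(other species)."""
    if g0_auto_other <= 0:
        raise ValueError(
            f"autocorrelation amplitude must be positive, got {g0_auto_other}"
        )
    return g0_cross / g0_auto_other


def scan_result(fits: ScanFits, scan_id: str = "") -> ScanResult:
    """Assemble amplitudes and codiffusion statistics from a per-scan fit triple.

    Scans with any non-converged fit are flagged (and excluded from
    condition summaries), never dropped silently.
    """
    flags = []
    for name, fit in (("auto_a", fits.auto_a), ("auto_b", fits.auto_b), ("cross", fits.cross)):
        if not fit.converged:
            flags.append(f"nonconverged_{name}")
    g0_a, g0_b, g0_x = fits.auto_a.g0, fits.auto_b.g0, fits.cross.g0
    try:
        fc = cross_correlated_fraction(g0_x, g0_a, g0_b)
        frac_a = codiffusing_fraction(g0_x, g0_b)
        frac_b = codiffusing_fraction(g0_x, g0_a)
    except ValueError:
        flags.append("nonpositive_auto_amplitude")
        fc = frac_a = frac_b = math.nan
    return ScanResult(
        scan_id=scan_id,
        g0_auto_a=g0_a,
        g0_auto_b=g0_b,
        g0_cross=g0_x,
        tau_d_auto_a=fits.auto_a.tau_d,
        tau_d_auto_b=fits.auto_b.tau_d,
        tau_d_cross=fits.cross.tau_d,
        fc=fc,
        frac_a_codiffusing=frac_a,
        frac_b_codiffusing=frac_b,
        flags=tuple(flags),
    )


def results_frame(results: Sequence[ScanResult]) -> pd.DataFrame:
    """Tabulate scan results (one row per scan, flags joined with ';')."""
    rows = []
    for r in results:
        row = {m: getattr(r, m) for m in METRICS}
        row["scan_id"] = r.scan_id
        row["flags"] = ";".join(r.flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=["scan_id", *METRICS, "flags"])


def summarize_condition(results: Sequence[ScanResult], label: str) -> ConditionSummary:
    """Per-metric mean/SEM/median/extent over the unflagged scans.

    Means are taken over the unclipped per-scan values; SEM = SD/sqrt(n)
    with the sample (ddof=1) standard deviation.
    """
    usable = [r for r in results if r.usable]
    if len(usable) < 2:
        raise ValueError(
            f"need at least 2 unflagged scans to summarize, got {len(usable)}"
        )
    rows = {}
    for m in METRICS:
        vals = np.array([getattr(r, m) for r in usable], dtype=float)
        n = vals.size
        rows[m] = {
            "n": n,
            "mean": vals.mean(),
            "sem": vals.std(ddof=1) / math.sqrt(n),
            "median": float(np.median(vals)),
            "min": vals.min(),
            "max": vals.max(),
        }
    table = pd.DataFrame(rows).T[["n", "mean", "sem", "median", "min", "max"]]
    table["n"] = table["n"].astype(int)
    return ConditionSummary(
        label=label,
        table=table,
        scan_ids=tuple(r.scan_id for r in usable),
    )


def welch_ttest(sample_x: Sequence[float], sample_y: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed unequal-variance t test: returns (t, Satterthwaite df, p)."""
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 or y.var(ddof=1) == 0:
        raise ValueError("degenerate sample with zero variance; t statistic undefined")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
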