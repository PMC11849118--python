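"""Brownian-dynamics scan simulator for two-color FCCS.

Generates synthetic spectral scans with the statistical structure the
downstream analysis assumes: three populations of membrane-bound
diffusers -- free species A (mCherry-like, e.g. ABHD5), free species B
(YFP-like, e.g. PNPLA3) and heterodimeric A.B complexes -- undergoing
2D Brownian motion in a periodic square, observed through a Gaussian
1/e^2 detection profile, dispersed over a spectral axis and recorded
with EMCCD-style Poisson + gain + read noise.

The normalization convention ties the simulator to the analytic FCS
laws: particle numbers are parameterized as mean counts in the
*effective focal area* ``pi * w**2`` (w the 1/e^2 beam waist), so the
fitted autocorrelation amplitude obeys ``G0 = 1 / N_eff`` and the dwell
time obeys ``tau_D = w**2 / (4 D)`` for a single species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .datatypes import EmissionSpectrum, IntensityTrace, ScanFrames

__all__ = [
    "SimulationConfig",
    "ParticleTrajectories",
    "default_spectra",
    "simulate_positions",
    "traces_from_positions",
    "spectral_frames_from_traces",
    "simulate_scan",
    "simulate_condition",
    "CHANNEL_A",
    "CHANNEL_B",
]

CHANNEL_A = "A"  # mCherry-like (ABHD5-style construct)
CHANNEL_B = "B"  # YFP-like (PNPLA3-style construct)

POPULATIONS = ("free_a", "free_b", "complex")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated scan.

    Mean particle counts (``mean_free_a``, ``mean_free_b``,
    ``mean_complex``) are expressed in the effective focal area
    ``pi * beam_waist**2``; actual numbers in the periodic box are
    Poisson-resampled per scan at the correspondingly scaled mean.
    Brightness and background are detected photoelectrons per frame
    (pre-gain); camera counts apply ``em_gain`` and read noise on top.
    """

    mean_free_a: float = 5.5
    mean_free_b: float = 0.9
    mean_complex: float = 4.5
    diff_a: float = 1.0          # um^2/s
    diff_b: float = 1.0          # um^2/s
    diff_ab: float = 0.4         # um^2/s, complexes diffuse slower
    beam_waist: float = 0.25     # um, 1/e^2 radius
    frame_interval: float = 1.0 / 769.0  # s
    n_frames: int = 25000
    brightness_a: float = 3.0    # photons/molecule/frame at spot center
    brightness_b: float = 3.0
    background: float = 0.1      # photons/bin/frame
    em_gain: float = 250.0
    read_noise_sd: float = 2.0   # camera counts
    n_bins: int = 16
    box_half_width: float = 1.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_free_a", "mean_free_b", "mean_complex",
                     "brightness_a", "brightness_b", "background",
                     "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("diff_a", "diff_b", "diff_ab"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.beam_waist <= 0:
            raise ValueError("beam_waist must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.em_gain <= 0:
            raise ValueError("em_gain must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.box_half_width < 4.0 * self.beam_waist:
            raise ValueError("box_half_width must be >= 4 * beam_waist")

    @property
    def focal_area(self) -> float:
        """Effective focal area pi*w^2 (um^2)."""
        return math.pi * self.beam_waist ** 2

    @property
    def box_area(self) -> float:
        return (2.0 * self.box_half_width) ** 2

    @property
    def area_ratio(self) -> float:
        """Box area over effective focal area: scales focal-area means to box means."""
        return self.box_area / self.focal_area

    def diffusion_of(self, population: str) -> float:
        return {"free_a": self.diff_a, "free_b": self.diff_b,
                "complex": self.diff_ab}[population]


@dataclass
class ParticleTrajectories:
    """Frame-indexed 2D positions per population.

    ``positions[pop]`` has shape ``(n_frames, n_particles, 2)`` in um,
    wrapped into the periodic box ``[-L, L)``.
    """

    positions: dict
    config: SimulationConfig

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    def counts(self) -> dict:
        return {pop: arr.shape[1] for pop, arr in self.positions.items()}


def default_spectra(n_bins: int = 16) -> list[EmissionSpectrum]:
    """Reference emission spectra of the two simulated fluorophores.

    Gaussian-shaped bin profiles: channel B (YFP-like) peaks in the
    bluer bins, channel A (mCherry-like) in the redder bins, with the
    moderate overlap typical of a prism-dispersed two-color experiment.
    """
    bins = np.arange(n_bins, dtype=float)
    center_b = 0.28 * (n_bins - 1)
    center_a = 0.66 * (n_bins - 1)
    width = 0.125 * n_bins
    spec_a = np.exp(-0.5 * ((bins - center_a) / width) ** 2)
    spec_b = np.exp(-0.5 * ((bins - center_b) / width) ** 2)
    return [EmissionSpectrum(CHANNEL_A, spec_a), EmissionSpectrum(CHANNEL_B, spec_b)]


def _rng_from(config: SimulationConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def simulate_positions(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> ParticleTrajectories:
    """Simulate 2D Brownian trajectories for all three populations.

    Per-scan particle numbers are Poisson draws with mean
    ``mean_pop * area_ratio`` (the focal-area mean scaled to the box).
    Initial positions are uniform in the box; steps are i.i.d. Gaussian
    with per-axis variance ``2 * D * dt``; positions wrap periodically.
    """
    rng = _rng_from(config, rng)
    L = config.box_half_width
    means = {
        "free_a": config.mean_free_a,
        "free_b": config.mean_free_b,
        "complex": config.mean_complex,
    }
    positions: dict = {}
    for pop in POPULATIONS:
        n = int(rng.poisson(means[pop] * config.area_ratio))
        if n == 0:
            positions[pop] = np.zeros((config.n_frames, 0, 2), dtype=np.float32)
            continue
        start = rng.uniform(-L, L, size=(1, n, 2)).astype(np.float32)
        d = config.diffusion_of(pop)
        if d > 0:
            sd = math.sqrt(2.0 * d * config.frame_interval)
            steps = rng.normal(0.0, sd, size=(config.n_frames - 1, n, 2)).astype(np.float32)
            path = np.concatenate([start, steps], axis=0)
            np.cumsum(path, axis=0, out=path)
        else:
            path = np.broadcast_to(start, (config.n_frames, n, 2)).copy()
        # wrap into [-L, L)
        path = np.mod(path + L, 2.0 * L) - L
        positions[pop] = path
    return ParticleTrajectories(positions=positions, config=config)


def _population_signal(path: np.ndarray, brightness: float, waist: float) -> np.ndarray:
    """Summed Gaussian-profile detection signal of one population vs frame."""
    if path.shape[1] == 0:
        return np.zeros(path.shape[0])
    r2 = path[:, :, 0].astype(np.float64) ** 2 + path[:, :, 1].astype(np.float64) ** 2
    return brightness * np.exp(-2.0 * r2 / waist ** 2).sum(axis=1)


def traces_from_positions(
    traj: ParticleTrajectories,
    config: Optional[SimulationConfig] = None,
) -> tuple[IntensityTrace, IntensityTrace]:
    """Noise-free expected detection traces for both channels.

    Each molecule contributes ``brightness * exp(-2 r^2 / w^2)`` to its
    channel, with r the distance from the spot center (the box center);
    complexes carry one fluorophore of each color and contribute to both
    channels.
    """
    cfg = config if config is not None else traj.config
    if set(traj.positions) != set(POPULATIONS):
        raise ValueError(f"trajectories must carry populations {POPULATIONS}")
    n_frames = traj.n_frames
    for pop, arr in traj.positions.items():
        if arr.shape[0] != n_frames:
            raise ValueError(f"population {pop!r} frame count {arr.shape[0]} != {n_frames}")
    w = cfg.beam_waist
    sig_a = _population_signal(traj.positions["free_a"], cfg.brightness_a, w)
    sig_b = _population_signal(traj.positions["free_b"], cfg.brightness_b, w)
    # complexes carry one fluorophore of each color; compute geometry once
    prof_c = _population_signal(traj.positions["complex"], 1.0, w)
    trace_a = IntensityTrace(CHANNEL_A, sig_a + cfg.brightness_a * prof_c, cfg.frame_interval)
    trace_b = IntensityTrace(CHANNEL_B, sig_b + cfg.brightness_b * prof_c, cfg.frame_interval)
    return trace_a, trace_b


def spectral_frames_from_traces(
    traces: Sequence[IntensityTrace],
    spectra: Sequence[EmissionSpectrum],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
) -> ScanFrames:
    """Disperse channel traces over spectral bins and apply camera noise.

    Expected photons per bin and frame are ``sum_f I_f(t) * S_f + background``.
    With ``noise=True`` the realized camera counts are
    ``em_gain * Poisson(expected) + Normal(0, read_noise_sd)`` floored at
    zero (a simple EMCCD surrogate; the excess-noise factor of the EM
    register is not modeled). With ``noise=False`` the expected photon
    frames are returned unchanged (no gain), so unmixing inverts them
    exactly.
    """
    if len(traces) != len(spectra):
        raise ValueError("need exactly one spectrum per trace")
    by_id = {s.fluorophore: s for s in spectra}
    n_bins = {s.n_bins for s in spectra}
    if len(n_bins) != 1:
        raise ValueError("spectra are on different bin grids")
    expected = np.full((config.n_frames, n_bins.pop()), float(config.background))
    for trace in traces:
        if trace.fluorophore not in by_id:
            raise ValueError(f"no spectrum for fluorophore {trace.fluorophore!r}")
        if trace.n_frames != config.n_frames:
            raise ValueError("trace length does not match config.n_frames")
        expected += np.outer(trace.values, by_id[trace.fluorophore].weights)
    if not noise:
        counts = expected
    else:
        rng = _rng_from(config, rng)
        counts = config.em_gain * rng.poisson(expected).astype(float)
        if config.read_noise_sd > 0:
            counts += rng.normal(0.0, config.read_noise_sd, size=counts.shape)
        np.clip(counts, 0.0, None, out=counts)
    meta = {"seed": config.seed, "noise": noise, "em_gain": config.em_gain}
    return ScanFrames(counts=counts, frame_interval=config.frame_interval, meta=meta)


def simulate_scan(
    config: SimulationConfig,
    spectra: Optional[Sequence[EmissionSpectrum]] = None,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
) -> ScanFrames:
    """Full forward model for one scan: positions -> traces -> spectral frames."""
    rng = _rng_from(config, rng)
    if spectra is None:
        spectra = default_spectra(config.n_bins)
    traj = simulate_positions(config, rng=rng)
    traces = traces_from_positions(traj, config)
    return spectral_frames_from_traces(traces, spectra, config, rng=rng, noise=noise)


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-scan integer seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def simulate_condition(
    config: SimulationConfig,
    n_scans: int,
    master_seed: int,
    spectra: Optional[Sequence[EmissionSpectrum]] = None,
    noise: bool = True,
) -> list[ScanFrames]:
    """Simulate ``n_scans`` independent scans of one condition.

    Each scan redraws its particle numbers (Poisson) and trajectories
    from a child seed derived deterministically from ``master_seed``,
    emulating repeated scans at different spots of different cells.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    scans = []
    for seed in child_seeds(master_seed, n_scans):
        cfg = replace(config, seed=seed)
        scans.append(simulate_scan(cfg, spectra=spectra, noise=noise))
    return scans


def simulate_condition_traces(
    config: SimulationConfig,
    n_scans: int,
    master_seed: int,
) -> list[tuple[IntensityTrace, IntensityTrace]]:
    """Trace-only variant of :func:`simulate_condition` (no spectral stage).

    Returns the noise-free expected detection traces per scan; useful
    when the spectral unmixing stage is not under study.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    out = []
    for seed in child_seeds(master_seed, n_scans):
        cfg = replace(config, seed=seed)
        traj = simulate_positions(cfg)
        out.append(traces_from_positions(traj, cfg))
    return out
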