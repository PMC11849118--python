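"""Per-residue protein-lipid contact fractions from coordinate trajectories.

A residue is "in contact" with a lipid class during a frame when any of
its particles lies within a cutoff distance of any particle of that
class (minimum-image distances when a periodic box is given); the
contact fraction is the share of frames with contact. The default
cutoff of 6.0 A is a coarse-grained bead-scale convention (4.5 A is the
common heavy-atom choice for all-atom trajectories).

Lipid classes follow the monolayer/TAG composition of a lipid droplet
model: POPC, DOPE, SAPI phospholipids and the TAG core, plus "other".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "LIPID_CLASSES",
    "LabeledTrajectory",
    "contact_fraction",
    "binding_regions",
    "ContactSceneSpec",
    "synth_trajectory",
]

LIPID_CLASSES = ("POPC", "DOPE", "SAPI", "TAG", "other")
DEFAULT_CUTOFF = 6.0  # Angstrom


@dataclass
class LabeledTrajectory:
    """Coordinates plus per-particle labels over a trajectory.

    ``coords``: (n_frames, n_particles, 3) in Angstrom. Each particle is
    either protein (``residue_index >= 0``, ``lipid_class`` empty) or a
    lipid bead (``residue_index == -1``, ``lipid_class`` one of
    :data:`LIPID_CLASSES`). ``box``: optional per-frame orthorhombic box
    lengths (n_frames, 3) enabling minimum-image distances.
    """

    coords: np.ndarray
    residue_index: np.ndarray
    lipid_class: np.ndarray
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_particles, 3)")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates must be finite")
        res = np.asarray(self.residue_index, dtype=int)
        cls = np.asarray(self.lipid_class, dtype=object)
        if res.shape != (c.shape[1],) or cls.shape != (c.shape[1],):
            raise ValueError("labels must have one entry per particle")
        unknown = {str(x) for x in cls[res < 0]} - set(LIPID_CLASSES)
        if unknown:
            raise ValueError(f"unknown lipid class label(s): {sorted(unknown)}")
        if self.box is not None:
            b = np.asarray(self.box, dtype=float)
            if b.shape != (c.shape[0], 3):
                raise ValueError("box must have shape (n_frames, 3)")
            if np.any(b <= 0):
                raise ValueError("box lengths must be positive")
            self.box = b
        self.coords = c
        self.residue_index = res
        self.lipid_class = cls

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.residue_index[self.residue_index >= 0])


def _min_dist_tree(res_pts: np.ndarray, lip_pts: np.ndarray) -> np.ndarray:
    """Per-point distance to the nearest lipid particle (no box)."""
    tree = cKDTree(lip_pts)
    d, _ = tree.query(res_pts, k=1)
    return d


def _min_dist_brute(
    res_pts: np.ndarray, lip_pts: np.ndarray, box: Optional[np.ndarray]
) -> np.ndarray:
    """Per-point minimum distance by all-pairs search, minimum-image aware."""
    delta = res_pts[:, None, :] - lip_pts[None, :, :]
    if box is not None:
        delta -= box * np.rint(delta / box)
    return np.sqrt((delta**2).sum(axis=2)).min(axis=1)


def contact_fraction(
    traj: LabeledTrajectory,
    cutoff: float = DEFAULT_CUTOFF,
    classes: Sequence[str] = ("POPC", "DOPE", "SAPI", "TAG"),
    method: str = "auto",
) -> pd.DataFrame:
    """Residue x lipid-class matrix of contact fractions in [0, 1].

    ``method``: ``"tree"`` (k-d tree nearest neighbor, only without a
    box), ``"brute"`` (all-pairs, minimum-image aware) or ``"auto"``.
    An empty lipid class yields a zero column with a warning.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if traj.n_frames < 1:
        raise ValueError("trajectory must have at least one frame")
    unknown = set(classes) - set(LIPID_CLASSES)
    if unknown:
        raise ValueError(f"unknown lipid class label(s): {sorted(unknown)}")
    if method not in ("auto", "tree", "brute"):
        raise ValueError("method must be 'auto', 'tree' or 'brute'")
    if method == "tree" and traj.box is not None:
        raise ValueError("method 'tree' does not support periodic boxes")

    residues = traj.residues
    prot = traj.residue_index >= 0
    res_ids = traj.residue_index[prot]
    order = np.argsort(res_ids, kind="stable")
    res_ids_sorted = res_ids[order]
    # boundaries of each residue's particle block for grouped minima
    starts = np.searchsorted(res_ids_sorted, residues, side="left")

    counts = pd.DataFrame(0.0, index=residues, columns=list(classes))
    class_masks = {c: np.asarray([x == c for x in traj.lipid_class]) & ~prot for c in classes}
    for c in classes:
        if not class_masks[c].any():
            warnings.warn(f"lipid class {c!r} has no particles; fractions are 0", stacklevel=2)

    use_tree = method == "tree" or (method == "auto" and traj.box is None)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        res_pts = frame[prot][order]
        box = traj.box[f] if traj.box is not None else None
        for c in classes:
            lip_pts = frame[class_masks[c]]
            if lip_pts.shape[0] == 0:
                continue
            if use_tree:
                d = _min_dist_tree(res_pts, lip_pts)
            else:
                d = _min_dist_brute(res_pts, lip_pts, box)
            per_res = np.minimum.reduceat(d, starts)
            counts.loc[:, c] += (per_res <= cutoff).astype(float)
    fractions = counts / traj.n_frames
    fractions.index.name = "residue"
    return fractions


def binding_regions(
    fractions: pd.DataFrame,
    threshold: float = 0.5,
    min_run: int = 3,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residues with contact above threshold.

    A residue qualifies when its maximum contact fraction over the lipid
    classes is >= ``threshold``; runs shorter than ``min_run`` are
    dropped. Returns closed residue-index intervals.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    residues = np.asarray(fractions.index, dtype=int)
    hot = fractions.max(axis=1).to_numpy() >= threshold
    regions: list[tuple[int, int]] = []
    start = None
    prev = None
    for r, h in zip(residues, hot):
        contiguous = prev is not None and r == prev + 1
        if h and start is not None and contiguous:
            prev = r
            continue
        if start is not None and prev - start + 1 >= min_run:
            regions.append((int(start), int(prev)))
        start = r if h else None
        prev = r
    if start is not None and prev - start + 1 >= min_run:
        regions.append((int(start), int(prev)))
    return regions


@dataclass(frozen=True)
class ContactSceneSpec:
    """Toy-trajectory layout with planted, known contacts.

    ``n_residues`` protein particles sit on a line at ``far_distance``
    above a lipid plane (one bead per lipid per class at z=0).
    ``planted``: mapping residue -> (class, fraction of frames in
    contact); during contact frames the residue particle is placed
    ``contact_distance`` from that class bead. ``jitter_sd`` adds
    Gaussian positional noise.
    """

    n_residues: int = 10
    n_frames: int = 8
    lipid_counts: dict = None  # class -> count; default one bead per class
    planted: dict = None       # residue -> (class, fraction)
    far_distance: float = 50.0
    contact_distance: float = 2.0
    jitter_sd: float = 0.0
    spacing: float = 20.0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_frames < 1:
            raise ValueError("n_residues and n_frames must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.contact_distance <= 0 or self.far_distance <= self.contact_distance:
            raise ValueError("need far_distance > contact_distance > 0")
        object.__setattr__(self, "lipid_counts", dict(self.lipid_counts or {c: 1 for c in ("POPC", "DOPE", "SAPI", "TAG")}))
        planted = dict(self.planted or {})
        for res, (cls, frac) in planted.items():
            if not (0 <= res < self.n_residues):
                raise ValueError(f"planted residue {res} out of range")
            if cls not in self.lipid_counts:
                raise ValueError(f"planted class {cls!r} has no lipids in the scene")
            if not (0.0 <= frac <= 1.0):
                raise ValueError("planted fraction must be in [0, 1]")
        object.__setattr__(self, "planted", planted)


def synth_trajectory(spec: ContactSceneSpec, seed: int = 0) -> tuple[LabeledTrajectory, pd.DataFrame]:
    """Deterministic toy trajectory plus its ground-truth contact matrix.

    In noise-free mode (``jitter_sd=0``) the ground truth is exact for
    any cutoff between ``contact_distance`` and ``far_distance``'s
    geometry; with jitter it holds to within the jitter scale.
    """
    rng = np.random.default_rng(seed)
    classes = list(spec.lipid_counts)
    # lipid beads on a line at z=0, one block per class
    lipid_pos = []
    lipid_cls = []
    x = 0.0
    class_anchor = {}
    for c in classes:
        class_anchor[c] = x
        for _ in range(spec.lipid_counts[c]):
            lipid_pos.append([x, 0.0, 0.0])
            lipid_cls.append(c)
            x += spec.spacing
        x += spec.spacing
    lipid_pos = np.asarray(lipid_pos)
    n_lip = len(lipid_pos)

    res_home = np.column_stack(
        [
            np.arange(spec.n_residues) * spec.spacing,
            np.full(spec.n_residues, 2.0 * spec.spacing),
            np.full(spec.n_residues, spec.far_distance),
        ]
    )
    coords = np.empty((spec.n_frames, spec.n_residues + n_lip, 3))
    truth = pd.DataFrame(0.0, index=np.arange(spec.n_residues), columns=classes)
    contact_frames = {
        res: set(range(int(round(frac * spec.n_frames))))
        for res, (cls, frac) in spec.planted.items()
    }
    for f in range(spec.n_frames):
        frame_res = res_home.copy()
        for res, (cls, frac) in spec.planted.items():
            if f in contact_frames[res]:
                frame_res[res] = [class_anchor[cls], 0.0, spec.contact_distance]
        coords[f, : spec.n_residues] = frame_res
        coords[f, spec.n_residues :] = lipid_pos
        if spec.jitter_sd > 0:
            coords[f] += rng.normal(0.0, spec.jitter_sd, size=coords[f].shape)
    for res, (cls, frac) in spec.planted.items():
        truth.loc[res, cls] = len(contact_frames[res]) / spec.n_frames
    traj = LabeledTrajectory(
        coords=coords,
        residue_index=np.concatenate(
            [np.arange(spec.n_residues), -np.ones(n_lip, dtype=int)]
        ),
        lipid_class=np.asarray([""] * spec.n_residues + lipid_cls, dtype=object),
    )
    truth.index.name = "residue"
    return traj, truth
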