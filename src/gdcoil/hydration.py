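"""Hydration-shell statistics around a Gd(III) centre.

Post-processing of labelled multi-frame trajectories: the radial
distribution function of water hydrogens about the metal, the
second-shell occupancy distribution, and continuous-residence lifetime
analysis. Waters are counted per molecule — a molecule is in shell when
ANY of its selected hydrogens is — with molecule identity given by the
shared atom label (all hydrogens of one water carry the same label,
e.g. ``HW12``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["TrajectoryFrames", "RDFResult", "OccupancyResult",
           "LifetimeResult", "rdf", "shell_occupancy",
           "residence_lifetimes", "DEFAULT_SHELL"]

#: default second-shell bounds (Å), bracketing the ≈3.6 Å H_wat–Gd peak
DEFAULT_SHELL = (3.0, 4.5)


@dataclass
class TrajectoryFrames:
    """Time-ordered labelled coordinates.

    coords has shape (n_frames, n_atoms, 3) in Å; exactly one atom per
    frame carries the ``center_label`` prefix; ``dt_ns`` is the frame
    spacing; ``box`` gives orthorhombic box lengths (Å) when periodic.
    """

    coords: np.ndarray
    labels: Sequence[str]
    dt_ns: float
    center_label: str = "GD"
    water_label: str = "HW"
    box: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one frame")
        self.labels = list(self.labels)
        if len(self.labels) != self.coords.shape[1]:
            raise ValueError("labels must match the atom count")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be > 0")
        centers = [i for i, lab in enumerate(self.labels)
                   if lab.startswith(self.center_label)]
        if len(centers) != 1:
            raise ValueError(f"expected exactly one '{self.center_label}' "
                             f"centre atom, found {len(centers)}")
        self._center_idx = centers[0]
        if self.box is not None:
            self.box = tuple(float(b) for b in self.box)
            if len(self.box) != 3 or any(b <= 0 for b in self.box):
                raise ValueError("box must be three positive lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def length_ns(self) -> float:
        return self.n_frames * self.dt_ns

    def water_indices(self) -> np.ndarray:
        idx = np.array([i for i, lab in enumerate(self.labels)
                        if lab.startswith(self.water_label)], dtype=int)
        if idx.size == 0:
            raise ValueError(
                f"selector '{self.water_label}' matches no atoms; labels "
                f"present: {sorted({l[:2] for l in self.labels})}")
        return idx

    def molecules(self) -> List[np.ndarray]:
        """Water atoms grouped into molecules by identical label."""
        groups: Dict[str, List[int]] = {}
        order: List[str] = []
        for i in self.water_indices():
            lab = self.labels[i]
            if lab not in groups:
                groups[lab] = []
                order.append(lab)
            groups[lab].append(i)
        return [np.array(groups[lab], dtype=int) for lab in order]

    def center_distances(self, atom_idx: np.ndarray) -> np.ndarray:
        """Centre-to-atom distances, shape (n_frames, len(atom_idx));
        orthorhombic minimum image when a box is present."""
        d = self.coords[:, atom_idx, :] - self.coords[:, [self._center_idx], :]
        if self.box is not None:
            box = np.asarray(self.box)
            d -= box * np.round(d / box)
        return np.linalg.norm(d, axis=2)


@dataclass
class RDFResult:
    r: np.ndarray          # bin centres, Å
    g: np.ndarray
    counts: np.ndarray     # raw pair counts per bin (all frames)
    density: float         # mean target density used for normalisation
    n_frames: int


@dataclass
class OccupancyResult:
    histogram: Dict[int, float]   # occupancy -> fraction of frames
    mean: float
    per_frame: np.ndarray         # occupancy count per frame


@dataclass
class LifetimeResult:
    lifetimes_ns: np.ndarray      # completed (uncensored) residences
    censored_ns: np.ndarray       # runs touching a trajectory end
    survival_t: np.ndarray        # ns
    survival_s: np.ndarray        # S(t) = frac of uncensored lifetimes >= t


def rdf(traj: TrajectoryFrames, r_max: float, dr: float) -> RDFResult:
    """Radial distribution function of water hydrogens about the centre.

    g(r) = frame-averaged pair count per shell / (shell volume × ρ),
    with exact spherical-shell volumes and ρ the mean target density
    inside the analysis region (sphere of radius ``r_max``, or the box
    with minimum-image distances when periodic).
    """
    if not (r_max > dr > 0):
        raise ValueError("need r_max > dr > 0")
    if traj.box is not None and r_max > 0.5 * min(traj.box):
        raise ValueError("r_max exceeds half the shortest box length")
    dist = traj.center_distances(traj.water_indices())
    edges = np.arange(0.0, r_max + 0.5 * dr, dr)
    if edges[-1] < r_max:
        edges = np.append(edges, r_max)
    counts, edges = np.histogram(dist.ravel(), bins=edges)
    shell_vol = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    if traj.box is not None:
        rho = dist.shape[1] / float(np.prod(traj.box))
    else:
        n_in = np.mean(np.sum(dist < r_max, axis=1))
        rho = n_in / (4.0 * np.pi / 3.0 * r_max ** 3)
    if rho == 0:
        raise ValueError("no target atoms inside the analysis region")
    g = counts / (traj.n_frames * shell_vol * rho)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g, counts=counts, density=float(rho),
                     n_frames=traj.n_frames)


def _in_shell(traj: TrajectoryFrames, r_min: float,
              r_max: float) -> np.ndarray:
    """Boolean (n_frames, n_molecules): molecule in [r_min, r_max)."""
    if not (0 <= r_min < r_max):
        raise ValueError("need 0 <= r_min < r_max")
    mols = traj.molecules()
    out = np.zeros((traj.n_frames, len(mols)), dtype=bool)
    for j, atoms in enumerate(mols):
        d = traj.center_distances(atoms)
        out[:, j] = np.any((d >= r_min) & (d < r_max), axis=1)
    return out


def shell_occupancy(traj: TrajectoryFrames,
                    r_min: float = DEFAULT_SHELL[0],
                    r_max: float = DEFAULT_SHELL[1]) -> OccupancyResult:
    """Per-frame count of water molecules in the shell [r_min, r_max),
    its normalized histogram and mean."""
    occ = _in_shell(traj, r_min, r_max).sum(axis=1)
    values, freq = np.unique(occ, return_counts=True)
    hist = {int(v): float(c) / traj.n_frames for v, c in zip(values, freq)}
    return OccupancyResult(histogram=hist, mean=float(occ.mean()),
                           per_frame=occ)


def residence_lifetimes(traj: TrajectoryFrames,
                        r_min: float = DEFAULT_SHELL[0],
                        r_max: float = DEFAULT_SHELL[1]) -> LifetimeResult:
    """Continuous-residence lifetimes per water molecule.

    Maximal runs of consecutive in-shell frames become durations
    run_length × dt. Runs touching either trajectory end are censored
    (they only bound the true residence from below) and reported
    separately. The survival curve uses uncensored lifetimes only.
    """
    inside = _in_shell(traj, r_min, r_max)
    complete: List[float] = []
    censored: List[float] = []
    nf = traj.n_frames
    for j in range(inside.shape[1]):
        col = inside[:, j]
        if not col.any():
            continue
        padded = np.diff(np.concatenate(([0], col.view(np.int8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)  # exclusive
        for s, e in zip(starts, ends):
            dur = (e - s) * traj.dt_ns
            if s == 0 or e == nf:
                censored.append(dur)
            else:
                complete.append(dur)
    lifetimes = np.sort(np.asarray(complete, dtype=float))
    cens = np.sort(np.asarray(censored, dtype=float))
    if lifetimes.size:
        t = np.unique(lifetimes)
        s = np.array([(lifetimes >= ti).mean() for ti in t])
    else:
        t = np.empty(0)
        s = np.empty(0)
    return LifetimeResult(lifetimes_ns=lifetimes, censored_ns=cens,
                          survival_t=t, survival_s=s)
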