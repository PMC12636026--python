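"""Kinetic-stability, helicity and proteolysis summary statistics.

* ``ratio_index`` — the time for a challenge signal (e.g. Tb(III)
  emission under phosphate) to drop to 80 % of its initial value,
  the field's standard "ratio index" stability benchmark.
* ``helix_fraction`` — percent folded from the mean residue ellipticity
  at 222 nm.
* ``tryptic_fragments`` — trypsin digest prediction with isopeptide
  cross-linked lysines resistant to cleavage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple

import numpy as np

__all__ = [
    "DecaySeries", "CDRecord", "PeptideSequence", "Fragment",
    "RatioIndex", "ratio_index", "helix_fraction", "tryptic_fragments",
    "MB1_2", "KH2_20X",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class DecaySeries:
    """Challenge time series: time (min, strictly increasing from 0),
    signal, optional matched control channel."""

    time: np.ndarray
    signal: np.ndarray
    control: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.size != self.signal.size:
            raise ValueError("time and signal must have equal length")
        if self.time[0] != 0.0 or np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing from 0")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
            if self.control.size != self.time.size:
                raise ValueError("control must match the time grid")
            if np.any(self.control <= 0):
                raise ValueError("control must be positive")


@dataclass
class CDRecord:
    """CD observable: mean residue ellipticity at 222 nm
    (deg·cm²·dmol⁻¹) and the peptide length it was normalised with."""

    mre_222: float
    n_residues: int
    temperature: float = 293.0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")


@dataclass
class PeptideSequence:
    """One-letter sequence with terminal caps and isopeptide
    cross-linked lysine positions (1-based)."""

    residues: str
    n_term_cap: str = "none"       # none | acetyl
    c_term_cap: str = "none"       # none | amide
    crosslinked_positions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("sequence must be non-empty")
        bad = set(self.residues) - _AA
        if bad:
            raise ValueError(f"non-standard residues: {sorted(bad)}")
        if self.n_term_cap not in ("none", "acetyl"):
            raise ValueError("n_term_cap must be 'none' or 'acetyl'")
        if self.c_term_cap not in ("none", "amide"):
            raise ValueError("c_term_cap must be 'none' or 'amide'")
        for pos in self.crosslinked_positions:
            if not 1 <= pos <= len(self.residues):
                raise ValueError(f"cross-link position {pos} out of range")
            if self.residues[pos - 1] != "K":
                raise ValueError(f"cross-link position {pos} is "
                                 f"'{self.residues[pos - 1]}', not K")


class RatioIndex(NamedTuple):
    time_min: float
    censored: bool


def ratio_index(series: DecaySeries, threshold: float = 0.8) -> RatioIndex:
    """Earliest time at which the normalized signal falls to
    ``threshold`` of its initial value (linear interpolation between
    bracketing samples); censored at t_max when never crossed.

    When a control channel is present, the signal is divided by it
    point-wise before normalization (challenge vs buffer control).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    sig = series.signal.copy()
    if series.control is not None:
        sig = sig / series.control
    if sig[0] == 0:
        raise ValueError("initial signal must be nonzero")
    norm = sig / sig[0]
    below = norm <= threshold
    if not below.any():
        return RatioIndex(float(series.time[-1]), True)
    k = int(np.argmax(below))
    if k == 0:
        return RatioIndex(float(series.time[0]), False)
    t0, t1 = series.time[k - 1], series.time[k]
    y0, y1 = norm[k - 1], norm[k]
    t = t0 + (threshold - y0) * (t1 - t0) / (y1 - y0)
    return RatioIndex(float(t), False)


def helix_fraction(record: CDRecord,
                   theta_coil: float = 640.0,
                   theta_helix: Optional[float] = None):
    """Fraction folded from θ_222.

    Uses the chain-length-corrected helix limit
    θ_helix = −40000·(1 − 2.5/n) and θ_coil = +640 deg·cm²·dmol⁻¹ by
    default (both configurable; the choice is recorded by the caller).
    Returns ``(fraction, out_of_range)`` with the fraction clipped to
    [0, 1].
    """
    th = (-40000.0 * (1.0 - 2.5 / record.n_residues)
          if theta_helix is None else theta_helix)
    if th == theta_coil:
        raise ValueError("degenerate helicity endpoints (theta_helix == "
                         "theta_coil)")
    f = (record.mre_222 - theta_coil) / (th - theta_coil)
    out_of_range = not (0.0 <= f <= 1.0)
    return float(np.clip(f, 0.0, 1.0)), out_of_range


@dataclass(frozen=True)
class Fragment:
    """A digest product: sequence plus surviving terminal caps and the
    1-based span within the parent."""

    sequence: str
    start: int
    end: int
    n_term_cap: str = "none"
    c_term_cap: str = "none"
    missed_cleavages: int = 0

    def __str__(self) -> str:
        pre = "Ac-" if self.n_term_cap == "acetyl" else ""
        post = "-NH2" if self.c_term_cap == "amide" else ""
        return f"{pre}{self.sequence}{post}"


def _cleavage_sites(seq: PeptideSequence) -> List[int]:
    """0-based indices i such that trypsin cuts between residue i and
    i+1: after K/R, not before P, and not at a cross-linked K."""
    s = seq.residues
    xl = set(seq.crosslinked_positions)
    sites = []
    for i in range(len(s) - 1):
        if s[i] in "KR" and s[i + 1] != "P" and (i + 1) not in xl:
            sites.append(i)
    return sites


def tryptic_fragments(seq: PeptideSequence,
                      max_missed_cleavages: int = 0) -> List[Fragment]:
    """Predicted trypsin digest products.

    Cleaves C-terminal to every Lys/Arg except before Pro and at
    cross-linked lysines (the modified side chain is protease
    resistant). With ``max_missed_cleavages = 0`` the fragments
    concatenate exactly to the input, in order; a positive value
    additionally enumerates partial-digestion products with up to that
    many internal sites retained.
    """
    sites = _cleavage_sites(seq)
    edges = [-1] + sites + [len(seq.residues) - 1]
    frags: List[Fragment] = []
    for a_idx in range(len(edges) - 1):
        top = min(a_idx + 1 + max_missed_cleavages, len(edges) - 1)
        for b_idx in range(a_idx + 1, top + 1):
            start, end = edges[a_idx] + 1, edges[b_idx]
            frags.append(Fragment(
                sequence=seq.residues[start:end + 1],
                start=start + 1, end=end + 1,
                n_term_cap=seq.n_term_cap if start == 0 else "none",
                c_term_cap=(seq.c_term_cap
                            if end == len(seq.residues) - 1 else "none"),
                missed_cleavages=b_idx - a_idx - 1,
            ))
    frags.sort(key=lambda f: (f.start, f.end))
    if max_missed_cleavages == 0:
        frags.sort(key=lambda f: f.start)
    return frags


# Sequences of the two peptides (five heptads flanked by capped Gly).
# KH2-20X carries the isopeptide cross-link at Lys15 (g) to Glu20 (e)
# on the adjacent strand, which renders Lys15 trypsin-resistant.
MB1_2 = PeptideSequence(
    residues="GIAAIEQKIAANEWKDAAIEQKIAAIEQKIAAIEQKG",
    n_term_cap="acetyl", c_term_cap="amide",
)

KH2_20X = PeptideSequence(
    residues=MB1_2.residues,
    n_term_cap="acetyl", c_term_cap="amide",
    crosslinked_positions=(15,),
)
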