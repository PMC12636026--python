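"""Seeded generators emulating each measurement the analyses consume.

Every generator draws from one ``numpy.random.default_rng(seed)``
stream in a documented order, so output is bit-reproducible under a
fixed seed. Defaults reproduce the study conditions: 30 log-spaced
NMRD frequencies over 0.01–70 MHz, 3.3 μM peptide sites with the metal
delivered as an equimolar EGTA complex, first-order emission decay
under phosphate challenge, and a 3.6 Å tethered second shell with
exponential dwell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .binding import BindingModel, TitrationSeries, speciation_1to1
from .hydration import TrajectoryFrames
from .kinetics import DecaySeries
from .relaxation import NMRDProfile, RelaxationModel, total_r1_profile

__all__ = ["NoiseModel", "default_frequency_grid", "gen_nmrd",
           "gen_competition_titration", "gen_decay", "gen_trajectory"]


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: 'multiplicative' (y·(1+σε)) or 'additive'
    (y+σε), ε ~ N(0,1)."""

    kind: str
    sigma: float

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative", "additive"):
            raise ValueError("kind must be 'multiplicative' or 'additive'")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(y.shape)
        if self.kind == "multiplicative":
            return y * (1.0 + self.sigma * eps)
        return y + self.sigma * eps

    def describe(self) -> str:
        return f"{self.kind} gaussian, sigma={self.sigma}"


def default_frequency_grid(n_points: int = 30) -> np.ndarray:
    """Log-spaced proton Larmor frequencies, 0.01–70 MHz."""
    return np.geomspace(0.01, 70.0, n_points)


def gen_nmrd(model: RelaxationModel,
             frequencies: Optional[Sequence[float]] = None,
             noise: Optional[NoiseModel] = None,
             seed: int = 0, label: str = "") -> NMRDProfile:
    """Forward-simulated NMRD profile, optionally with noise.

    With ``noise=None`` the output equals ``total_r1_profile`` bitwise.
    """
    freqs = (default_frequency_grid() if frequencies is None
             else np.asarray(frequencies, dtype=float))
    profile = total_r1_profile(freqs, model)
    tag = label or "synthetic nmrd"
    if noise is None:
        profile.label = f"{tag} (noise: none)"
        return profile
    rng = np.random.default_rng(seed)
    r1 = noise.apply(profile.r1, rng)
    if np.any(r1 <= 0):
        raise ValueError("noise drove relaxivity non-positive; reduce sigma")
    return NMRDProfile(frequencies=freqs, r1=r1,
                       temperature=model.temperature,
                       label=f"{tag} (noise: {noise.describe()})")


def gen_competition_titration(model: BindingModel,
                              metal_totals: Optional[Sequence[float]] = None,
                              peptide_total: float = 3.3,
                              competitor_totals="equimolar",
                              noise: Optional[NoiseModel] = None,
                              seed: int = 0) -> TitrationSeries:
    """Competition (or direct) titration from two 1:1 equilibria.

    ``competitor_totals='equimolar'`` delivers the metal as a 1:1
    metal–competitor complex (E_T = M_T at every point), the usual
    EGTA-buffered titration design; pass 0 for a direct titration or an
    explicit array otherwise. Concentrations in μM.
    """
    mt = (np.linspace(0.0, 3.0 * peptide_total, 20)
          if metal_totals is None else np.asarray(metal_totals, float))
    if isinstance(competitor_totals, str):
        if competitor_totals != "equimolar":
            raise ValueError("competitor_totals must be an array, 0, or "
                             "'equimolar'")
        et = mt.copy()
    else:
        et = np.broadcast_to(np.asarray(competitor_totals, float),
                             mt.shape).copy()
    _, mp, me = speciation_1to1(mt, peptide_total, et,
                                10.0 ** model.log_ka_peptide,
                                10.0 ** model.log_ka_competitor)
    signal = (model.signal_baseline + model.signal_bound_peptide * mp
              + model.signal_bound_competitor * me)
    if noise is not None:
        signal = noise.apply(signal, np.random.default_rng(seed))
    return TitrationSeries(metal_total=mt, signal=signal,
                           peptide_total=peptide_total,
                           competitor_total=et)


def gen_decay(k_per_min: float,
              t_grid_min: Optional[Sequence[float]] = None,
              noise: Optional[NoiseModel] = None,
              with_control: bool = False,
              seed: int = 0) -> DecaySeries:
    """First-order emission decay exp(−k·t) under a challenge, with an
    optional flat unit control channel."""
    if k_per_min < 0:
        raise ValueError("k must be >= 0")
    t = (np.linspace(0.0, 1440.0, 145) if t_grid_min is None
         else np.asarray(t_grid_min, float))
    sig = np.exp(-k_per_min * t)
    if noise is not None:
        sig = noise.apply(sig, np.random.default_rng(seed))
    control = np.ones_like(t) if with_control else None
    return DecaySeries(time=t, signal=sig, control=control)


def gen_trajectory(n_frames: int = 1000, dt_ns: float = 0.1,
                   n_bulk: int = 50, n_tethered: int = 2,
                   tau_res_ns: float = 4.0, shell_radius_A: float = 3.6,
                   region_radius_A: float = 12.0, p_in: float = 0.5,
                   seed: int = 0) -> TrajectoryFrames:
    """Labelled trajectory with one Gd centre, ideal-gas bulk waters and
    telegraph-process tethered second-shell waters.

    Bulk waters (labels ``HWB<i>``) are redrawn uniformly in the
    analysis sphere every frame (ideal gas). Tethered waters (labels
    ``HWT<i>``) alternate between the shell radius and the bulk with
    exponential dwell: per-frame leave probability dt/τ_res, re-entry
    probability chosen so the stationary in-shell fraction is ``p_in``
    (symmetric when p_in = 0.5). Draw order per frame: bulk positions,
    then per tethered water the state update and its position.
    """
    if n_bulk < 0 or n_tethered < 0:
        raise ValueError("water counts must be >= 0")
    if n_bulk + n_tethered == 0:
        raise ValueError("need at least one water")
    if tau_res_ns <= 0:
        raise ValueError("tau_res_ns must be > 0")
    if not 0 < p_in < 1:
        raise ValueError("p_in must lie in (0, 1)")
    if not 0 < shell_radius_A < region_radius_A:
        raise ValueError("shell radius must lie inside the analysis sphere")
    static = np.isinf(tau_res_ns)
    p_leave = 0.0 if static else dt_ns / tau_res_ns
    if p_leave >= 1.0:
        raise ValueError("dt_ns must be smaller than tau_res_ns")
    p_enter = min(p_leave * p_in / (1.0 - p_in), 1.0)

    rng = np.random.default_rng(seed)
    n_atoms = 1 + n_bulk + n_tethered
    labels = (["GD"] + [f"HWB{i}" for i in range(n_bulk)]
              + [f"HWT{i}" for i in range(n_tethered)])
    coords = np.zeros((n_frames, n_atoms, 3))
    # τ_res = ∞ means permanently tethered; otherwise start from the
    # stationary distribution of the telegraph process.
    state = (np.ones(n_tethered, dtype=bool) if static
             else rng.random(n_tethered) < p_in)

    def uniform_in_sphere(n, r_lo, r_hi):
        u = rng.random((n, 1))
        r = (r_lo ** 3 + u * (r_hi ** 3 - r_lo ** 3)) ** (1.0 / 3.0)
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return r * v

    for f in range(n_frames):
        if n_bulk:
            coords[f, 1:1 + n_bulk] = uniform_in_sphere(
                n_bulk, 0.0, region_radius_A)
        for j in range(n_tethered):
            u = rng.random()
            state[j] = (u >= p_leave) if state[j] else (u < p_enter)
            if state[j]:
                pos = uniform_in_sphere(1, shell_radius_A, shell_radius_A)
            else:  # parked well outside the shell, inside the region
                pos = uniform_in_sphere(1, 0.6 * region_radius_A,
                                        region_radius_A)
            coords[f, 1 + n_bulk + j] = pos[0]
    return TrajectoryFrames(coords=coords, labels=labels, dt_ns=dt_ns)
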