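"""Forward model of longitudinal water-proton relaxivity r1(ν).

The model describes a Gd(III) centre with **no** inner-sphere water.
Relaxivity is the sum of

* a second-sphere dipolar term: a few water molecules hydrogen-bonded
  near the metal (q_ss at distance r_ss) whose motion is split into a
  slow global tumbling (τ_RG) and a fast local rotation (τ_RL) coupled
  by a Lipari–Szabo order parameter S², and
* a Freed outer-sphere term from freely diffusing water (closest
  approach a, relative diffusion coefficient D),

both modulated by Gd(III) electron-spin relaxation driven by a
transient zero-field splitting (Δ², τ_v).

Internally everything is SI (s, rad/s, m); the public surface speaks
MHz, Å and mM⁻¹·s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .constants import (
    GAMMA_H,
    HBAR,
    MU0_OVER_4PI,
    MU_B,
    N_AVOGADRO,
    WATER_MOLARITY_MM,
    gamma_electron,
)

__all__ = [
    "ElectronSpinParams",
    "SecondSphereParams",
    "OuterSphereParams",
    "RelaxationModel",
    "NMRDProfile",
    "angular_frequencies",
    "lipari_szabo_j",
    "electron_relaxation_rates",
    "second_sphere_r1",
    "freed_j",
    "outer_sphere_r1",
    "total_r1_profile",
    "kh2_20x_model",
    "mb1_2_model",
]

ANGSTROM = 1.0e-10


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ElectronSpinParams:
    """Gd(III) electron-spin parameters (transient zero-field splitting).

    Parameters
    ----------
    delta2 : mean-square ZFS fluctuation Δ², s⁻².
    tau_v : ZFS correlation time τ_v, s.
    spin : electron spin quantum number S (7/2 for Gd(III)).
    g : electron g-factor.
    """

    delta2: float = 1.0e19
    tau_v: float = 20.0e-12
    spin: float = 3.5
    g: float = 2.0

    def __post_init__(self) -> None:
        _require(self.spin > 0 and float(2 * self.spin).is_integer(),
                 "spin must be a positive half-integer")
        _require(self.delta2 >= 0, "delta2 must be >= 0")
        _require(self.tau_v > 0, "tau_v must be > 0")
        _require(self.g > 0, "g must be > 0")


@dataclass(frozen=True)
class SecondSphereParams:
    """Second-sphere water pool.

    q_ss waters at Gd–H distance ``r_ss_A`` (Å), residence time
    ``tau_m_ss`` (s), with Lipari–Szabo dynamics: global correlation
    time ``tau_rg``, local ``tau_rl`` (s), order parameter ``s2``.
    """

    q_ss: float = 2.0
    r_ss_A: float = 3.6
    tau_m_ss: float = 5.0e-9
    tau_rg: float = 7.0e-9
    tau_rl: float = 318.0e-12
    s2: float = 0.5

    def __post_init__(self) -> None:
        _require(self.q_ss >= 0, "q_ss must be >= 0")
        _require(self.r_ss_A > 0, "r_ss_A must be > 0")
        for name in ("tau_m_ss", "tau_rg", "tau_rl"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0.0 <= self.s2 <= 1.0, "s2 must lie in [0, 1]")


@dataclass(frozen=True)
class OuterSphereParams:
    """Freed outer-sphere parameters: closest approach ``a_A`` (Å) and
    relative diffusion coefficient ``d`` (m²·s⁻¹)."""

    a_A: float = 4.0
    d: float = 2.3e-10

    def __post_init__(self) -> None:
        _require(self.a_A > 0, "a_A must be > 0")
        _require(self.d > 0, "d must be > 0")

    @property
    def tau_d(self) -> float:
        """Translational diffusion correlation time τ_D = a²/D, s."""
        a_m = self.a_A * ANGSTROM
        return a_m * a_m / self.d


@dataclass(frozen=True)
class RelaxationModel:
    """Complete parameter set for the q=0 (no inner sphere) model."""

    second_sphere: SecondSphereParams = field(default_factory=SecondSphereParams)
    outer_sphere: OuterSphereParams = field(default_factory=OuterSphereParams)
    electron: ElectronSpinParams = field(default_factory=ElectronSpinParams)
    temperature: float = 298.0  # K, metadata only

    def replace(self, **updates) -> "RelaxationModel":
        """Return a copy with leaf parameters replaced by keyword.

        Recognised keys are the field names of the three component
        dataclasses (e.g. ``tau_rl``, ``s2``, ``delta2``, ``q_ss``).
        """
        ss = {k: v for k, v in updates.items()
              if k in SecondSphereParams.__dataclass_fields__}
        os_ = {k: v for k, v in updates.items()
               if k in OuterSphereParams.__dataclass_fields__}
        el = {k: v for k, v in updates.items()
              if k in ElectronSpinParams.__dataclass_fields__}
        unknown = set(updates) - set(ss) - set(os_) - set(el)
        _require(not unknown, f"unknown model parameters: {sorted(unknown)}")
        return RelaxationModel(
            second_sphere=replace(self.second_sphere, **ss),
            outer_sphere=replace(self.outer_sphere, **os_),
            electron=replace(self.electron, **el),
            temperature=self.temperature,
        )


@dataclass
class NMRDProfile:
    """A ¹H NMRD profile: relaxivity vs proton Larmor frequency.

    frequencies are in MHz (strictly increasing, > 0), r1 in mM⁻¹·s⁻¹.
    """

    frequencies: np.ndarray
    r1: np.ndarray
    r1_err: Optional[np.ndarray] = None
    temperature: float = 298.0
    concentration_mM: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.r1 = np.asarray(self.r1, dtype=float)
        _require(self.frequencies.ndim == 1, "frequencies must be 1-D")
        _require(self.frequencies.shape == self.r1.shape,
                 "frequencies and r1 must have equal length")
        _require(np.all(self.frequencies > 0), "frequencies must be > 0")
        _require(np.all(np.diff(self.frequencies) > 0),
                 "frequencies must be strictly increasing")
        _require(np.all(self.r1 > 0), "r1 must be > 0")
        if self.r1_err is not None:
            self.r1_err = np.asarray(self.r1_err, dtype=float)
            _require(self.r1_err.shape == self.r1.shape,
                     "r1_err must match r1 in length")
            _require(np.all(self.r1_err > 0), "r1_err must be > 0")

    def __len__(self) -> int:
        return self.frequencies.size


# ---------------------------------------------------------------------------
# spectral densities and rates


def angular_frequencies(nu_mhz, g: float = 2.0):
    """Proton and electron angular Larmor frequencies (rad/s) at a given
    proton Larmor frequency in MHz."""
    nu = np.asarray(nu_mhz, dtype=float)
    _require(bool(np.all(nu > 0)), "frequency must be > 0 MHz")
    omega_i = 2.0 * np.pi * nu * 1.0e6
    omega_s = (gamma_electron(g) / GAMMA_H) * omega_i
    return omega_i, omega_s


def lipari_szabo_j(omega, tau_global: float, tau_local: float, s2: float):
    """Lipari–Szabo model-free spectral density (units of time, s).

    J(ω) = S²·τ_g/(1+ω²τ_g²) + (1−S²)·τ_l/(1+ω²τ_l²)
    """
    _require(tau_global > 0 and tau_local > 0, "correlation times must be > 0")
    _require(0.0 <= s2 <= 1.0, "S2 must lie in [0, 1]")
    omega = np.asarray(omega, dtype=float)
    return (s2 * tau_global / (1.0 + (omega * tau_global) ** 2)
            + (1.0 - s2) * tau_local / (1.0 + (omega * tau_local) ** 2))


def electron_relaxation_rates(omega_s, electron: ElectronSpinParams):
    """Longitudinal and transverse electron-spin relaxation rates
    (1/T1e, 1/T2e in s⁻¹) in the transient-ZFS model."""
    omega_s = np.asarray(omega_s, dtype=float)
    s = electron.spin
    pref = 4.0 * s * (s + 1.0) - 3.0
    x = (omega_s * electron.tau_v) ** 2
    r1e = (electron.delta2 * electron.tau_v / 25.0) * pref * (
        1.0 / (1.0 + x) + 4.0 / (1.0 + 4.0 * x))
    r2e = (electron.delta2 * electron.tau_v / 50.0) * pref * (
        3.0 + 5.0 / (1.0 + x) + 2.0 / (1.0 + 4.0 * x))
    return r1e, r2e


def _dipolar_prefactor(electron: ElectronSpinParams, r_ss_A: float) -> float:
    # (2/15)(μ0/4π)² γI² g² μB² S(S+1) / r⁶  — SBM dipolar constant, s⁻²
    r_m = r_ss_A * ANGSTROM
    s = electron.spin
    return ((2.0 / 15.0) * MU0_OVER_4PI ** 2 * GAMMA_H ** 2
            * electron.g ** 2 * MU_B ** 2 * s * (s + 1.0) / r_m ** 6)


def second_sphere_r1(nu_mhz, ss: SecondSphereParams,
                     electron: ElectronSpinParams):
    """Second-sphere relaxivity (mM⁻¹·s⁻¹) at proton frequency nu_mhz.

    The ω_I dipolar term uses effective correlation times built from
    1/τ_RG (global) or 1/τ_RL (local), plus 1/τ_M^SS and 1/T1e; the ω_S
    term pairs with 1/T2e.
    """
    omega_i, omega_s = angular_frequencies(nu_mhz, electron.g)
    r1e, r2e = electron_relaxation_rates(omega_s, electron)

    def eff(tau_rot, rate_e):
        return 1.0 / (1.0 / tau_rot + 1.0 / ss.tau_m_ss + rate_e)

    j_i = _ls_mixed(omega_i, eff(ss.tau_rg, r1e), eff(ss.tau_rl, r1e), ss.s2)
    j_s = _ls_mixed(omega_s, eff(ss.tau_rg, r2e), eff(ss.tau_rl, r2e), ss.s2)
    rate_1m = _dipolar_prefactor(electron, ss.r_ss_A) * (3.0 * j_i + 7.0 * j_s)
    t1m = 1.0 / rate_1m
    return (ss.q_ss / WATER_MOLARITY_MM) / (t1m + ss.tau_m_ss)


def _ls_mixed(omega, tau_g, tau_l, s2):
    # Lipari–Szabo sum where τ_g/τ_l may themselves be arrays (they carry
    # the frequency-dependent electron rates).
    return (s2 * tau_g / (1.0 + (omega * tau_g) ** 2)
            + (1.0 - s2) * tau_l / (1.0 + (omega * tau_l) ** 2))


def freed_j(omega, tau_d: float, t_je: float = np.inf):
    """Freed dimensionless spectral density for translational diffusion.

    z = sqrt(iωτ_D + τ_D/T_je);  J = Re[(1 + z/4)/(1 + z + 4z²/9 + z³/9)].
    Bounded in (0, 1].
    """
    _require(tau_d > 0, "tau_d must be > 0")
    omega = np.asarray(omega, dtype=float)
    leak = 0.0 if np.isinf(t_je) else tau_d / t_je
    z = np.sqrt(1j * omega * tau_d + leak)
    num = 1.0 + z / 4.0
    den = 1.0 + z + 4.0 * z ** 2 / 9.0 + z ** 3 / 9.0
    return np.real(num / den)


def _freed_j_rate(omega, tau_d, rate_e):
    # freed_j parameterised by an electron *rate* array (1/T_je).
    z = np.sqrt(1j * np.asarray(omega, float) * tau_d + tau_d * rate_e)
    return np.real((1.0 + z / 4.0)
                   / (1.0 + z + 4.0 * z ** 2 / 9.0 + z ** 3 / 9.0))


def outer_sphere_constant(electron: ElectronSpinParams) -> float:
    """Freed prefactor C_os (per-mM units): (32π/405)(μ0/4π)²γ_I²γ_S²ħ²
    S(S+1)·N_A per mol·m⁻³ (1 mM = 1 mol·m⁻³)."""
    s = electron.spin
    gamma_s = gamma_electron(electron.g)
    return ((32.0 * np.pi / 405.0) * MU0_OVER_4PI ** 2 * GAMMA_H ** 2
            * gamma_s ** 2 * HBAR ** 2 * s * (s + 1.0) * N_AVOGADRO)


def outer_sphere_r1(nu_mhz, os_params: OuterSphereParams,
                    electron: ElectronSpinParams):
    """Outer-sphere relaxivity (mM⁻¹·s⁻¹) from the Freed model."""
    omega_i, omega_s = angular_frequencies(nu_mhz, electron.g)
    r1e, r2e = electron_relaxation_rates(omega_s, electron)
    tau_d = os_params.tau_d
    a_m = os_params.a_A * ANGSTROM
    c_os = outer_sphere_constant(electron) / (a_m * os_params.d)
    return c_os * (3.0 * _freed_j_rate(omega_i, tau_d, r1e)
                   + 7.0 * _freed_j_rate(omega_s, tau_d, r2e))


def total_r1_profile(frequencies: Sequence[float],
                     model: RelaxationModel,
                     label: str = "") -> NMRDProfile:
    """Forward-simulate r1(ν) = second-sphere + outer-sphere terms."""
    freqs = np.asarray(frequencies, dtype=float)
    _require(freqs.ndim == 1 and freqs.size > 0, "need a 1-D frequency grid")
    _require(bool(np.all(freqs > 0)), "frequencies must be > 0")
    _require(bool(np.all(np.diff(freqs) > 0)),
             "frequencies must be strictly increasing")
    r1 = (second_sphere_r1(freqs, model.second_sphere, model.electron)
          + outer_sphere_r1(freqs, model.outer_sphere, model.electron))
    return NMRDProfile(frequencies=freqs, r1=np.asarray(r1, float),
                       temperature=model.temperature, label=label)


# ---------------------------------------------------------------------------
# published parameterizations (main-text values; electron-spin defaults)


def kh2_20x_model() -> RelaxationModel:
    """Cross-linked Gd(KH2-20X): τ_RG = 7 ns, τ_RL = 318 ps, τ_M^SS = 5 ns."""
    return RelaxationModel(
        second_sphere=SecondSphereParams(q_ss=2.0, r_ss_A=3.6,
                                         tau_m_ss=5.0e-9, tau_rg=7.0e-9,
                                         tau_rl=318.0e-12, s2=0.5),
        outer_sphere=OuterSphereParams(a_A=4.0, d=2.3e-10),
        electron=ElectronSpinParams(),
    )


def mb1_2_model() -> RelaxationModel:
    """Non-cross-linked Gd(MB1-2)₃: τ_RG = 5 ns, τ_RL = 184 ps, τ_M^SS = 3 ns."""
    return RelaxationModel(
        second_sphere=SecondSphereParams(q_ss=2.0, r_ss_A=3.6,
                                         tau_m_ss=3.0e-9, tau_rg=5.0e-9,
                                         tau_rl=184.0e-12, s2=0.5),
        outer_sphere=OuterSphereParams(a_A=4.0, d=2.3e-10),
        electron=ElectronSpinParams(),
    )
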