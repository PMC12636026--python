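"""Physical constants (SI) used throughout the relaxation model.

Values are CODATA-2018; they are fixed here so that every computed
relaxivity is bit-reproducible.
"""

MU0_OVER_4PI = 1.0e-7
"""Vacuum permeability / 4π, T·m·A⁻¹."""

GAMMA_H = 2.6752218744e8
"""¹H gyromagnetic ratio, rad·s⁻¹·T⁻¹."""

MU_B = 9.2740100783e-24
"""Bohr magneton, J·T⁻¹."""

HBAR = 1.054571817e-34
"""Reduced Planck constant, J·s."""

N_AVOGADRO = 6.02214076e23
"""Avogadro constant, mol⁻¹."""

WATER_MOLARITY_MM = 55500.0
"""Molar concentration of pure water, mM; enters the second-sphere
mole-fraction factor q/55500."""


def gamma_electron(g: float = 2.0) -> float:
    """Electron gyromagnetic ratio γ_S = g·μ_B/ħ in rad·s⁻¹·T⁻¹."""
    return g * MU_B / HBAR
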