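# gdcoil

Quantitative analyses for lanthanide-binding coiled-coil MRI contrast
agents: ¹H NMRD relaxometry of an inner-sphere-free Gd(III) centre,
Ln(III) affinity inference from luminescence titrations, kinetic- and
proteolytic-stability statistics, and hydration-shell trajectory
statistics — plus seeded synthetic-data generators so every analysis is
exercisable offline.

It is written for chemists and structural biologists working on de novo
peptide scaffolds (three-helix bundles with an engineered Ln(III) site)
who need to turn raw relaxometric, spectroscopic and simulation outputs
into the numbers such studies report.

## The model at the core

For a Gd(III) site with no inner-sphere water, longitudinal relaxivity
is the sum of a **second-sphere** dipolar term and a **Freed
outer-sphere** term:

r₁(ν) = r₁^SS(ν) + r₁^OS(ν)

The second-sphere term treats q^SS waters at Gd–H distance r^SS with
residence time τ_M^SS, whose motion splits into global tumbling (τ_RG)
and fast local rotation (τ_RL) coupled by a Lipari–Szabo order
parameter S²:

- J(ω) = S²·τ_g/(1+ω²τ_g²) + (1−S²)·τ_l/(1+ω²τ_l²), with
  1/τ_{g,l} = 1/τ_{RG,RL} + 1/τ_M^SS + 1/T_{1,2e}
- 1/T₁m = (2/15)(μ₀/4π)² γ_I² g² μ_B² S(S+1) r⁻⁶ [3J(ω_I) + 7J(ω_S)]
- r₁^SS = (q^SS/55500) / (T₁m + τ_M^SS)

Electron-spin relaxation follows the transient zero-field-splitting
model (Δ², τ_v), and the outer-sphere term is the Freed expression with
closest approach a and relative diffusion coefficient D. NMRD profiles
are fitted by seeded multi-start weighted least squares with a
user-declared free/fixed partition (typically free: τ_RL, τ_M^SS, S²).

Binding analysis solves the exact two-ligand 1:1 speciation (always
with depletion) to fit EGTA-competition titrations for an apparent
log K_a, alongside Hill fits of direct titrations. Hydration analysis
computes the Gd–H_wat radial distribution function, second-shell
(3.0–4.5 Å) occupancy histograms and continuous-residence lifetimes
from labelled trajectories.

## Worked example

```python
import numpy as np
from gdcoil import kh2_20x_model, gen_nmrd, fit_nmrd

model = kh2_20x_model()          # cross-linked bundle parameterization
profile = gen_nmrd(model)        # 30 noiseless points, 0.01-70 MHz
fit = fit_nmrd(profile, free=("tau_rl", "tau_m_ss", "s2"),
               model=model, n_starts=8, seed=0)
print(f"tau_RL  = {fit.fitted_values['tau_rl'] * 1e12:.1f} ps")
print(f"tau_MSS = {fit.fitted_values['tau_m_ss'] * 1e9:.2f} ns")
print(f"S2      = {fit.fitted_values['s2']:.3f}")
```

prints

```
tau_RL  = 318.0 ps
tau_MSS = 5.00 ns
S2      = 0.500
```

i.e. the refit recovers the generating second-sphere dynamics — a
318 ps local rotational correlation time and a 5 ns water residence
time — exactly, because the profile is noiseless and the model
identifiable. The same workflow on the command line:

```sh
gdcoil synth nmrd --config model.yaml --seed 0 --out profile.csv
gdcoil fit-nmrd --profile profile.csv --config model.yaml --out fit.json
gdcoil fit-binding --mode competition --series titration.csv --out ka.json
```

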