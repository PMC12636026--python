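# Methods

## Relaxation model

The forward model describes the longitudinal relaxivity r₁(ν) of a
Gd(III) centre buried in a three-helix coiled-coil bundle with **zero
inner-sphere waters**. Two mechanisms contribute:

**Second sphere.** q^SS water molecules hydrogen-bonded near the metal
(default q^SS = 2 at r^SS = 3.6 Å Gd–H) relax via the
Solomon–Bloembergen–Morgan dipolar interaction. Their motion is
described model-free: slow global tumbling of the bundle (τ_RG) and
fast local rotation of the waters (τ_RL), coupled by an order parameter
S² ∈ [0, 1] (0 = independent motions, 1 = fully correlated). Effective
correlation rates add the water residence rate 1/τ_M^SS and the
electron-spin rates; the ω_I dipolar term pairs with 1/T₁e and the ω_S
term with 1/T₂e (the standard SBM convention — made explicit here
because different codes differ). The per-mM conversion uses the water
molarity 55.5 M, i.e. r₁^SS = (q^SS/55500)/(T₁m + τ_M^SS); the model is
therefore exactly linear in q^SS.

**Outer sphere.** Freely diffusing water contributes the Freed
translational term with closest approach a (default 4 Å) and relative
diffusion coefficient D (default 2.3 × 10⁻¹⁰ m² s⁻¹, the value the
underlying study fixed), τ_D = a²/D, and the dimensionless spectral
density J(z) = Re[(1 + z/4)/(1 + z + 4z²/9 + z³/9)] with
z = √(iωτ_D + τ_D/T_je). Dimensional analysis fixes the per-mM number
density at N_A per mol·m⁻³ (1 mM ≡ 1 mol·m⁻³); with this normalisation
the term reproduces familiar outer-sphere magnitudes (a few mM⁻¹s⁻¹
for D ≈ 2 × 10⁻⁹ m² s⁻¹).

**Electron spin.** Transient zero-field splitting with mean-square
amplitude Δ² and correlation time τ_v, S = 7/2, g = 2. The published
fits' Δ², τ_v and S² values were not available to this package, so the
defaults Δ² = 1.0 × 10¹⁹ s⁻², τ_v = 20 ps, S² = 0.5 are used. They are
plausible for Gd(III) in a slowly tumbling scaffold and serve the
self-consistent generate-then-fit tests; single-frequency *point*
predictions in the dispersive region (20–60 MHz) are sensitive to
Δ²·τ_v, so absolute relaxivities at a given field should only be
trusted after fitting these parameters to a measured profile.

Physical constants are CODATA-2018, fixed in `gdcoil.constants` for
bit-reproducibility. Temperature is metadata only (single-temperature
model at 298 K); no activation-energy dependence is modelled.

Two reference parameterizations ship with the package: the cross-linked
bundle (τ_RG = 7 ns, τ_RL = 318 ps, τ_M^SS = 5 ns) and the
non-cross-linked trimer (τ_RG = 5 ns, τ_RL = 184 ps, τ_M^SS = 3 ns).

## NMRD fitting

Weighted least squares (weights 1/σ² when point errors are given, unity
otherwise) over a user-declared free/fixed partition of
{τ_RL, τ_M^SS, S², Δ², τ_v, q^SS}. Numerical choices, all normative for
reproducibility:

- positive parameters are optimised on a log scale and S² on a logit
  scale, so box bounds are respected smoothly;
- trust-region-reflective least squares, ftol 10⁻¹⁰ on the relative
  residual change, evaluation budget 5000;
- multi-start (default 8 starts) from seeded log-uniform draws within
  bounds, because the objective is multi-modal in (Δ², τ_v); the
  first draws of the stream are shared for any start count, so more
  starts can only improve the returned minimum;
- a fit reports how many starts agree with the best residual within
  0.1 %, and a constant profile raises an identifiability warning
  rather than failing silently;
- uncertainties by residual-resampling bootstrap (fixed design grid,
  default 500 draws, percentile intervals).

The q^SS model scan refits with each candidate water count held fixed
and ranks by residual. Profile comparison interpolates linearly in
log-frequency onto the coarser grid over the overlapping range and
reports mean/max relative differences plus a reference-symmetry flag.

## Binding analysis

Speciation of one metal over two independent 1:1 ligands (peptide site,
competitor) is solved exactly per titration point by bracketed root
finding on the metal mass balance (strictly increasing in free M, so
[0, M_T] always brackets), followed by Newton polish; mass balances
hold to < 10⁻¹⁰ relative. The assembled trimer is treated as a single
Ln site, with per-site concentration bookkeeping, and ligand depletion
is always modelled — the regime of interest is far from free ≈ total.

The competition fit exploits that, for fixed log K_a, the signal model
baseline + s_P·[MP] + s_E·[ME] is linear in its coefficients: the fit
is a 1-D bounded scalar optimisation over log K_a with the signal
coefficients profiled out by linear least squares. Uncertainty comes
from the curvature of the RSS(log K_a) profile; a flat profile (e.g.
s_P = s_E with zero baseline, where the signal tracks total bound
metal) is flagged as an identifiability failure. Both nonzero and zero
bound-competitor emission are supported; the default has s_E > 0.

The conditional Tb–EGTA constant at pH 7.5 is a required input with a
documented default of log K' = 14.5, derived from the absolute
stability constant (log K = 17.7) corrected for EGTA protonation
(pKa 9.40 and 8.79 give log α_H ≈ 3.2 at pH 7.5). In self-consistent
generate-then-fit analyses this value cancels: the recovered peptide
constant is invariant across decades of the competitor constant.

The Hill fit (signal = baseline + A·Mⁿ/(K_dⁿ + Mⁿ)) is a separate code
path used for direct titrations; its n is never reused inside the
competition model, which assumes 1:1 binding.

## Kinetics, helicity, digest

- **Ratio index**: time for the (control-corrected, t=0-normalised)
  signal to fall to 80 % of its initial value; linear interpolation
  between bracketing samples (no interpolation rule is standard, so
  linear is the documented choice); censored at t_max when never
  crossed. When a buffer-control channel is present the signal is
  divided by it at matched times; otherwise raw normalisation is used.
- **Helicity**: fraction folded = (θ₂₂₂ − θ_coil)/(θ_helix − θ_coil)
  with θ_helix = −40000(1 − 2.5/n) and θ_coil = +640 deg·cm²·dmol⁻¹ as
  documented, configurable defaults; values outside [0, 1] are clipped
  and flagged.
- **Tryptic digest**: cleavage C-terminal to Lys/Arg, blocked before
  Pro and at isopeptide-cross-linked lysines (the modified side chain
  resists the protease). Terminal caps survive on terminal fragments;
  optional missed-cleavage enumeration (default 0). With the shipped
  sequences, cross-linking Lys15 joins the two binding-site heptads
  into the single uncleaved IAANEWK+DAAIEQK fragment.

## Hydration statistics

A trajectory is labelled coordinates with one centre atom; water
molecule identity is the shared atom label, and a molecule is in shell
when **any** of its selected hydrogens is (per-molecule counting). The
default second shell is [3.0, 4.5) Å, bracketing the ≈ 3.6 Å Gd–H_wat
peak. The RDF divides frame-averaged shell counts by exact
spherical-shell volumes times the mean target density of the analysis
region (the infinitesimal 4πr²dr form biases the innermost bins);
orthorhombic minimum-image distances are used when a box is present,
with r_max capped at half the shortest box length. Residence lifetimes
are maximal runs of consecutive in-shell frames × dt, with no grace
period for single-frame exits (the simplest defensible reading of
"residence"); runs touching either trajectory end are censored and
reported separately, and the survival curve uses uncensored lifetimes
only.

## Synthetic data

Each generator draws from one seeded `default_rng` stream in a
documented order and is bit-reproducible. They emulate:

- **NMRD**: the forward model on 30 log-spaced points over
  0.01–70 MHz (the measured span), with optional multiplicative or
  additive Gaussian noise recorded in the output metadata;
- **titrations**: exact speciation plus the linear signal model; the
  default design is 20 points, 3.3 μM peptide sites, metal delivered
  as the equimolar competitor complex;
- **decay**: first-order loss exp(−kt) with an optional flat control;
- **trajectories**: one fixed centre, ideal-gas bulk waters redrawn
  each frame, and tethered second-shell waters following a telegraph
  process with per-frame leave probability dt/τ_res (mean dwell
  τ_res) and re-entry probability set by the stationary in-shell
  fraction p_in. Three symmetric tethered waters emulate the
  cross-linked bundle's shell statistics (mean occupancy 1.5,
  empty-shell fraction 0.125).

What they do **not** emulate: temperature dependence, serum-matrix
effects, instrument drift or correlated noise, real force-field water
structure (bulk waters are point scatterers with no excluded volume,
and tethered waters sit at a fixed radius), or partial proteolysis
kinetics. Passing round-trip tests therefore demonstrates estimator
correctness and identifiability under the stated noise models — not
agreement with any particular measured dataset.

## Test-suite problem sizes

Simulation sizes were chosen to keep the full suite fast while leaving
comfortable statistical margins: 12 random models for noiseless
self-consistency, 100 replicates for the noisy-recovery study (its
RMSE threshold 0.30 was frozen from a pre-registered seeded run of the
same configuration), 20 replicates × 200 resamples for bootstrap
coverage, 200 replicates for the Hill-recovery envelope, 500 ns of
telegraph dynamics with 10 tethered waters for lifetime statistics,
and 10⁶ points for the ideal-gas RDF check.

## Known limitations

- Absolute point relaxivities depend on electron-spin parameters the
  package defaults cannot claim; fit them per dataset.
- The transient-ZFS electron model is the low-field-theory standard
  form; no static ZFS or higher-order effects.
- Transverse relaxivity (r₂), Curie-spin terms, inner-sphere terms and
  temperature series are out of scope.
- EGTA speciation is absorbed into a single conditional constant; pH
  is metadata.
- Lifetime statistics carry the usual censoring bias when dwell times
  approach the trajectory length.
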