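# Methods

This note documents the physical models, numerical choices and known
limitations behind `microkin`, in the order data flows through the package.

## Thermochemistry (RRHO)

Each species is treated as an ideal-gas rigid rotor with independent
harmonic oscillators. From an electronic energy E_elec (Hartree), harmonic
wavenumbers ν̃ᵢ (cm⁻¹, imaginary modes negative) and a geometry:

- **ZPE** = Σᵢ N_A h c ν̃ᵢ / 2 over real modes only.
- **Translation**: E = (3/2)RT; S from the Sackur–Tetrode equation at the
  standard-state pressure.
- **Rotation**: E = 0 (monoatomic), RT (linear) or (3/2)RT; S from the
  classical rotor partition function with the principal moments of inertia
  and a symmetry number σ (user metadata, default 1). Linearity is inferred
  from moment-of-inertia degeneracy (smallest moment < 10⁻⁶ amu Å²) unless
  the user sets it.
- **Vibration**: per mode with x = h c ν̃/(k_B T), E = RT·x/(eˣ−1)
  (thermal, ZPE kept separate), S = R[x/(eˣ−1) − ln(1−e^{−x})].
- **Electronic**: S = R ln(multiplicity); excited electronic states are
  ignored.
- **Assembly**: H = E_elec + ZPE + E_trans + E_rot + E_vib + RT (the
  ideal-gas pV term), G = H − T·S_total. Absolute H and G are reported in
  kcal/mol (conversion 627.5094740631 kcal·mol⁻¹ per Hartree, pinned with
  the full CODATA-2018 constant table in `constants.py`).

A transition state carries exactly one imaginary mode, which is excluded
from every vibrational sum; two or more imaginary modes fail validation
(relaxable for partially optimized inputs).

**Low-frequency entropy.** Harmonic entropy diverges as ν̃ → 0, so three
treatments are exposed, applied to entropy only: `none` (default), `floor`
(modes below ν₀ raised to ν₀), and `qrrho` (Grimme-type interpolation
w·S_harm + (1−w)·S_free-rotor with w = 1/(1+(ν₀/ν̃)⁴), free-rotor moment
damped by B_av = 10⁻⁴⁴ kg m²; ν₀ default 100 cm⁻¹). Plain RRHO is the
default because it is the convention quantum-chemistry codes use in their
own printed thermochemistry blocks, which keeps our G directly comparable
to theirs; the quasi-RRHO options are for users who prefer damped soft-mode
entropies.

**Masses** are most-abundant-isotope masses from a pinned, versioned table
(`masses.py`); they enter the translational and rotational partition
functions only. **Standard states**: `gas_1atm` (default), `gas_1bar`, and
`solution_1M` (translational entropy evaluated at the pressure of a 1 mol/L
ideal gas, P = c°RT).

## Energy referencing

Relative energies are differences against a user-declared linear
combination of reference species. The combination must balance the
species' elemental composition exactly (coefficients handled as rationals,
`limit_denominator(10⁶)`); any imbalance raises an error that lists the
offending elements — no cross-composition number is ever returned.
`solve_reference_coefficients` inverts the element-count matrix exactly
(sympy, rational arithmetic) when a unique non-negative solution exists,
as a convenience for building assignments.

Merging intermediates sums electronic energies, compositions and every
additive thermochemical component, which models fragments at infinite
separation; the part names are kept as provenance. A state merged from the
reference species therefore sits at exactly 0 kcal/mol relative energy.

## Rate constants

Eyring's equation k = κ(k_BT/h)e^{−ΔG‡/RT} with κ = 1 by default
(no tunneling; settable per step). For a step of molecularity m > 1 the
pressure-standard-state ΔG‡ is converted to concentration units with
(RT/P°)^{m−1} in L/mol (or (1/c°)^{m−1} = 1 for the 1 M solution standard
state). Unimolecular rates are standard-state invariant. ΔG‡ is computed
as G(TS) − ΣG(reactants) (and G(TS) − ΣG(products) for the reverse), so
detailed balance k_f/k_r = e^{−ΔG_rxn/RT} holds to rounding. Negative
computed barriers — common when RRHO free energies put a TS below loosely
bound reactants — produce a warning, not an error, and the rate is computed
as written.

## Microkinetics

Mass-action ODEs dC/dt = ν·r(c) are integrated with SciPy's BDF and an
analytic Jacobian; defaults rtol = 10⁻⁸, atol = 10⁻¹² because TST rate
constants within one network routinely span more than ten orders of
magnitude. The model is a closed isothermal batch reactor; no flow terms.

- **Equilibrium detection**: a terminal event when ‖dC/dt‖∞ drops below
  eq_tol (default 10⁻¹²·max(c₀, 1) s⁻¹); if the integrator reaches t_end
  with the norm already below the threshold the result is likewise flagged.
- **Output grid**: log-spaced from t_end·10⁻⁹ to t_end (plus t = 0) so both
  the fast transient and the equilibrium plateau are resolved; callers may
  pass an explicit grid.
- **Conservation**: conserved moieties are the rational left null space of
  ν, computed by exact elimination (sympy); every result reports the
  maximum relative drift of each moiety total (observed ≲ 10⁻¹⁰, bound
  10⁻⁶ asserted in tests).
- **Negative undershoots** beyond −atol are clipped with a warning.

**Selectivity** is c_target/(c_target + Σ c_competitors) at the equilibrium
time; evaluating before equilibrium requires `force=True` and warns. For
parallel irreversible first-order channels this equals k₁/(k₁+k₂) at any
time, which the competing-channel fixture exploits.

**Initial-rate probes.** Apparent activation energies and reaction orders
need an operational "rate". We use a finite difference of the probe
species over the window [0, t_w] where t_w is the time at which the
limiting reactant (lowest-c₀ species being consumed, or user-specified)
reaches 5 % conversion by the initial slope estimate. Because the window
tracks a fixed conversion fraction, the small finite-window bias is a
constant factor across temperatures and concentrations and cancels in the
log-space slopes. Ea = −R·slope of ln r vs 1/T; order = slope of ln r vs
ln c₀; both by ordinary least squares with R² reported. For single-step
Eyring kinetics the apparent Ea is ΔH‡ + RT̄ (the prefactor's T-linearity
contributes RT̄), which the tests confirm to 2 %.

## Synthetic inputs

The fixtures module generates every test input deterministically from a
seed: random species (2–8 atoms on a perturbed cubic lattice, frequencies
50–3500 cm⁻¹, energies −250…−50 Ha, exactly one negative mode for TS
templates), the pinned ORCA-like output text for them, a first-order decay
network with its exponential closed form, a two-channel competition
parameterized by ΔΔG‡ with its Boltzmann selectivity closed form, and
noiseless/log-normal-noisy Arrhenius rate tables. Geometries are plausible
but not optimized structures: they exercise parsing, composition algebra
and the thermochemistry plumbing, while numerical correctness is always
asserted against closed forms or exact algebra, not against real
molecules. Passing tests therefore demonstrate the statistical-mechanics
and numerics are right, not that any particular chemistry is.

## Problem sizes

The test suite and the acceptance script use deliberately small problems —
networks of ≤ 6 species, ≤ 1000 parser round trips, 4-point fits — chosen
so the whole pipeline (including the stiff integrations) completes in
seconds while still covering every code path and closed form.

## Known limitations

- No tunneling (κ is a user constant), variational TST, or non-adiabatic
  effects.
- No anharmonicity, hindered rotors, or conformational averaging; the
  RRHO entropy of soft modes is only as good as the chosen treatment.
- Gas-phase thermochemistry only; the solution standard state rescales
  translational entropy but adds no solvation free energy.
- The mechanism JSON schema is this package's own (version 1); it is not a
  byte-compatible clone of any other tool's format.
- Reaction-coordinate step extraction in the `rates` CLI assumes network
  entries are ordered along the coordinate with each TS flanked by minima.
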