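"""Ideal-gas rigid-rotor harmonic-oscillator (RRHO) thermochemistry.

Given an electronic energy, a geometry and a set of harmonic wavenumbers,
this module assembles the standard statistical-mechanics corrections:

* zero-point vibrational energy, ZPE = Σ N_A h c ν̃ᵢ / 2 over real modes;
* translational entropy from the Sackur–Tetrode equation;
* rotational entropy from the principal moments of inertia (classical
  rigid-rotor partition function with a symmetry number σ);
* vibrational energy and entropy per harmonic mode with
  x = h c ν̃ / (k_B T):  E = R T x/(eˣ−1),
  S = R [x/(eˣ−1) − ln(1−e^{−x})];
* electronic entropy R ln(2S+1) from the spin multiplicity.

Enthalpy is H = E_elec + ZPE + E_trans + E_rot + E_vib + RT (ideal-gas pV
term) and G = H − T·S_total.  Imaginary modes (negative wavenumbers) are
excluded from every vibrational sum, which makes a transition state with a
single imaginary frequency a first-class input.

Low-frequency entropy treatments
--------------------------------
Harmonic entropies of very soft modes diverge logarithmically as ν̃ → 0.
Three treatments are offered (entropy only; energies stay harmonic):

* ``none`` — plain RRHO (the default, and the convention quantum-chemistry
  codes print in their own thermochemistry blocks);
* ``floor`` — modes below a cutoff ν₀ are raised to ν₀;
* ``qrrho`` — Grimme-style quasi-RRHO: each mode's entropy is the damped
  interpolation w·S_harm + (1−w)·S_free_rotor with
  w(ν̃) = 1 / (1 + (ν₀/ν̃)⁴) and the free-rotor entropy evaluated for an
  effective moment μ' = μB/(μ+B), μ = h/(8π²cν̃), B = 10⁻⁴⁴ kg m².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import ATM, CONSTANTS, R, R_CAL, HARTREE_TO_KCAL, KCAL_TO_J
from .errors import DomainError, GeometryError, ValidationError
from .masses import atomic_mass
from .qc_io import Geometry, RawQCRecord

__all__ = [
    "ThermoConditions",
    "ThermoResult",
    "zero_point_energy",
    "translational_entropy",
    "rotational_entropy",
    "vibrational_thermo",
    "electronic_entropy",
    "thermochemistry",
    "principal_moments",
    "is_linear",
]

LowFreqTreatment = Literal["none", "floor", "qrrho"]
StandardState = Literal["gas_1atm", "gas_1bar", "solution_1M"]

_QRRHO_B_AV = 1.0e-44  # kg m^2, Grimme's average moment for the damped rotor


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature, pressure and model switches for one evaluation."""

    T: float = 298.15                 # K
    P: float = ATM                    # Pa
    frequency_scale: float = 1.0
    low_freq_treatment: LowFreqTreatment = "none"
    low_freq_cutoff: float = 100.0    # cm^-1, ν₀ for floor/qrrho
    standard_state: StandardState = "gas_1atm"

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise DomainError(f"T = {self.T} K must be positive")
        if self.P <= 0:
            raise DomainError(f"P = {self.P} Pa must be positive")
        if self.frequency_scale <= 0:
            raise DomainError("frequency_scale must be positive")
        if self.low_freq_cutoff < 0:
            raise DomainError("low_freq_cutoff must be >= 0")

    @property
    def effective_pressure(self) -> float:
        """Pressure entering S_trans after the standard-state choice."""
        if self.standard_state == "gas_1atm":
            return 101325.0
        if self.standard_state == "gas_1bar":
            return 1.0e5
        # 1 mol/L ideal gas: P = c R T with c = 1000 mol/m^3
        return 1000.0 * R * self.T


@dataclass
class ThermoResult:
    """All thermochemical components at one (T, P).

    Energies in kcal/mol (absolute, electronic energy included in ``enthalpy``
    and ``gibbs``); entropies in cal/(mol K).
    """

    zpe: float
    e_thermal_trans: float
    e_thermal_rot: float
    e_thermal_vib: float
    s_trans: float
    s_rot: float
    s_vib: float
    s_elec: float
    enthalpy: float
    gibbs: float
    T: float

    @property
    def entropy_total(self) -> float:
        return self.s_trans + self.s_rot + self.s_vib + self.s_elec

    @property
    def thermal_correction(self) -> float:
        """G − E_elec in kcal/mol (useful for reporting)."""
        rt = R * self.T / KCAL_TO_J
        return (
            self.zpe
            + self.e_thermal_trans
            + self.e_thermal_rot
            + self.e_thermal_vib
            + rt
            - self.T * self.entropy_total / 1000.0
        )


def _real_modes(frequencies: Iterable[float], scale: float = 1.0) -> np.ndarray:
    nu = np.asarray(list(frequencies), dtype=float)
    return scale * nu[nu > 0]


def zero_point_energy(frequencies: Sequence[float], scale: float = 1.0) -> float:
    """ZPE in kcal/mol; imaginary (negative) modes are excluded."""
    nu = _real_modes(frequencies, scale)
    joules_per_mol = CONSTANTS.NA * CONSTANTS.h * CONSTANTS.c * nu.sum() / 2.0
    return joules_per_mol / KCAL_TO_J


def translational_entropy(mass: float, T: float, P: float) -> float:
    """Sackur–Tetrode entropy in cal/(mol K) for an ideal gas of ``mass`` amu."""
    if mass <= 0:
        raise DomainError(f"mass = {mass} amu must be positive")
    if T <= 0 or P <= 0:
        raise DomainError("T and P must be positive")
    m = mass * CONSTANTS.amu
    lam = (2.0 * math.pi * m * CONSTANTS.kB * T / CONSTANTS.h**2) ** 1.5
    q = lam * CONSTANTS.kB * T / P
    return R_CAL * (math.log(q) + 2.5)


def principal_moments(geometry: Geometry) -> np.ndarray:
    """Principal moments of inertia in kg m², ascending."""
    masses = np.array([atomic_mass(el) for el in geometry.elements])
    coords = np.asarray(geometry.coordinates, dtype=float) * 1.0e-10  # Å → m
    masses_kg = masses * CONSTANTS.amu
    com = (masses_kg[:, None] * coords).sum(axis=0) / masses_kg.sum()
    r = coords - com
    inertia = np.zeros((3, 3))
    for mi, ri in zip(masses_kg, r):
        inertia += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    return np.sort(np.linalg.eigvalsh(inertia))


_LINEAR_TOL_AMU_A2 = 1.0e-6  # amu Å², degeneracy test for linearity


def is_linear(geometry: Geometry) -> bool:
    """True when the smallest principal moment vanishes (within tolerance)."""
    if geometry.n_atoms <= 1:
        return True
    moments = principal_moments(geometry) / (CONSTANTS.amu * 1.0e-20)  # amu Å²
    return moments[0] < _LINEAR_TOL_AMU_A2


def rotational_entropy(
    geometry: Geometry, sigma: int, T: float, linear: bool | None = None
) -> float:
    """Classical rigid-rotor entropy in cal/(mol K).

    Monoatomics return 0.  ``linear=None`` infers linearity from the
    moment-of-inertia degeneracy.
    """
    if sigma < 1:
        raise DomainError(f"symmetry number {sigma} < 1")
    if T <= 0:
        raise DomainError("T must be positive")
    if geometry.n_atoms == 0:
        raise GeometryError("empty geometry")
    if geometry.n_atoms == 1:
        return 0.0
    moments = principal_moments(geometry)
    if linear is None:
        linear = is_linear(geometry)
    hbar2 = (CONSTANTS.h / (2.0 * math.pi)) ** 2
    if linear:
        I = moments[-1]
        if I <= 0:
            raise GeometryError("all atoms coincide: no rotational axis")
        theta = hbar2 / (2.0 * I * CONSTANTS.kB)
        q = T / (sigma * theta)
        return R_CAL * (math.log(q) + 1.0)
    if np.any(moments <= 0):
        raise GeometryError("degenerate (collinear/coincident) polyatomic geometry")
    thetas = hbar2 / (2.0 * moments * CONSTANTS.kB)
    q = math.sqrt(math.pi) / sigma * math.sqrt(T**3 / float(np.prod(thetas)))
    return R_CAL * (math.log(q) + 1.5)


def _harmonic_mode_entropy(nu: float, T: float) -> float:
    """Harmonic-oscillator entropy of a single mode, in R units."""
    x = CONSTANTS.h * CONSTANTS.c * nu / (CONSTANTS.kB * T)
    return x / math.expm1(x) - math.log1p(-math.exp(-x))

def _free_rotor_mode_entropy(nu: float, T: float) -> float:
    """Grimme free-rotor entropy of a soft mode, in R units."""
    mu = CONSTANTS.h / (8.0 * math.pi**2 * CONSTANTS.c * nu)
    mu_eff = mu * _QRRHO_B_AV / (mu + _QRRHO_B_AV)
    q = math.sqrt(
        8.0 * math.pi**3 * mu_eff * CONSTANTS.kB * T / CONSTANTS.h**2
    )
    return 0.5 + math.log(q)


def vibrational_thermo(
    frequencies: Sequence[float],
    T: float,
    treatment: LowFreqTreatment = "none",
    cutoff: float = 100.0,
    scale: float = 1.0,
) -> tuple[float, float]:
    """Thermal vibrational energy (kcal/mol, excluding ZPE) and entropy
    (cal/(mol K)) summed over real modes."""
    if T <= 0:
        raise DomainError("T must be positive")
    nu_all = _real_modes(frequencies, scale)
    e_r = 0.0  # in R*T units
    s_r = 0.0  # in R units
    for nu in nu_all:
        x = CONSTANTS.h * CONSTANTS.c * nu / (CONSTANTS.kB * T)
        e_r += x / math.expm1(x)
        if treatment == "none":
            s_r += _harmonic_mode_entropy(nu, T)
        elif treatment == "floor":
            s_r += _harmonic_mode_entropy(max(nu, cutoff), T)
        elif treatment == "qrrho":
            w = 1.0 / (1.0 + (cutoff / nu) ** 4) if cutoff > 0 else 1.0
            s_r += w * _harmonic_mode_entropy(nu, T) + (1.0 - w) * _free_rotor_mode_entropy(nu, T)
        else:
            raise DomainError(f"unknown low-frequency treatment {treatment!r}")
    e_vib = R * T * e_r / KCAL_TO_J
    s_vib = R_CAL * s_r
    return e_vib, s_vib


def electronic_entropy(multiplicity: int) -> float:
    """R ln(multiplicity) in cal/(mol K)."""
    if multiplicity < 1:
        raise DomainError(f"multiplicity {multiplicity} < 1")
    return R_CAL * math.log(multiplicity)


def thermochemistry(
    record: RawQCRecord,
    conditions: ThermoConditions = ThermoConditions(),
    *,
    symmetry_number: int = 1,
    linear: bool | None = None,
    validate: bool = True,
) -> ThermoResult:
    """Assemble H, S and G for one species under the RRHO model.

    A transition state (exactly one imaginary mode) is accepted; the
    imaginary mode is excluded from every sum.  Two or more imaginary modes
    raise :class:`ValidationError` unless ``validate=False``.
    """
    n_imag = sum(1 for f in record.frequencies if f < 0)
    if validate and n_imag > 1:
        raise ValidationError(
            f"{record.source_path or 'record'}: {n_imag} imaginary modes "
            "(a minimum has 0, a transition state exactly 1)"
        )
    if record.geometry is None:
        raise DomainError("thermochemistry requires a geometry (for mass/inertia)")

    T = conditions.T
    rt_kcal = R * T / KCAL_TO_J

    mass = sum(atomic_mass(el) for el in record.geometry.elements)
    monoatomic = record.geometry.n_atoms == 1
    lin = linear if linear is not None else is_linear(record.geometry)

    zpe = zero_point_energy(record.frequencies, conditions.frequency_scale)
    e_trans = 1.5 * rt_kcal
    e_rot = 0.0 if monoatomic else (rt_kcal if lin else 1.5 * rt_kcal)
    e_vib, s_vib = vibrational_thermo(
        record.frequencies,
        T,
        conditions.low_freq_treatment,
        conditions.low_freq_cutoff,
        conditions.frequency_scale,
    )
    s_trans = translational_entropy(mass, T, conditions.effective_pressure)
    s_rot = (
        0.0
        if monoatomic
        else rotational_entropy(record.geometry, symmetry_number, T, lin)
    )
    s_elec = electronic_entropy(record.multiplicity)

    e_elec_kcal = record.electronic_energy * HARTREE_TO_KCAL
    enthalpy = e_elec_kcal + zpe + e_trans + e_rot + e_vib + rt_kcal
    entropy_total = s_trans + s_rot + s_vib + s_elec
    gibbs = enthalpy - T * entropy_total / 1000.0

    return ThermoResult(
        zpe=zpe,
        e_thermal_trans=e_trans,
        e_thermal_rot=e_rot,
        e_thermal_vib=e_vib,
        s_trans=s_trans,
        s_rot=s_rot,
        s_vib=s_vib,
        s_elec=s_elec,
        enthalpy=enthalpy,
        gibbs=gibbs,
        T=T,
    )
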