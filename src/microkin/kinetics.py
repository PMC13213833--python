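"""Transition-state-theory rate constants.

The Eyring equation relates an elementary step's rate constant to its Gibbs
energy of activation:

    k = κ · (k_B T / h) · exp(−ΔG‡ / RT)

with κ the transmission coefficient (default 1, no tunneling).  ΔG‡ from an
ideal-gas calculation refers to the pressure standard state, so a step of
molecularity m > 1 is converted to concentration units by (RT/P°)^{m−1}
(gas) or (1/C°)^{m−1} with C° = 1 mol/L (solution); unimolecular rates are
standard-state independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

from .constants import ATM, BAR, CONSTANTS, R, R_KCAL
from .errors import CompositionError, DomainError, StateError
from .network import SpeciesRecord

__all__ = [
    "ElementaryStep",
    "RateConstant",
    "eyring_rate",
    "gibbs_from_rate",
    "step_rates",
    "equilibrium_constant",
]

StandardState = Literal["gas_1atm", "gas_1bar", "solution_1M"]


@dataclass(frozen=True)
class RateConstant:
    """A TST rate constant: s⁻¹ (unimolecular) or M^{1−m} s⁻¹ otherwise."""

    value: float
    molecularity: int
    T: float

    @property
    def units(self) -> str:
        if self.molecularity == 1:
            return "s^-1"
        return f"M^-{self.molecularity - 1} s^-1"


def _standard_state_factor(
    molecularity: int, T: float, standard_state: StandardState
) -> float:
    """(RT/P°)^{m−1} in (L/mol)^{m−1} for gas; (1/C°)^{m−1} for solution."""
    if molecularity == 1:
        return 1.0
    if standard_state == "solution_1M":
        return 1.0  # C° = 1 mol/L
    p0 = ATM if standard_state == "gas_1atm" else BAR
    molar_volume_L = R * T / p0 * 1000.0  # m³/mol → L/mol
    return molar_volume_L ** (molecularity - 1)


def eyring_rate(
    dg_act: float,
    T: float,
    kappa: float = 1.0,
    molecularity: int = 1,
    standard_state: StandardState = "gas_1atm",
) -> RateConstant:
    """Eyring rate constant for an activation free energy in kcal/mol."""
    if T <= 0:
        raise DomainError(f"T = {T} K must be positive")
    if kappa <= 0:
        raise DomainError(f"kappa = {kappa} must be positive")
    if molecularity < 1:
        raise DomainError(f"molecularity {molecularity} < 1")
    k = kappa * CONSTANTS.kB * T / CONSTANTS.h * math.exp(-dg_act / (R_KCAL * T))
    k *= _standard_state_factor(molecularity, T, standard_state)
    return RateConstant(value=k, molecularity=molecularity, T=T)


def gibbs_from_rate(
    k: float | RateConstant,
    T: float,
    kappa: float = 1.0,
    molecularity: int = 1,
    standard_state: StandardState = "gas_1atm",
) -> float:
    """ΔG‡ in kcal/mol from a rate constant; exact inverse of :func:`eyring_rate`."""
    value = k.value if isinstance(k, RateConstant) else float(k)
    if isinstance(k, RateConstant):
        molecularity = k.molecularity
        T = k.T
    if value <= 0:
        raise DomainError("rate constant must be positive")
    if T <= 0 or kappa <= 0:
        raise DomainError("T and kappa must be positive")
    value /= _standard_state_factor(molecularity, T, standard_state)
    return -R_KCAL * T * math.log(value * CONSTANTS.h / (kappa * CONSTANTS.kB * T))


def equilibrium_constant(dg_rxn: float, T: float) -> float:
    """exp(−ΔG_rxn/RT) for ΔG in kcal/mol."""
    if T <= 0:
        raise DomainError("T must be positive")
    return math.exp(-dg_rxn / (R_KCAL * T))


@dataclass
class ElementaryStep:
    """A reversible elementary step with optional transition state.

    ``reactants``/``products`` map species names to stoichiometric counts.
    Barriers are in kcal/mol at ``T``; either may be filled in later by
    :func:`step_rates`.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    ts: str | None = None
    dg_forward: float | None = None
    dg_reverse: float | None = None
    kappa: float = 1.0
    T: float = 298.15
    label: str = ""

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise DomainError("a step needs at least one reactant and one product")
        if self.kappa <= 0:
            raise DomainError("kappa must be positive")
        if (
            self.dg_forward is not None
            and self.dg_reverse is not None
        ):
            # ΔG‡_f − ΔG‡_r must equal ΔG_rxn by construction; nothing to
            # check without thermo, but both barriers must be finite.
            if not (math.isfinite(self.dg_forward) and math.isfinite(self.dg_reverse)):
                raise DomainError("barriers must be finite")

    @property
    def molecularity_forward(self) -> int:
        return sum(self.reactants.values())

    @property
    def molecularity_reverse(self) -> int:
        return sum(self.products.values())

    @property
    def dg_reaction(self) -> float:
        if self.dg_forward is None or self.dg_reverse is None:
            raise StateError("barriers not set")
        return self.dg_forward - self.dg_reverse


def _side_gibbs(
    side: Mapping[str, int], species: Mapping[str, SpeciesRecord], what: str
) -> float:
    total = 0.0
    for name, count in side.items():
        rec = species.get(name)
        if rec is None or rec.thermo is None:
            raise StateError(f"{what}: no thermochemistry for species {name!r}")
        total += count * rec.thermo.gibbs
    return total


def _check_step_balance(
    step: ElementaryStep, species: Mapping[str, SpeciesRecord]
) -> None:
    def side_comp(side: Mapping[str, int]):
        comp: dict[str, int] = {}
        for name, count in side.items():
            rec = species.get(name)
            if rec is None:
                raise StateError(f"unknown species {name!r}")
            for el, n in rec.composition.items():
                comp[el] = comp.get(el, 0) + count * n
        return comp

    lhs, rhs = side_comp(step.reactants), side_comp(step.products)
    # Records without geometry/composition cannot be checked; skip silently.
    if lhs and rhs and lhs != rhs:
        raise CompositionError(
            f"step {step.label or step.reactants}: reactants {lhs} vs products {rhs}"
        )


def step_rates(
    step: ElementaryStep,
    species: Mapping[str, SpeciesRecord],
    standard_state: StandardState = "gas_1atm",
) -> tuple[RateConstant, RateConstant]:
    """Forward and reverse Eyring rate constants for a step.

    ΔG‡_f = G(TS) − ΣG(reactants), ΔG‡_r = G(TS) − ΣG(products) from the
    species' thermochemistry at the step temperature.  Negative barriers are
    allowed (warned about): within TST they simply produce k > k_B T/h.
    """
    if step.ts is None:
        if step.dg_forward is None or step.dg_reverse is None:
            raise StateError("step has neither a TS species nor explicit barriers")
        dg_f, dg_r = step.dg_forward, step.dg_reverse
    else:
        ts = species.get(step.ts)
        if ts is None or ts.thermo is None:
            raise StateError(f"no thermochemistry for TS {step.ts!r}")
        _check_step_balance(step, species)
        g_ts = ts.thermo.gibbs
        dg_f = g_ts - _side_gibbs(step.reactants, species, "forward")
        dg_r = g_ts - _side_gibbs(step.products, species, "reverse")
        step.dg_forward, step.dg_reverse = dg_f, dg_r
    if dg_f < 0 or dg_r < 0:
        warnings.warn(
            f"step {step.label or step.ts}: negative activation free energy "
            f"(ΔG‡_f = {dg_f:.3f}, ΔG‡_r = {dg_r:.3f} kcal/mol); "
            "TST rates computed anyway",
            stacklevel=2,
        )
    k_f = eyring_rate(dg_f, step.T, step.kappa, step.molecularity_forward, standard_state)
    k_r = eyring_rate(dg_r, step.T, step.kappa, step.molecularity_reverse, standard_state)
    return k_f, k_r
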