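"""Species and mechanism data model: composition algebra and relative energies.

A *reference assignment* maps a species to a linear combination of reference
calculations with non-negative coefficients; the combination must balance the
species' elemental composition exactly.  Relative energies (electronic, G or
H) are then differences against that combination — the same convention a
spreadsheet of reaction intermediates uses, which makes activation and
reaction energies simple differences of relative energies whenever two
states share a composition or a common reference.

Merged intermediates model infinitely separated fragments: their electronic
energies, thermal corrections and compositions add.  Provenance (the list of
part names) is kept for reporting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Literal, Mapping, Sequence

import sympy

from .constants import HARTREE_TO_KCAL
from .errors import CompositionError, DomainError, StateError, ValidationError
from .qc_io import Geometry
from .thermo import ThermoResult

__all__ = [
    "SpeciesRecord",
    "Mechanism",
    "ReferenceAssignment",
    "EnergyProfile",
    "composition",
    "merge_intermediates",
    "relative_energy",
    "activation_energy",
    "reaction_energy",
    "build_profile",
    "solve_reference_coefficients",
]

Role = Literal["minimum", "transition_state", "reference"]
EnergyProperty = Literal["electronic", "gibbs", "enthalpy"]

#: species name → [(reference name, coefficient ≥ 0)]
ReferenceAssignment = Mapping[str, Sequence[tuple[str, float]]]


def composition(geometry: Geometry) -> dict[str, int]:
    """Element → count map of a geometry (order-independent)."""
    return dict(Counter(geometry.elements))


@dataclass
class SpeciesRecord:
    """One row of a mechanism: a quantum-chemistry result with metadata."""

    name: str
    role: Role = "minimum"
    electronic_energy: float | None = None    # Hartree
    geometry: Geometry | None = None
    frequencies: list[float] = field(default_factory=list)
    multiplicity: int = 1
    symmetry_number: int = 1
    linear: bool | None = None
    composition_override: dict[str, int] | None = None
    thermo: ThermoResult | None = None
    source: str | None = None
    parts: list[str] = field(default_factory=list)  # provenance of merges

    @property
    def composition(self) -> dict[str, int]:
        if self.composition_override is not None:
            return dict(self.composition_override)
        if self.geometry is not None:
            return composition(self.geometry)
        return {}

    @property
    def n_imaginary(self) -> int:
        return sum(1 for f in self.frequencies if f < 0)

    def validate(self) -> None:
        if self.role == "transition_state" and self.frequencies:
            if self.n_imaginary != 1:
                raise ValidationError(
                    f"{self.name}: transition state has {self.n_imaginary} "
                    "imaginary modes, expected exactly 1"
                )
        elif self.role != "transition_state" and self.n_imaginary > 0:
            raise ValidationError(
                f"{self.name}: {self.role} has {self.n_imaginary} imaginary modes"
            )


@dataclass
class Mechanism:
    """Named networks of species plus reference assignments."""

    networks: dict[str, list[SpeciesRecord]]
    references: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    temperature: float = 298.15
    pressure: float = 101325.0

    def species(self, name: str) -> SpeciesRecord:
        for records in self.networks.values():
            for rec in records:
                if rec.name == name:
                    return rec
        raise KeyError(name)

    def all_species(self) -> list[SpeciesRecord]:
        return [rec for records in self.networks.values() for rec in records]


def _scaled_composition(
    refs: Sequence[tuple[SpeciesRecord, float]]
) -> dict[str, Fraction]:
    total: dict[str, Fraction] = {}
    for rec, coeff in refs:
        frac = Fraction(coeff).limit_denominator(10**6)
        for el, n in rec.composition.items():
            total[el] = total.get(el, Fraction(0)) + frac * n
    return {el: v for el, v in total.items() if v != 0}


def _check_balance(species: SpeciesRecord, refs: Sequence[tuple[SpeciesRecord, float]]) -> None:
    want = {el: Fraction(n) for el, n in species.composition.items()}
    have = _scaled_composition(refs)
    if want != have:
        imbalance = {
            el: float(want.get(el, Fraction(0)) - have.get(el, Fraction(0)))
            for el in set(want) | set(have)
            if want.get(el, Fraction(0)) != have.get(el, Fraction(0))
        }
        raise CompositionError(
            f"{species.name}: reference combination does not balance "
            f"composition; element imbalance (species − references): {imbalance}"
        )


def _value(species: SpeciesRecord, prop: EnergyProperty) -> float:
    """Energy of a species in kcal/mol for the requested property."""
    if prop == "electronic":
        if species.electronic_energy is None:
            raise StateError(f"{species.name}: no electronic energy")
        return species.electronic_energy * HARTREE_TO_KCAL
    if species.thermo is None:
        raise StateError(f"{species.name}: no thermochemistry for {prop!r}")
    return species.thermo.gibbs if prop == "gibbs" else species.thermo.enthalpy


def merge_intermediates(
    parts: Sequence[SpeciesRecord], name: str
) -> SpeciesRecord:
    """Sum separate fragments into one pseudo-species (role ``minimum``).

    Electronic energies, compositions, and — when every part carries thermo —
    ZPE/H/S/G all add, which models the fragments at infinite separation.
    """
    if not parts:
        raise DomainError("merge_intermediates: empty part list")
    if any(p.electronic_energy is None for p in parts):
        raise StateError("merge_intermediates: every part needs an energy")
    comp: Counter = Counter()
    for p in parts:
        comp.update(p.composition)
    thermo = None
    if all(p.thermo is not None for p in parts):
        t0 = parts[0].thermo
        if any(abs(p.thermo.T - t0.T) > 1e-9 for p in parts):
            raise StateError("merge_intermediates: parts evaluated at different T")
        thermo = ThermoResult(
            zpe=sum(p.thermo.zpe for p in parts),
            e_thermal_trans=sum(p.thermo.e_thermal_trans for p in parts),
            e_thermal_rot=sum(p.thermo.e_thermal_rot for p in parts),
            e_thermal_vib=sum(p.thermo.e_thermal_vib for p in parts),
            s_trans=sum(p.thermo.s_trans for p in parts),
            s_rot=sum(p.thermo.s_rot for p in parts),
            s_vib=sum(p.thermo.s_vib for p in parts),
            s_elec=sum(p.thermo.s_elec for p in parts),
            enthalpy=sum(p.thermo.enthalpy for p in parts),
            gibbs=sum(p.thermo.gibbs for p in parts),
            T=t0.T,
        )
    return SpeciesRecord(
        name=name,
        role="minimum",
        electronic_energy=sum(p.electronic_energy for p in parts),
        composition_override=dict(comp),
        multiplicity=1,
        thermo=thermo,
        parts=[p.name for p in parts],
    )


def _resolve_refs(
    species: SpeciesRecord,
    refs: ReferenceAssignment,
    lookup: Mapping[str, SpeciesRecord],
) -> list[tuple[SpeciesRecord, float]]:
    assignment = refs.get(species.name)
    if assignment is None:
        raise CompositionError(f"{species.name}: no reference assignment")
    return [(lookup[rname], coeff) for rname, coeff in assignment]


def relative_energy(
    species: SpeciesRecord,
    refs: ReferenceAssignment,
    lookup: Mapping[str, SpeciesRecord],
    prop: EnergyProperty = "electronic",
) -> float:
    """Energy of ``species`` minus its reference combination, kcal/mol."""
    resolved = _resolve_refs(species, refs, lookup)
    _check_balance(species, resolved)
    ref_value = sum(coeff * _value(rec, prop) for rec, coeff in resolved)
    return _value(species, prop) - ref_value


def _comparable(a: SpeciesRecord, b: SpeciesRecord, refs: ReferenceAssignment) -> bool:
    if a.composition and a.composition == b.composition:
        return True
    ra, rb = refs.get(a.name), refs.get(b.name)
    return ra is not None and rb is not None


def reaction_energy(
    a: SpeciesRecord,
    b: SpeciesRecord,
    refs: ReferenceAssignment,
    lookup: Mapping[str, SpeciesRecord],
    prop: EnergyProperty = "electronic",
) -> float:
    """E(b) − E(a) in kcal/mol; states must share composition or references."""
    if not _comparable(a, b, refs):
        raise CompositionError(
            f"states {a.name!r} and {b.name!r} have different compositions "
            f"({a.composition} vs {b.composition}) and no common reference"
        )
    if a.composition and a.composition == b.composition and (
        a.name not in refs or b.name not in refs
    ):
        return _value(b, prop) - _value(a, prop)
    return relative_energy(b, refs, lookup, prop) - relative_energy(a, refs, lookup, prop)


def activation_energy(
    ts: SpeciesRecord,
    from_state: SpeciesRecord,
    refs: ReferenceAssignment,
    lookup: Mapping[str, SpeciesRecord],
    prop: EnergyProperty = "electronic",
) -> float:
    """Barrier E(ts) − E(from_state) in kcal/mol."""
    return reaction_energy(from_state, ts, refs, lookup, prop)


@dataclass
class EnergyProfile:
    """An ordered list of states with relative energies along a coordinate."""

    states: list[tuple[str, float, Role]]
    prop: EnergyProperty
    T: float

    @property
    def labels(self) -> list[str]:
        return [s[0] for s in self.states]

    @property
    def values(self) -> list[float]:
        return [s[1] for s in self.states]


def build_profile(
    states: Sequence[SpeciesRecord],
    refs: ReferenceAssignment,
    lookup: Mapping[str, SpeciesRecord],
    prop: EnergyProperty = "electronic",
    T: float = 298.15,
) -> EnergyProfile:
    """Relative-energy profile over an ordered list of mutually comparable states."""
    if not states:
        raise DomainError("build_profile: empty state list")
    labels = [s.name for s in states]
    if len(set(labels)) != len(labels):
        raise DomainError("build_profile: duplicate state labels")
    points = [
        (s.name, relative_energy(s, refs, lookup, prop), s.role) for s in states
    ]
    return EnergyProfile(states=points, prop=prop, T=T)


def solve_reference_coefficients(
    species: SpeciesRecord, candidates: Sequence[SpeciesRecord]
) -> dict[str, Fraction] | None:
    """Solve Σ cⱼ·composition(refⱼ) = composition(species) for rational cⱼ ≥ 0.

    Returns the coefficient map when the linear system has a unique
    non-negative solution, else ``None`` (under- or over-determined, or a
    negative coefficient required).
    """
    elements = sorted(
        set(species.composition) | {el for c in candidates for el in c.composition}
    )
    if not elements or not candidates:
        return None
    A = sympy.Matrix(
        [[c.composition.get(el, 0) for c in candidates] for el in elements]
    )
    b = sympy.Matrix([species.composition.get(el, 0) for el in elements])
    if A.rank() != len(candidates) or A.rank() != sympy.Matrix.hstack(A, b).rank():
        return None
    sol = A.solve_least_squares(b)
    if any(v < 0 for v in sol):
        return None
    # verify exactness (rank test above guarantees consistency, but be safe)
    if sympy.simplify(A * sol - b).norm() != 0:
        return None
    return {
        c.name: Fraction(int(sympy.fraction(v)[0]), int(sympy.fraction(v)[1]))
        for c, v in zip(candidates, sol)
        if v != 0
    }
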