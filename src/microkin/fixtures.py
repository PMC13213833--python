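"""Synthetic inputs with known answers.

Everything the other modules consume — geometries, ORCA-like output texts,
mechanism files, kinetic networks — can be generated here deterministically
from a seed, together with the closed-form result the simulation or fit is
expected to reproduce.  The geometries are physically plausible random
structures, not optimized ones: they exercise parsing, composition algebra
and the RRHO plumbing, while numerical correctness is checked against the
closed forms, not against real molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import R_KCAL
from .errors import DomainError
from .kinetics import eyring_rate
from .mkm import MKMProblem, NetworkStep, build_network
from .network import SpeciesRecord
from .qc_io import Geometry, RawQCRecord

__all__ = [
    "FixtureSpec",
    "make_species",
    "make_orca_like_text",
    "make_first_order_network",
    "make_competing_network",
    "make_arrhenius_dataset",
]

_ELEMENT_POOL = ["C", "H", "O", "N", "F", "Cl", "Br", "S", "P"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for deterministic synthetic species generation."""

    seed: int = 0
    n_atoms_min: int = 2
    n_atoms_max: int = 8
    freq_min: float = 50.0          # cm^-1
    freq_max: float = 3500.0
    energy_min: float = -250.0      # Hartree
    energy_max: float = -50.0
    transition_state: bool = False
    multiplicity: int = 1


def make_species(spec: FixtureSpec = FixtureSpec(), name: str = "species") -> SpeciesRecord:
    """A random but self-consistent species record.

    Identical spec (including seed) → identical record.  A transition-state
    spec gets exactly one imaginary (negative) frequency.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = int(rng.integers(spec.n_atoms_min, spec.n_atoms_max + 1))
    elements = [str(rng.choice(_ELEMENT_POOL)) for _ in range(n_atoms)]
    # spread atoms on a perturbed cubic lattice so no two coincide
    side = max(2, int(math.ceil(n_atoms ** (1.0 / 3.0))))
    sites = [
        (i % side, (i // side) % side, i // (side * side))
        for i in range(n_atoms)
    ]
    # 6 decimals: matches the precision the ORCA-like emitter prints, so
    # text round trips are exact
    coords = [
        tuple(round(1.5 * s + 0.3 * rng.uniform(-1, 1), 6) for s in site)
        for site in sites
    ]
    geometry = Geometry(elements, [tuple(map(float, c)) for c in coords],
                        comment=f"synthetic fixture seed={spec.seed}")
    n_modes = max(0, 3 * n_atoms - 6)
    freqs = sorted(
        float(rng.uniform(spec.freq_min, spec.freq_max)) for _ in range(n_modes)
    )
    if spec.transition_state:
        if not freqs:
            freqs = [500.0]
        freqs[0] = -abs(float(rng.uniform(100.0, 1500.0)))
    energy = float(rng.uniform(spec.energy_min, spec.energy_max))
    return SpeciesRecord(
        name=name,
        role="transition_state" if spec.transition_state else "minimum",
        electronic_energy=round(energy, 9),
        geometry=geometry,
        frequencies=[round(f, 2) for f in freqs],
        multiplicity=spec.multiplicity,
    )


def make_orca_like_text(record: SpeciesRecord | RawQCRecord) -> str:
    """Emit the pinned ORCA-like output dialect for a record.

    ``qc_io.parse_orca_like`` inverts this emitter exactly (energies to the
    printed 9 decimals, frequencies to 2).  Six exact-zero placeholder modes
    are emitted before the real frequencies, as a frequency job would for
    the translational/rotational modes; the parser drops them.
    """
    lines = [
        "                                 *****************",
        "                                 * Synthetic output *",
        "                                 *****************",
        "",
    ]
    geometry = record.geometry
    if geometry is not None:
        lines += [
            "CARTESIAN COORDINATES (ANGSTROEM)",
            "---------------------------------",
        ]
        for el, (x, y, z) in zip(geometry.elements, geometry.coordinates):
            lines.append(f"  {el:<3s}{x:15.6f}{y:15.6f}{z:15.6f}")
        lines.append("")
    lines += [
        f" Multiplicity           Mult            ....    {record.multiplicity}",
        "",
        f"FINAL SINGLE POINT ENERGY      {record.electronic_energy:.9f}",
        "",
    ]
    if record.frequencies:
        lines += [
            "-----------------------",
            "VIBRATIONAL FREQUENCIES",
            "-----------------------",
            "",
        ]
        placeholders = [0.0] * 6
        for i, nu in enumerate(placeholders + list(record.frequencies)):
            lines.append(f"{i:>6d}: {nu:>12.2f} cm**-1")
        lines.append("")
    return "\n".join(lines) + "\n"


def make_first_order_network(
    k: float, c0: float = 1.0, t_end: float | None = None
) -> tuple[MKMProblem, Callable[[np.ndarray], np.ndarray]]:
    """Irreversible A → B with rate constant ``k`` and its closed form.

    Returns the problem plus ``c_A(t) = c0·exp(−k t)`` for assertions.
    """
    if k < 0:
        raise DomainError("k must be non-negative")
    network = build_network([NetworkStep({"A": 1}, {"B": 1}, k_f=k, label="A->B")])
    # long enough for the equilibrium event (‖dC/dt‖ < eq_tol) to fire
    t_end = t_end if t_end is not None else (60.0 / k if k > 0 else 1.0)
    problem = MKMProblem(network=network, c0={"A": c0}, t_end=t_end)

    def closed_form(t: np.ndarray) -> np.ndarray:
        return c0 * np.exp(-k * np.asarray(t, dtype=float))

    return problem, closed_form


def make_competing_network(
    ddg: float, g_act_base: float = 15.0, T: float = 373.15, c0: float = 1.0
) -> tuple[MKMProblem, float]:
    """Two irreversible channels A → B and A → C with barriers g and g+ΔΔG‡.

    Rate constants come from the Eyring equation at ``T``; the attached
    analytic selectivity toward B is 1/(1+exp(−ΔΔG‡/RT)), independent of
    when it is evaluated.
    """
    if T <= 0:
        raise DomainError("T must be positive")
    k1 = eyring_rate(g_act_base, T).value
    k2 = eyring_rate(g_act_base + ddg, T).value
    network = build_network(
        [
            NetworkStep({"A": 1}, {"B": 1}, k_f=k1, label="A->B"),
            NetworkStep({"A": 1}, {"C": 1}, k_f=k2, label="A->C"),
        ]
    )
    t_end = 60.0 / (k1 + k2)
    problem = MKMProblem(network=network, c0={"A": c0}, t_end=t_end, T=T)
    analytic_selectivity = 1.0 / (1.0 + math.exp(-ddg / (R_KCAL * T)))
    return problem, analytic_selectivity


def make_arrhenius_dataset(
    ea: float,
    ln_a: float,
    temperatures: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(T, k) pairs from k(T) = exp(lnA − Ea/RT), optionally log-normal noisy.

    ``ea`` in kcal/mol.  With ``noise_sd`` > 0 each rate is multiplied by
    exp(ε), ε ~ N(0, noise_sd²), drawn from the given seed.
    """
    if len(temperatures) < 2:
        raise DomainError("need at least two temperatures")
    rng = np.random.default_rng(seed)
    out = []
    for T in temperatures:
        if T <= 0:
            raise DomainError("temperatures must be positive")
        k = math.exp(ln_a - ea / (R_KCAL * T))
        if noise_sd > 0:
            k *= math.exp(noise_sd * rng.standard_normal())
        out.append((float(T), k))
    return out
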