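"""Physical constants and unit conversions (CODATA 2018, pinned).

All thermochemistry and kinetics in this package run off this single table so
that closed-form oracles and the implementation can never drift apart.
Energies are stored internally in Hartree where they come from electronic
structure, and reported in kcal/mol; entropies are reported in cal/(mol K).
"""

from dataclasses import dataclass
from typing import Final


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-2018 constants. SI units unless stated otherwise."""

    kB: float = 1.380649e-23          # J/K (exact)
    h: float = 6.62607015e-34         # J s (exact)
    c: float = 2.99792458e10          # cm/s (exact; cm-based for wavenumbers)
    NA: float = 6.02214076e23         # 1/mol (exact)
    amu: float = 1.66053906660e-27    # kg
    cal: float = 4.184                # J (thermochemical calorie, exact)
    hartree_to_kcal: float = 627.5094740631  # kcal/mol per Hartree

    @property
    def R(self) -> float:
        """Molar gas constant, J/(mol K)."""
        return self.kB * self.NA


CONSTANTS: Final[PhysicalConstants] = PhysicalConstants()

#: J/(mol K)
R: Final[float] = CONSTANTS.R
#: kcal/(mol K) — gas constant in reporting units
R_KCAL: Final[float] = R / (CONSTANTS.cal * 1000.0)
#: cal/(mol K)
R_CAL: Final[float] = R / CONSTANTS.cal

HARTREE_TO_KCAL: Final[float] = CONSTANTS.hartree_to_kcal
KCAL_TO_J: Final[float] = CONSTANTS.cal * 1000.0
KJ_PER_KCAL: Final[float] = 4.184

ATM: Final[float] = 101325.0   # Pa
BAR: Final[float] = 1.0e5      # Pa
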