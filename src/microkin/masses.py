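"""Atomic data: element symbols and pinned atomic masses.

Masses are the most-abundant-isotope masses in amu (version 1 of the table;
values pinned so thermochemistry is reproducible across environments).
``SYMBOLS`` covers the full periodic table for symbol validation; the mass
table covers the elements that occur in molecular thermochemistry practice —
asking for the mass of an element outside it raises ``UnknownElementError``.
"""

from .errors import UnknownElementError

SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe
    Co Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn
    Sb Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W
    Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf
    Es Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

ISOTOPE_MASS_VERSION = 1

#: most-abundant-isotope mass, amu
MASSES = {
    "H": 1.00782503207, "He": 4.002603254, "Li": 7.016004548,
    "Be": 9.012182201, "B": 11.009305406, "C": 12.0,
    "N": 14.003074005, "O": 15.994914620, "F": 18.998403224,
    "Ne": 19.992440175, "Na": 22.989769281, "Mg": 23.985041699,
    "Al": 26.981538627, "Si": 27.976926532, "P": 30.973761629,
    "S": 31.972070999, "Cl": 34.968852682, "Ar": 39.962383123,
    "K": 38.963706679, "Ca": 39.962590983, "Sc": 44.955911909,
    "Ti": 47.947946281, "V": 50.943959507, "Cr": 51.940507472,
    "Mn": 54.938045141, "Fe": 55.934937475, "Co": 58.933195048,
    "Ni": 57.935342907, "Cu": 62.929597474, "Zn": 63.929142222,
    "Ga": 68.925573587, "Ge": 73.921177767, "As": 74.921596478,
    "Se": 79.916521271, "Br": 78.918337087, "Kr": 83.911506687,
    "Rb": 84.911789737, "Sr": 87.905612124, "Y": 88.905848295,
    "Zr": 89.904704416, "Nb": 92.906378058, "Mo": 97.905408169,
    "Ru": 101.904349312, "Rh": 102.905504292, "Pd": 105.903485715,
    "Ag": 106.905096820, "Cd": 113.903358554, "In": 114.903878484,
    "Sn": 119.902194676, "Sb": 120.903815686, "Te": 129.906224399,
    "I": 126.904472681, "Xe": 131.904153457, "Cs": 132.905451932,
    "Ba": 137.905247237, "La": 138.906353267, "Ce": 139.905438706,
    "W": 183.950931188, "Re": 186.955753109, "Os": 191.961480700,
    "Ir": 192.962926400, "Pt": 194.964791134, "Au": 196.966568662,
    "Hg": 201.970643011, "Tl": 204.974427541, "Pb": 207.976652071,
    "Bi": 208.980398734, "U": 238.050788247,
}


def is_valid_symbol(symbol: str) -> bool:
    return symbol in SYMBOLS


def atomic_mass(symbol: str) -> float:
    """Mass of ``symbol`` in amu; raises UnknownElementError if unknown."""
    try:
        return MASSES[symbol]
    except KeyError:
        raise UnknownElementError(
            f"no pinned atomic mass for element {symbol!r}"
        ) from None
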