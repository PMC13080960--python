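"""Periodic-table data: symbols, covalent radii, default valences."""

from __future__ import annotations

# All 118 IUPAC element symbols, canonical capitalization.
ELEMENT_SYMBOLS: frozenset[str] = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

_TWO_LETTER = frozenset(s for s in ELEMENT_SYMBOLS if len(s) == 2)

# Covalent radii in angstrom (Cordero et al. single-bond values, common subset).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24,
    "Cu": 1.32, "Zn": 1.22, "As": 1.19, "Se": 1.20, "Br": 1.20,
    "Mo": 1.54, "Ag": 1.45, "Cd": 1.44, "I": 1.39, "Pt": 1.36, "Au": 1.36,
    "Hg": 1.32,
}

# Default (neutral, lowest) valences used by formal-charge bookkeeping.
DEFAULT_VALENCE: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "As": 3, "Se": 2, "Br": 1, "I": 1,
}

# Elements that accept expanded valence shells (allowed coordination numbers).
HYPERVALENT: dict[str, tuple[int, ...]] = {
    "P": (3, 5),
    "S": (2, 4, 6),
    "As": (3, 5),
    "Se": (2, 4, 6),
}


def canonical_symbol(text: str) -> str | None:
    """Canonicalize an element symbol ('FE' -> 'Fe'); None if not an element."""
    s = text.strip()
    if not s:
        return None
    sym = s[0].upper() + s[1:].lower()
    return sym if sym in ELEMENT_SYMBOLS else None


def is_two_letter_symbol(text: str) -> bool:
    sym = canonical_symbol(text)
    return sym is not None and sym in _TWO_LETTER
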