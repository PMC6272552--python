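"""Per-element reference data: nuclear charges, masses, covalent radii."""

from __future__ import annotations

# element symbol -> nuclear charge
SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
    # Drude / virtual site marker
    "X": 0,
}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

# standard atomic weights (amu)
MASSES = {
    "H": 1.00794, "He": 4.002602, "Li": 6.941, "Be": 9.012182,
    "B": 10.811, "C": 12.0107, "N": 14.0067, "O": 15.9994,
    "F": 18.9984032, "Ne": 20.1797, "Na": 22.98976928, "Mg": 24.3050,
    "Al": 26.9815386, "Si": 28.0855, "P": 30.973762, "S": 32.065,
    "Cl": 35.453, "Ar": 39.948, "K": 39.0983, "Ca": 40.078,
    "Br": 79.904, "I": 126.90447, "X": 0.4,
}

# single-bond covalent radii (Å), Cordero-type table
COVALENT_RADII_ANG = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "I": 1.39,
}


def z_of(symbol: str) -> int:
    try:
        return SYMBOL_TO_Z[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def mass_of(symbol: str) -> float:
    try:
        return MASSES[symbol]
    except KeyError:
        raise ValueError(f"no tabulated mass for element: {symbol!r}") from None


def covalent_radius_ang(symbol: str) -> float:
    try:
        return COVALENT_RADII_ANG[symbol]
    except KeyError:
        raise ValueError(
            f"no covalent radius tabulated for element: {symbol!r}"
        ) from None
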