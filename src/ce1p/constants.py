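"""Physical constants, unit conversions and per-element data tables.

Internal units are hartree and bohr throughout the package; kJ/mol and
angstrom appear only at I/O boundaries.
"""

from __future__ import annotations

import numpy as np

HARTREE_TO_KJMOL = 2625.499639
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
]
_EXTRA = {"Br": 35, "I": 53, "Kr": 36, "Xe": 54}

SYMBOL_TO_Z = {s: i for i, s in enumerate(ELEMENTS) if i > 0}
SYMBOL_TO_Z.update(_EXTRA)
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}


def atomic_number(symbol: str) -> int:
    s = symbol.strip()
    s = s[0].upper() + s[1:].lower() if len(s) > 1 else s.upper()
    try:
        return SYMBOL_TO_Z[s]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


# Free-atom static dipole polarizabilities (bohr^3), Thakkar-style recommended
# values for neutral atoms.  Editable: the polarization model reads this table.
FREE_POLARIZABILITY = {
    "H": 4.50, "He": 1.38, "Li": 164.04, "Be": 37.74, "B": 20.43,
    "C": 11.67, "N": 7.26, "O": 5.24, "F": 3.70, "Ne": 2.66,
    "Na": 162.88, "Mg": 71.22, "Al": 57.79, "Si": 37.17, "P": 24.93,
    "S": 19.37, "Cl": 14.57, "Ar": 11.09, "K": 291.10, "Ca": 157.90,
    "Br": 21.03, "I": 32.98, "Kr": 16.78, "Xe": 27.06,
}

# Monatomic cations whose valence shell is emptied relative to the neutral
# atom: the neutral-atom polarizability is qualitatively wrong for these, so
# ion-specific values are tabulated.  Keyed by (symbol, charge).
ION_POLARIZABILITY = {
    ("Li", 1): 0.192,
    ("Na", 1): 0.998,
    ("K", 1): 5.34,
}


def free_polarizability(symbol: str, charge: int = 0) -> float:
    """alpha' of the free reference species (bohr^3)."""
    key = (symbol, charge)
    if charge != 0 and key in ION_POLARIZABILITY:
        return ION_POLARIZABILITY[key]
    try:
        return FREE_POLARIZABILITY[symbol]
    except KeyError:
        raise ValueError(f"no free polarizability tabulated for {symbol}") from None


# Covalent radii (angstrom), Cordero-style, used for bond detection.
COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Ar": 1.06, "K": 2.03, "Ca": 1.76,
    "Br": 1.20, "I": 1.39, "Kr": 1.16, "Xe": 1.40,
}

# Bragg-Slater radii (angstrom) used to scale radial integration grids.
BRAGG_RADIUS = {
    "H": 0.35, "He": 0.31, "Li": 1.45, "Be": 1.05, "B": 0.85,
    "C": 0.70, "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 0.45,
    "Na": 1.80, "Mg": 1.50, "Al": 1.25, "Si": 1.10, "P": 1.00,
    "S": 1.00, "Cl": 1.00, "Ar": 0.88, "K": 2.20, "Ca": 1.80,
    "Br": 1.15, "I": 1.40, "Kr": 1.25, "Xe": 1.55,
}

# Average crystallographic (neutron) X-H bond lengths in angstrom, used when
# normalizing hydrogen positions from X-ray structures.
XH_BOND_LENGTHS = {"C": 1.083, "N": 1.009, "O": 0.983, "B": 1.180}


def bragg_radius_bohr(symbol: str) -> float:
    return BRAGG_RADIUS.get(symbol, 1.0) * ANGSTROM_TO_BOHR


def covalent_radius_bohr(symbol: str) -> float:
    return COVALENT_RADIUS.get(symbol, 1.2) * ANGSTROM_TO_BOHR


def as_float_array(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=np.float64))
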