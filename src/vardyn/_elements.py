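"""Embedded per-element parameter tables.

Masses in amu, van der Waals radii in Angstrom, Lennard-Jones well depth
epsilon in kcal/mol, LJ sigma in Angstrom. Values are generic force-field
magnitudes adequate for the geometric descriptors and the declared
pairwise-energy stability surrogate; they are not tied to any specific
published force field.
"""

from __future__ import annotations

ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

VDW_RADIUS = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

# (epsilon kcal/mol, sigma Angstrom)
LJ_PARAMS = {
    "H": (0.0157, 2.50),
    "C": (0.0860, 3.40),
    "N": (0.1700, 3.25),
    "O": (0.2100, 2.96),
    "S": (0.2500, 3.56),
    "P": (0.2000, 3.74),
}

# crude partial charges keyed by backbone role, falling back to element
ROLE_CHARGE = {
    "N": -0.42,
    "H": 0.27,
    "CA": 0.03,
    "C": 0.60,
    "O": -0.57,
}

ELEMENT_CHARGE = {
    "H": 0.10,
    "C": 0.00,
    "N": -0.30,
    "O": -0.40,
    "S": -0.10,
    "P": 0.00,
}

DEFAULT_MASS = 12.011
DEFAULT_VDW = 1.70


def element_from_atom_name(name: str) -> str:
    """Infer the element from a PDB-style atom name (first alphabetic char)."""
    for ch in name.strip():
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")
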