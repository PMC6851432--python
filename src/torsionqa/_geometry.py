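"""Idealized amino-acid geometry tables.

Bond lengths (Å) and angles (degrees) are rounded textbook values
(Engh & Huber-like); they are pinned here so that build → measure
round trips in the test suite are stable to well below 1e-3 degrees.
Only heavy atoms are described.
"""

from __future__ import annotations

from typing import NamedTuple, Union

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = frozenset(THREE_TO_ONE)

# Nonstandard residues mapped to a standard parent for scoring purposes.
NONSTANDARD_PARENT = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine
    "HYP": "PRO",  # hydroxyproline
    "PYL": "LYS",  # pyrrolysine
    "MLY": "LYS",
    "CSO": "CYS",
    "PTR": "TYR",
    "SEP": "SER",
    "TPO": "THR",
}

# Number of sidechain chi torsions per residue type (standard definitions).
N_CHI = {
    "GLY": 0, "ALA": 0,
    "SER": 1, "CYS": 1, "VAL": 1, "THR": 1,
    "ASP": 2, "ASN": 2, "HIS": 2, "ILE": 2, "LEU": 2,
    "PHE": 2, "PRO": 2, "TRP": 2, "TYR": 2,
    "MET": 3, "GLU": 3, "GLN": 3,
    "LYS": 4, "ARG": 4,
}

# Canonical sidechain heavy-atom counts (CB and beyond).
N_SC = {
    "GLY": 0, "ALA": 1, "SER": 2, "CYS": 2, "PRO": 3, "THR": 3,
    "VAL": 3, "ASP": 4, "ASN": 4, "ILE": 4, "LEU": 4, "MET": 4,
    "GLU": 5, "GLN": 5, "LYS": 5, "HIS": 6, "ARG": 7, "PHE": 7,
    "TYR": 8, "TRP": 10,
}

# chi1 is N-CA-CB-<X>; the fourth atom per residue type.
CHI1_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

# chi2 is CA-CB-<third>-<fourth>.
CHI2_ATOMS = {
    "ARG": ("CG", "CD"), "ASN": ("CG", "OD1"), "ASP": ("CG", "OD1"),
    "GLN": ("CG", "CD"), "GLU": ("CG", "CD"), "HIS": ("CG", "ND1"),
    "ILE": ("CG1", "CD1"), "LEU": ("CG", "CD1"), "LYS": ("CG", "CD"),
    "MET": ("CG", "SD"), "PHE": ("CG", "CD1"), "PRO": ("CG", "CD"),
    "TRP": ("CG", "CD1"), "TYR": ("CG", "CD1"),
}

# Residue types whose chi2 torsion is chemically 2-fold symmetric
# (terminal atom naming is arbitrary in experimental models).
CHI2_SYMMETRIC = frozenset({"ASP", "PHE", "TYR"})

# Backbone geometry.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
BOND_CA_CB = 1.530
ANGLE_C_CA_CB = 110.1
# Improper N-C-CA-CB fixing L-chirality of the alpha carbon.
IMPROPER_N_C_CA_CB = 122.6

ELEMENT_OF = {"C": "C", "N": "N", "O": "O", "S": "S"}


class ZEntry(NamedTuple):
    """One sidechain atom placed by natural-extension (NeRF).

    ``refs`` are three previously placed atom names (a, b, c); the new
    atom d satisfies |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion.  ``torsion`` is either a float
    (constant, degrees) or a ("chi1"|"chi2", offset) tuple meaning
    the named torsion plus a constant offset.
    """

    name: str
    refs: tuple[str, str, str]
    bond: float
    angle: float
    torsion: Union[float, tuple[str, float]]


def _z(name, refs, bond, angle, torsion):
    return ZEntry(name, refs, bond, angle, torsion)


_C1 = ("chi1", 0.0)
_C2 = ("chi2", 0.0)

# Sidechain Z-matrices (beyond CB, which is placed by the backbone builder).
SIDECHAIN_ZMATRIX: dict[str, list[ZEntry]] = {
    "GLY": [],
    "ALA": [],
    "SER": [_z("OG", ("N", "CA", "CB"), 1.417, 110.8, _C1)],
    "CYS": [_z("SG", ("N", "CA", "CB"), 1.808, 113.8, _C1)],
    "THR": [
        _z("OG1", ("N", "CA", "CB"), 1.433, 109.6, _C1),
        _z("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", -120.0)),
    ],
    "VAL": [
        _z("CG1", ("N", "CA", "CB"), 1.521, 110.5, _C1),
        _z("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", 122.5)),
    ],
    "LEU": [
        _z("CG", ("N", "CA", "CB"), 1.530, 116.3, _C1),
        _z("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _C2),
        _z("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi2", 122.5)),
    ],
    "ILE": [
        _z("CG1", ("N", "CA", "CB"), 1.530, 110.4, _C1),
        _z("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi1", -122.5)),
        _z("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _C2),
    ],
    "PRO": [
        _z("CG", ("N", "CA", "CB"), 1.492, 104.5, _C1),
        _z("CD", ("CA", "CB", "CG"), 1.503, 106.1, _C2),
    ],
    "MET": [
        _z("CG", ("N", "CA", "CB"), 1.520, 114.1, _C1),
        _z("SD", ("CA", "CB", "CG"), 1.803, 112.7, _C2),
        _z("CE", ("CB", "CG", "SD"), 1.791, 100.9, 180.0),
    ],
    "ASP": [
        _z("CG", ("N", "CA", "CB"), 1.516, 112.6, _C1),
        _z("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _C2),
        _z("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi2", 180.0)),
    ],
    "ASN": [
        _z("CG", ("N", "CA", "CB"), 1.516, 112.6, _C1),
        _z("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _C2),
        _z("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi2", 180.0)),
    ],
    "GLU": [
        _z("CG", ("N", "CA", "CB"), 1.520, 114.1, _C1),
        _z("CD", ("CA", "CB", "CG"), 1.516, 112.6, _C2),
        _z("OE1", ("CB", "CG", "CD"), 1.249, 118.4, 0.0),
        _z("OE2", ("CB", "CG", "CD"), 1.249, 118.4, 180.0),
    ],
    "GLN": [
        _z("CG", ("N", "CA", "CB"), 1.520, 114.1, _C1),
        _z("CD", ("CA", "CB", "CG"), 1.516, 112.6, _C2),
        _z("OE1", ("CB", "CG", "CD"), 1.231, 120.8, 0.0),
        _z("NE2", ("CB", "CG", "CD"), 1.328, 116.4, 180.0),
    ],
    "LYS": [
        _z("CG", ("N", "CA", "CB"), 1.520, 114.1, _C1),
        _z("CD", ("CA", "CB", "CG"), 1.520, 111.3, _C2),
        _z("CE", ("CB", "CG", "CD"), 1.520, 111.3, 180.0),
        _z("NZ", ("CG", "CD", "CE"), 1.489, 111.9, 180.0),
    ],
    "ARG": [
        _z("CG", ("N", "CA", "CB"), 1.520, 114.1, _C1),
        _z("CD", ("CA", "CB", "CG"), 1.520, 111.3, _C2),
        _z("NE", ("CB", "CG", "CD"), 1.461, 112.0, 180.0),
        _z("CZ", ("CG", "CD", "NE"), 1.329, 124.2, 180.0),
        _z("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
        _z("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0),
    ],
    "HIS": [
        _z("CG", ("N", "CA", "CB"), 1.497, 113.8, _C1),
        _z("ND1", ("CA", "CB", "CG"), 1.378, 122.7, _C2),
        _z("CD2", ("CA", "CB", "CG"), 1.354, 131.1, ("chi2", 180.0)),
        _z("CE1", ("CB", "CG", "ND1"), 1.321, 109.0, 180.0),
        _z("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0),
    ],
    "PHE": [
        _z("CG", ("N", "CA", "CB"), 1.502, 113.8, _C1),
        _z("CD1", ("CA", "CB", "CG"), 1.384, 120.7, _C2),
        _z("CD2", ("CA", "CB", "CG"), 1.384, 120.7, ("chi2", 180.0)),
        _z("CE1", ("CB", "CG", "CD1"), 1.382, 120.7, 180.0),
        _z("CE2", ("CB", "CG", "CD2"), 1.382, 120.7, 180.0),
        _z("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0),
    ],
    "TYR": [
        _z("CG", ("N", "CA", "CB"), 1.512, 113.9, _C1),
        _z("CD1", ("CA", "CB", "CG"), 1.389, 120.8, _C2),
        _z("CD2", ("CA", "CB", "CG"), 1.389, 120.8, ("chi2", 180.0)),
        _z("CE1", ("CB", "CG", "CD1"), 1.382, 121.1, 180.0),
        _z("CE2", ("CB", "CG", "CD2"), 1.382, 121.1, 180.0),
        _z("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        _z("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "TRP": [
        _z("CG", ("N", "CA", "CB"), 1.498, 113.6, _C1),
        _z("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _C2),
        _z("CD2", ("CA", "CB", "CG"), 1.433, 126.7, ("chi2", 180.0)),
        _z("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        _z("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        _z("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, 180.0),
        _z("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        _z("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
        _z("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, 0.0),
    ],
}

# Default sidechain torsions used when a fixture spec leaves chi free.
DEFAULT_CHI1 = -65.0
DEFAULT_CHI2 = 180.0


def element_of(atom_name: str) -> str:
    """Infer the element from a heavy-atom PDB name (first letter)."""
    return atom_name.strip()[0]


def _torsion_movers(res_type: str, which: str) -> frozenset[str]:
    moving: set[str] = set()
    for entry in SIDECHAIN_ZMATRIX[res_type]:
        spec = entry.torsion
        named = isinstance(spec, tuple) and spec[0] == which
        chained = which == "chi1" and isinstance(spec, tuple) and spec[0] == "chi2"
        if named or chained or any(r in moving for r in entry.refs):
            moving.add(entry.name)
    return frozenset(moving)


# Atoms that move rigidly when chi1 / chi2 is rotated.
CHI1_MOVERS = {rt: _torsion_movers(rt, "chi1") for rt in SIDECHAIN_ZMATRIX}
CHI2_MOVERS = {rt: _torsion_movers(rt, "chi2") for rt in SIDECHAIN_ZMATRIX}
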