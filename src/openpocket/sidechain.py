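"""Side-chain torsion geometry: chi definitions, measurement, and rotation.

Torsions follow the standard chi1-chi4 conventions.  Setting a torsion
rotates the distal heavy atoms about the central bond, keeping all bond
lengths and angles as found in the input coordinates; hydrogens are not
tracked (sampling and maps operate on heavy atoms).
"""

from __future__ import annotations

import math

import numpy as np

from .structure import Residue

#: chi dihedral atom quadruples per residue (standard chi1..chi4)
CHI_DEFS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "CYS": [("N", "CA", "CB", "SG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
}

#: heavy atoms displaced when rotating each chi (distal to the central bond)
MOVED_ATOMS: dict[str, list[list[str]]] = {
    "SER": [["OG"]],
    "CYS": [["SG"]],
    "THR": [["OG1", "CG2"]],
    "VAL": [["CG1", "CG2"]],
    "LEU": [["CG", "CD1", "CD2"], ["CD1", "CD2"]],
    "ILE": [["CG1", "CG2", "CD1"], ["CD1"]],
    "MET": [["CG", "SD", "CE"], ["SD", "CE"], ["CE"]],
    "LYS": [["CG", "CD", "CE", "NZ"], ["CD", "CE", "NZ"], ["CE", "NZ"], ["NZ"]],
    "ARG": [["CG", "CD", "NE", "CZ", "NH1", "NH2"],
            ["CD", "NE", "CZ", "NH1", "NH2"],
            ["NE", "CZ", "NH1", "NH2"], ["CZ", "NH1", "NH2"]],
    "ASP": [["CG", "OD1", "OD2"], ["OD1", "OD2"]],
    "ASN": [["CG", "OD1", "ND2"], ["OD1", "ND2"]],
    "GLU": [["CG", "CD", "OE1", "OE2"], ["CD", "OE1", "OE2"], ["OE1", "OE2"]],
    "GLN": [["CG", "CD", "OE1", "NE2"], ["CD", "OE1", "NE2"], ["OE1", "NE2"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"],
            ["ND1", "CD2", "CE1", "NE2"]],
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
            ["CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
            ["CD1", "CD2", "CE1", "CE2", "CZ", "OH"]],
    "TRP": [["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
            ["CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"]],
}

#: backbone heavy-atom names (never displaced by chi rotations)
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def has_rotatable_side_chain(residue: Residue) -> bool:
    if residue.name not in CHI_DEFS:
        return False
    quad0 = CHI_DEFS[residue.name][0]
    return all(residue.has_atom(n) for n in quad0)


def n_chis(residue: Residue) -> int:
    """Number of chi angles actually resolvable from the residue's atoms."""
    if residue.name not in CHI_DEFS:
        return 0
    count = 0
    for quad in CHI_DEFS[residue.name]:
        if all(residue.has_atom(n) for n in quad):
            count += 1
        else:
            break
    return count


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return math.degrees(math.atan2(y, x))


def measure_chis(residue: Residue) -> list[float]:
    """Current chi angles (degrees) for the residue."""
    out = []
    for k in range(n_chis(residue)):
        quad = CHI_DEFS[residue.name][k]
        pts = [residue.atom(n).coords for n in quad]
        out.append(dihedral(*pts))
    return out


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([
        [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s,
         ux * uz * (1 - c) + uy * s],
        [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c),
         uy * uz * (1 - c) - ux * s],
        [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s,
         c + uz * uz * (1 - c)],
    ])


def set_chi(residue: Residue, chi_index: int, angle_deg: float) -> None:
    """Rotate the distal atoms so chi ``chi_index`` equals ``angle_deg``."""
    quads = CHI_DEFS.get(residue.name)
    if quads is None or chi_index >= n_chis(residue):
        raise ValueError(f"{residue.label}: no chi{chi_index + 1}")
    a, b, c, d = (residue.atom(n).coords for n in quads[chi_index])
    current = dihedral(a, b, c, d)
    # right-hand rotation about the b->c axis decreases the dihedral
    delta = math.radians(current - angle_deg)
    rot = _rotation_matrix(c - b, delta)
    for name in MOVED_ATOMS[residue.name][chi_index]:
        if residue.has_atom(name):
            atom = residue.atom(name)
            atom.coords = b + rot @ (atom.coords - b)


def set_chis(residue: Residue, angles_deg: list[float] | tuple[float, ...]) -> None:
    """Set chi1..chiN in order (proximal first, so later settings persist)."""
    for k, ang in enumerate(angles_deg):
        set_chi(residue, k, float(ang))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, bond_angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Position atom d from internal coordinates relative to chain a-b-c.

    ``|d - c| = bond_length``, angle(b, c, d) = ``bond_angle_deg`` and
    dihedral(a, b, c, d) = ``torsion_deg`` (natural-extension reference
    frame construction).
    """
    theta = math.radians(bond_angle_deg)
    tau = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond_length * math.cos(theta),
        bond_length * math.sin(theta) * math.cos(tau),
        -bond_length * math.sin(theta) * math.sin(tau),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
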