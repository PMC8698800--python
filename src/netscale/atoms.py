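"""Atom metadata: van der Waals radii, residue templates, element inference.

The default radius table is the Bondi set for the elements that occur in
heavy-atom protein structures.  Residue templates list the standard PDB
heavy-atom names and side-chain bond connectivity for the twenty amino
acids; they drive atom-table construction, clash exclusion lists and the
minimizer topology.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

# Bondi van der Waals radii, Angstrom.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "SE": 1.90,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Side-chain bonds (standard PDB atom names), excluding the CA-CB bond
# which every non-glycine residue shares.
SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CB", "SG")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CB", "OG")],
    "THR": [("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"), ("CE2", "CZ2"),
            ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
}


def _sidechain_atoms(res_name: str) -> list[str]:
    if res_name == "GLY":
        return []
    seen: list[str] = ["CB"]
    for a, b in SIDECHAIN_BONDS[res_name]:
        for name in (a, b):
            if name not in seen and name != "N":
                seen.append(name)
    return seen


#: Heavy-atom names for each residue (backbone first), no terminal OXT.
RESIDUE_HEAVY_ATOMS: dict[str, list[str]] = {
    res: ["N", "CA", "C", "O"] + _sidechain_atoms(res) for res in SIDECHAIN_BONDS
}


def element_of_atom(atom_name: str, res_name: str | None = None) -> str:
    """Infer the element from a PDB atom name (protein convention)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name in ("OXT", "OT1", "OT2"):
        return "O"
    if name[0].isdigit():
        name = name[1:]
    if name[:2] in ("CL", "BR", "SE") and len(atom_name.strip()) <= 2:
        return name[:2]
    return name[0]


def load_radius_table(path: str | Path) -> dict[str, float]:
    """Read a two-column plain-text radius table (element, radius in Angstrom)."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        element, radius = line.split()
        table[element.upper()] = float(radius)
    return table


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Van der Waals radius of *element* in Angstrom.

    Raises ``KeyError`` naming the element if the table has no entry.
    """
    table = DEFAULT_VDW_RADII if table is None else table
    key = element.upper()
    if key not in table:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    radius = table[key]
    if radius <= 0:
        raise ValueError(f"non-positive radius for element {element!r}")
    return radius


def radii_for(elements, table: dict[str, float] | None = None) -> np.ndarray:
    """Vector of vdW radii for a sequence of element symbols."""
    return np.array([vdw_radius(e, table) for e in elements], dtype=float)


#: Amyloid-beta 1-40 sequence, shipped as a named fixture.
ABETA40_SEQUENCE = "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVV"
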