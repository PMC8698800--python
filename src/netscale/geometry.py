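"""Ideal peptide geometry: template bond/angle values, topology, NeRF placement.

One embedded table of ideal bond lengths and angles serves both the
synthetic backbone builder and the steric minimizer, keeping generator and
refiner self-consistent.  Values are standard trans-peptide geometry
(Engh/Huber-style averages).
"""

from __future__ import annotations

import numpy as np

from .atoms import SIDECHAIN_BONDS
from .core import AtomTable

# Ideal bond lengths, Angstrom, keyed by (atom_name, atom_name) within a
# residue or across the peptide bond.
IDEAL_BOND_LENGTHS: dict[tuple[str, str], float] = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("C", "N"): 1.329,   # peptide bond C(i)-N(i+1)
    ("CA", "CB"): 1.530,
    ("C", "OXT"): 1.231,
}

# Fallback bond lengths by element pair for side-chain bonds, Angstrom.
ELEMENT_BOND_LENGTHS: dict[frozenset, float] = {
    frozenset({"C"}): 1.53,
    frozenset({"C", "N"}): 1.47,
    frozenset({"C", "O"}): 1.42,
    frozenset({"C", "S"}): 1.81,
}

# Ideal angles, degrees, keyed by atom-name triples.
IDEAL_ANGLES_DEG: dict[tuple[str, str, str], float] = {
    ("N", "CA", "C"): 111.0,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N"): 116.6,   # to the next residue's N
    ("O", "C", "N"): 122.6,   # closes the planar carbonyl: 360 - 120.8 - 116.6
    ("C", "N", "CA"): 121.7,   # across the peptide bond
    ("N", "CA", "CB"): 110.5,
    ("C", "CA", "CB"): 110.1,
    ("CA", "C", "OXT"): 117.0,
    ("O", "C", "OXT"): 122.2,  # 360 - 120.8 - 117.0
}

def _cb_dihedral_deg() -> float:
    """Dihedral C-N-CA-CB consistent with the N-CA-C, N-CA-CB and C-CA-CB
    ideal angles (spherical cosine rule); the negative sign selects the
    L (S) alpha-carbon configuration."""
    t_nc = np.deg2rad(IDEAL_ANGLES_DEG[("N", "CA", "C")])
    t_ncb = np.deg2rad(IDEAL_ANGLES_DEG[("N", "CA", "CB")])
    t_ccb = np.deg2rad(IDEAL_ANGLES_DEG[("C", "CA", "CB")])
    cos_phi = (np.cos(t_ccb) - np.cos(t_nc) * np.cos(t_ncb)) / (
        np.sin(t_nc) * np.sin(t_ncb)
    )
    return -float(np.rad2deg(np.arccos(np.clip(cos_phi, -1.0, 1.0))))


#: Dihedral C(i-1)-N-CA-CB placing CB with L (S) alpha-carbon configuration.
CB_DIHEDRAL_DEG = _cb_dihedral_deg()


def ideal_bond_length(name_a: str, name_b: str, elem_a: str, elem_b: str) -> float:
    for key in ((name_a, name_b), (name_b, name_a)):
        if key in IDEAL_BOND_LENGTHS:
            return IDEAL_BOND_LENGTHS[key]
    pair = frozenset({elem_a.upper(), elem_b.upper()})
    if pair in ELEMENT_BOND_LENGTHS:
        return ELEMENT_BOND_LENGTHS[pair]
    return 1.50  # generic heavy-atom bond


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom from three reference positions (NeRF construction).

    The new atom is at distance ``bond`` from *c*, forming the given angle
    b-c-new and dihedral a-b-c-new.
    """
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("colinear reference atoms in NeRF placement")
    n /= norm
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


class Topology:
    """Bonded topology of a heavy-atom peptide: bonds, angles, exclusions."""

    def __init__(self, table: AtomTable):
        self.table = table
        self.bonds: list[tuple[int, int, float]] = []
        self.angles: list[tuple[int, int, int, float]] = []
        self._build()
        self.excluded = self._exclusion_pairs()

    def _idx(self, res: int, name: str):
        try:
            return self.table.atom_index(res, name)
        except KeyError:
            return None

    def _add_bond(self, i, j):
        if i is None or j is None:
            return
        d0 = ideal_bond_length(
            str(self.table.atom_names[i]), str(self.table.atom_names[j]),
            str(self.table.elements[i]), str(self.table.elements[j]),
        )
        self.bonds.append((i, j, d0))

    def _add_angle(self, i, j, k, key):
        if i is None or j is None or k is None:
            return
        self.angles.append((i, j, k, np.deg2rad(IDEAL_ANGLES_DEG[key])))

    def _build(self):
        table = self.table
        for r in range(1, table.n_residues + 1):
            res_name = str(table.res_names[table.res_ids == r][0])
            if res_name not in SIDECHAIN_BONDS:
                raise KeyError(f"no geometry template for residue {res_name!r}")
            n, ca, c, o = (self._idx(r, a) for a in ("N", "CA", "C", "O"))
            if n is None or ca is None or c is None:
                raise ValueError(f"residue {r} lacks a complete N/CA/C backbone")
            cb = self._idx(r, "CB")
            self._add_bond(n, ca)
            self._add_bond(ca, c)
            self._add_bond(c, o)
            if cb is not None:
                self._add_bond(ca, cb)
            for a_name, b_name in SIDECHAIN_BONDS[res_name]:
                self._add_bond(self._idx(r, a_name), self._idx(r, b_name))
            self._add_angle(n, ca, c, ("N", "CA", "C"))
            self._add_angle(ca, c, o, ("CA", "C", "O"))
            if cb is not None:
                self._add_angle(n, ca, cb, ("N", "CA", "CB"))
                self._add_angle(c, ca, cb, ("C", "CA", "CB"))
            if r < table.n_residues:
                n_next = self._idx(r + 1, "N")
                ca_next = self._idx(r + 1, "CA")
                self._add_bond(c, n_next)
                self._add_angle(ca, c, n_next, ("CA", "C", "N"))
                self._add_angle(o, c, n_next, ("O", "C", "N"))
                self._add_angle(c, n_next, ca_next, ("C", "N", "CA"))
            else:
                oxt = self._idx(r, "OXT")
                if oxt is not None:
                    self._add_bond(c, oxt)
                    self._add_angle(ca, c, oxt, ("CA", "C", "OXT"))
                    self._add_angle(o, c, oxt, ("O", "C", "OXT"))

    def _exclusion_pairs(self) -> set[frozenset]:
        """1-2 and 1-3 pairs excluded from nonbonded interactions."""
        neighbors: dict[int, set[int]] = {}
        for i, j, _ in self.bonds:
            neighbors.setdefault(i, set()).add(j)
            neighbors.setdefault(j, set()).add(i)
        excluded: set[frozenset] = set()
        for i, j, _ in self.bonds:
            excluded.add(frozenset((i, j)))
        for j, nbrs in neighbors.items():
            for i in nbrs:
                for k in nbrs:
                    if i < k:
                        excluded.add(frozenset((i, k)))
        return excluded

    def nonbonded_pairs(self) -> np.ndarray:
        """Index pairs (i, j), i<j, not excluded as 1-2 or 1-3."""
        n = self.table.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        mask = np.array(
            [frozenset((int(i), int(j))) not in self.excluded
             for i, j in zip(iu, ju)]
        )
        return np.stack([iu[mask], ju[mask]], axis=1)
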