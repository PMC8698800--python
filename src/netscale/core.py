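"""Core domain types: atom tables, structures, ensembles, triangle flattening.

A :class:`Structure` is one conformation — an ordered list of heavy-atom
records with coordinates in Angstrom.  An :class:`Ensemble` is a stack of
conformations of the same molecule: one shared :class:`AtomTable` plus a
``(n_frames, n_atoms, 3)`` coordinate array, in the spirit of mdtraj's
``Trajectory``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
from typing import Iterator, Sequence

import numpy as np

from .atoms import (
    ONE_TO_THREE,
    RESIDUE_HEAVY_ATOMS,
    THREE_TO_ONE,
    element_of_atom,
    vdw_radius,
)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom record (PDB naming convention, coordinates in Angstrom)."""

    atom_name: str
    element: str
    residue_index: int  # 1-based along the chain
    residue_name: str
    coords: np.ndarray

    def __post_init__(self):
        vdw_radius(self.element)  # element must be known
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")


class AtomTable:
    """Immutable per-atom metadata shared by every frame of an ensemble."""

    def __init__(self, atom_names, elements, res_ids, res_names):
        self.atom_names = np.asarray(atom_names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.res_names = np.asarray(res_names, dtype=object)
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.res_ids) == len(self.res_names) == n):
            raise ValueError("atom table columns have unequal lengths")
        if n == 0:
            raise ValueError("empty atom table")
        for e in set(self.elements):
            if str(e).upper() == "H":
                raise ValueError("atom table must not contain hydrogen records")
            vdw_radius(str(e))
        uniq = np.unique(self.res_ids)
        expected = np.arange(1, len(uniq) + 1)
        if not np.array_equal(np.sort(uniq), expected):
            raise ValueError("residue indices must be contiguous 1..n_residues")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return int(self.res_ids.max())

    @property
    def sequence(self) -> str:
        seq = []
        for r in range(1, self.n_residues + 1):
            name = self.res_names[self.res_ids == r][0]
            seq.append(THREE_TO_ONE.get(str(name), "X"))
        return "".join(seq)

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        return np.flatnonzero(self.res_ids == residue_index)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        mask = (self.res_ids == residue_index) & (self.atom_names == atom_name)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(
                f"residue {residue_index} has no atom named {atom_name!r}"
            )
        return int(idx[0])

    def fingerprint(self) -> str:
        """Stable hash of the atom metadata, used to guard model checkpoints."""
        payload = "|".join(
            f"{a}:{e}:{i}:{r}"
            for a, e, i, r in zip(
                self.atom_names, self.elements, self.res_ids, self.res_names
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomTable):
            return NotImplemented
        return (
            np.array_equal(self.atom_names, other.atom_names)
            and np.array_equal(self.elements, other.elements)
            and np.array_equal(self.res_ids, other.res_ids)
            and np.array_equal(self.res_names, other.res_names)
        )

    @classmethod
    def from_sequence(cls, sequence: str, cb_only: bool = False,
                      oxt: bool = True) -> "AtomTable":
        """Build the heavy-atom table for a peptide sequence.

        With ``cb_only`` side chains are truncated at CB; otherwise the full
        standard heavy-atom complement is used.  ``oxt`` appends the
        C-terminal carboxylate oxygen.
        """
        names, elements, res_ids, res_names = [], [], [], []
        for i, letter in enumerate(sequence, start=1):
            if letter not in ONE_TO_THREE:
                raise ValueError(f"unknown residue letter {letter!r}")
            res = ONE_TO_THREE[letter]
            atom_list = RESIDUE_HEAVY_ATOMS[res]
            if cb_only:
                atom_list = [a for a in atom_list if a in ("N", "CA", "C", "O", "CB")]
            for atom in atom_list:
                names.append(atom)
                elements.append(element_of_atom(atom, res))
                res_ids.append(i)
                res_names.append(res)
        if oxt:
            names.append("OXT")
            elements.append("O")
            res_ids.append(len(sequence))
            res_names.append(ONE_TO_THREE[sequence[-1]])
        return cls(names, elements, res_ids, res_names)


@dataclass
class Structure:
    """One conformation: an atom table plus ``(n_atoms, 3)`` coordinates in Angstrom."""

    table: AtomTable
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.table.n_atoms, 3):
            raise ValueError(
                f"coordinates shape {self.coords.shape} does not match "
                f"atom table with {self.table.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.table.n_atoms

    @property
    def n_residues(self) -> int:
        return self.table.n_residues

    @property
    def sequence(self) -> str:
        return self.table.sequence

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                str(self.table.atom_names[i]),
                str(self.table.elements[i]),
                int(self.table.res_ids[i]),
                str(self.table.res_names[i]),
                self.coords[i],
            )

    def copy(self) -> "Structure":
        return Structure(self.table, self.coords.copy())


@dataclass
class Ensemble:
    """A frame-indexed stack of conformations sharing one atom table."""

    table: AtomTable
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    frame_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (self.table.n_atoms, 3):
            raise ValueError("ensemble coordinates must have shape (F, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.n_frames)
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        if len(self.frame_ids) != self.n_frames:
            raise ValueError("frame_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.table, self.coords[i])

    def __iter__(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_structures(cls, structures: Sequence[Structure]) -> "Ensemble":
        if not structures:
            raise ValueError("no structures given")
        table = structures[0].table
        for k, s in enumerate(structures[1:], start=2):
            if s.table != table:
                raise ValueError(f"frame {k} has a different atom table")
        return cls(table, np.stack([s.coords for s in structures]))


# ---------------------------------------------------------------------------
# Upper-triangle flattening
# ---------------------------------------------------------------------------
# Fixed global order: row-major over the strict upper triangle, i.e. pairs
# (0,1), (0,2), ..., (0,n-1), (1,2), ..., (n-2,n-1).  Index map:
# k(i,j) = i*n - i*(i+1)/2 + (j - i - 1) for i < j.  This is the same order
# scipy's pdist/squareform use, so the two stages of the pipeline agree.


def flatten_upper(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Flatten a symmetric hollow matrix to its strict upper triangle (row-major)."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=atol):
        raise ValueError("matrix must be symmetric")
    if not np.allclose(np.diagonal(matrix), 0, atol=atol):
        raise ValueError("matrix must have zero diagonal")
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    return np.ascontiguousarray(matrix[iu, ju])


def unflatten_upper(values: np.ndarray, n: int | None = None) -> np.ndarray:
    """Inverse of :func:`flatten_upper`: rebuild the symmetric hollow matrix."""
    values = np.asarray(values)
    if values.ndim != 1:
        raise ValueError("flattened triangle must be one-dimensional")
    if n is None:
        n = triangle_size_to_n(len(values))
    if len(values) != n * (n - 1) // 2:
        raise ValueError(f"length {len(values)} is not n(n-1)/2 for n={n}")
    matrix = np.zeros((n, n), dtype=values.dtype)
    iu, ju = np.triu_indices(n, k=1)
    matrix[iu, ju] = values
    matrix[ju, iu] = values
    return matrix


def triangle_size_to_n(length: int) -> int:
    """Solve n(n-1)/2 = length for n, erroring on non-triangular lengths."""
    n = int(round((1 + np.sqrt(1 + 8 * length)) / 2))
    if n * (n - 1) // 2 != length:
        raise ValueError(f"{length} is not a triangular number")
    return n
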