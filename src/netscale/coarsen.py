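"""Coarse-graining: residue contact networks and heavy-atom distance vectors.

Each conformation is reduced to two flattened upper triangles:

* the binary protein structure network (PSN) adjacency over residues —
  two residues are in contact if any heavy-atom pair sits within
  ``scale`` times the sum of the atoms' van der Waals radii (the boundary
  is inclusive, default scale 1.1);
* the pairwise interatomic distance (PID) vector over all heavy atoms,
  in Angstrom.

The PSN vector is the model input, the PID vector the regression target.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
from scipy.spatial.distance import cdist, pdist

from .atoms import radii_for
from .core import AtomTable, Ensemble, Structure


def build_psn(structure: Structure, table: dict[str, float] | None = None,
              scale: float = 1.1) -> np.ndarray:
    """Binary residue-contact vector (flattened strict upper triangle).

    Bit (i, j) is 1 iff some atom of residue i and some atom of residue j
    lie at distance <= scale * (r_i + r_j), with r the van der Waals radii.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    n_res = structure.n_residues
    if n_res < 2:
        raise ValueError("PSN requires at least two residues")
    radii = radii_for(structure.table.elements, table)
    dist = cdist(structure.coords, structure.coords)
    cut = scale * np.add.outer(radii, radii)
    atom_contact = dist <= cut
    res_ids = structure.table.res_ids
    bits = np.zeros(n_res * (n_res - 1) // 2, dtype=np.uint8)
    groups = [np.flatnonzero(res_ids == r) for r in range(1, n_res + 1)]
    k = 0
    for i in range(n_res):
        gi = groups[i]
        for j in range(i + 1, n_res):
            bits[k] = atom_contact[np.ix_(gi, groups[j])].any()
            k += 1
    return bits


def compute_pid(structure: Structure) -> np.ndarray:
    """Heavy-atom pairwise distances, flattened in the global triangle order."""
    return pdist(structure.coords)


def coarsen_ensemble(ensemble: Ensemble, table: dict[str, float] | None = None,
                     scale: float = 1.1):
    """Per-frame (PSN adjacency, PID) pairs, frame order preserved.

    Returns ``(X, Y)`` with ``X`` of shape (F, R(R-1)/2) uint8 and ``Y``
    of shape (F, N(N-1)/2) float32.
    """
    X = np.stack([build_psn(frame, table, scale) for frame in ensemble])
    Y = np.stack([compute_pid(frame) for frame in ensemble]).astype(np.float32)
    return X, Y


def save_dataset(path: str | Path, X: np.ndarray, Y: np.ndarray,
                 atom_table: AtomTable) -> None:
    """Persist a coarsened dataset to an HDF5 container.

    Datasets ``X`` (frames x R(R-1)/2, uint8) and ``Y``
    (frames x N(N-1)/2, float32) plus atom-table metadata.
    """
    with h5py.File(str(path), "w") as h5:
        h5.create_dataset("X", data=np.asarray(X, dtype=np.uint8))
        h5.create_dataset("Y", data=np.asarray(Y, dtype=np.float32))
        meta = h5.create_group("atom_table")
        str_dt = h5py.string_dtype()
        meta.create_dataset("atom_names", data=list(map(str, atom_table.atom_names)), dtype=str_dt)
        meta.create_dataset("elements", data=list(map(str, atom_table.elements)), dtype=str_dt)
        meta.create_dataset("res_ids", data=atom_table.res_ids)
        meta.create_dataset("res_names", data=list(map(str, atom_table.res_names)), dtype=str_dt)


def load_dataset(path: str | Path):
    """Load ``(X, Y, atom_table)`` written by :func:`save_dataset`."""
    with h5py.File(str(path), "r") as h5:
        X = h5["X"][...]
        Y = h5["Y"][...]
        meta = h5["atom_table"]
        table = AtomTable(
            [s.decode() if isinstance(s, bytes) else str(s) for s in meta["atom_names"][...]],
            [s.decode() if isinstance(s, bytes) else str(s) for s in meta["elements"][...]],
            meta["res_ids"][...],
            [s.decode() if isinstance(s, bytes) else str(s) for s in meta["res_names"][...]],
        )
    return X, Y, table
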