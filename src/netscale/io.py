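"""Multi-model PDB reading and writing (heavy atoms, single chain).

Thin wrappers around biotite's PDB support that enforce the pipeline's
contract: hydrogens are discarded on read, every model must share one atom
table, and residue indices are renumbered to a contiguous 1..R range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .atoms import element_of_atom
from .core import AtomTable, Ensemble


def _model_to_arrays(model: struc.AtomArray):
    """Extract (names, elements, res_ids, res_names, coords) from one model,
    dropping hydrogens and validating the single-chain assumption."""
    chains = np.unique(model.chain_id)
    chains = chains[chains != ""]
    if len(chains) > 1:
        raise ValueError(
            f"multi-chain files are not supported (found chains {list(chains)})"
        )
    elements = []
    for el, name in zip(model.element, model.atom_name):
        el = str(el).strip().upper()
        if not el:
            el = element_of_atom(str(name)).upper()
        elements.append(el)
    elements = np.array(elements, dtype=object)
    heavy = ~np.isin(elements, ("H", "D"))
    names = model.atom_name[heavy].astype(object)
    elements = elements[heavy]
    res_ids_raw = model.res_id[heavy]
    res_names = model.res_name[heavy].astype(object)
    coords = np.asarray(model.coord[heavy], dtype=float)
    # renumber residues contiguously in order of first appearance
    _, first_idx = np.unique(res_ids_raw, return_index=True)
    order = res_ids_raw[np.sort(first_idx)]
    remap = {int(old): new for new, old in enumerate(order, start=1)}
    res_ids = np.array([remap[int(r)] for r in res_ids_raw], dtype=int)
    return names, elements, res_ids, res_names, coords


def read_pdb_ensemble(path: str | Path) -> Ensemble:
    """Read a (multi-)MODEL PDB file into an :class:`Ensemble`.

    Hydrogens are discarded; atom ordering is preserved as in the file.
    Raises a ``ValueError`` naming the first mismatching model if the
    models do not share an identical atom table.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise ValueError(f"{path}: no models found")
    tables, coord_list = [], []
    for m in range(1, n_models + 1):
        model = pdb.get_structure(model=m)
        names, elements, res_ids, res_names, coords = _model_to_arrays(model)
        tables.append((names, elements, res_ids, res_names))
        coord_list.append(coords)
    ref_names, ref_elements, ref_res_ids, ref_res_names = tables[0]
    for m, (names, elements, res_ids, res_names) in enumerate(tables[1:], start=2):
        if len(names) != len(ref_names):
            raise ValueError(
                f"{path}: model {m} has {len(names)} heavy atoms, "
                f"model 1 has {len(ref_names)}"
            )
        for i in range(len(names)):
            if (names[i] != ref_names[i] or elements[i] != ref_elements[i]
                    or res_ids[i] != ref_res_ids[i]
                    or res_names[i] != ref_res_names[i]):
                raise ValueError(
                    f"{path}: model {m} atom {i + 1} "
                    f"({res_names[i]}{res_ids[i]}:{names[i]}) does not match "
                    f"model 1 ({ref_res_names[i]}{ref_res_ids[i]}:{ref_names[i]})"
                )
    table = AtomTable(ref_names, ref_elements, ref_res_ids, ref_res_names)
    return Ensemble(table, np.stack(coord_list))


def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an :class:`Ensemble` as a standard multi-MODEL PDB file."""
    limit = 9999.999
    if np.any(np.abs(ensemble.coords) > limit):
        raise ValueError("coordinates exceed the PDB fixed-point field range")
    table = ensemble.table
    array = struc.AtomArray(table.n_atoms)
    array.atom_name = np.array([str(a) for a in table.atom_names], dtype="U6")
    array.element = np.array([str(e) for e in table.elements], dtype="U2")
    array.res_id = table.res_ids.astype(int)
    array.res_name = np.array([str(r) for r in table.res_names], dtype="U5")
    array.chain_id = np.full(table.n_atoms, "A", dtype="U4")
    array.hetero = np.zeros(table.n_atoms, dtype=bool)
    stack = struc.from_template(array, ensemble.coords.astype(np.float32))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
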