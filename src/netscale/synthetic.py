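"""Synthetic peptide conformational ensembles with transient secondary structure.

The generator emulates the training regime of a disordered-peptide MD
trajectory: many frames of one sequence, each frame sampling per-residue
backbone dihedrals from one of a small number of metastable state
patterns (helix / extended basins) with stochastic per-residue switching,
plus optional Cartesian noise.  Side chains are truncated at CB so the
full pipeline trains in minutes at desk scale, while remaining all-L and
clash-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atoms import ABETA40_SEQUENCE, radii_for
from .coarsen import coarsen_ensemble, save_dataset
from .core import AtomTable, Ensemble, Structure
from .geometry import (
    CB_DIHEDRAL_DEG,
    IDEAL_ANGLES_DEG,
    IDEAL_BOND_LENGTHS,
    Topology,
    place_atom,
)
from .neural import split_frames

#: Default peptide: the 20 N-terminal residues of amyloid-beta 1-40.
DEFAULT_SEQUENCE = ABETA40_SEQUENCE[:20]

#: (phi, psi) basin means in degrees, per conformational state.
STATE_BASINS = {
    "H": (-63.0, -42.0),   # alpha helix
    "E": (-120.0, 135.0),  # extended / beta
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic ensemble generator."""

    sequence: str = DEFAULT_SEQUENCE
    n_frames: int = 500
    basin_sigma_deg: float = 8.0
    switch_prob: float = 0.05
    frame_modes: int = 2
    coord_noise_sigma: float = 0.1
    seed: int = 0
    clash_scale: float = 0.7
    max_retries: int = 50
    basins: dict = field(default_factory=lambda: dict(STATE_BASINS))

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        if self.basin_sigma_deg < 0 or self.coord_noise_sigma < 0:
            raise ValueError("sigmas must be non-negative")


def build_backbone(sequence: str, phi_psi_list) -> Structure:
    """Construct a CB-truncated peptide from per-residue (phi, psi) pairs.

    N, CA, C, O (and CB, plus a C-terminal OXT) are placed by sequential
    internal-coordinate (NeRF) construction with ideal trans-peptide
    geometry (omega = 180 deg).  CB placement enforces the L
    configuration.  Deterministic.
    """
    phi_psi = np.asarray(phi_psi_list, dtype=float)
    if phi_psi.shape != (len(sequence), 2):
        raise ValueError("need one (phi, psi) pair per residue")
    table = AtomTable.from_sequence(sequence, cb_only=True, oxt=True)
    coords = np.zeros((table.n_atoms, 3))

    b_n_ca = IDEAL_BOND_LENGTHS[("N", "CA")]
    b_ca_c = IDEAL_BOND_LENGTHS[("CA", "C")]
    b_c_o = IDEAL_BOND_LENGTHS[("C", "O")]
    b_c_n = IDEAL_BOND_LENGTHS[("C", "N")]
    b_ca_cb = IDEAL_BOND_LENGTHS[("CA", "CB")]

    def set_atom(res, name, pos):
        coords[table.atom_index(res, name)] = pos

    def get(res, name):
        return coords[table.atom_index(res, name)]

    # first residue: N at origin, CA on +x, C in the xy-plane
    n1 = np.zeros(3)
    ca1 = np.array([b_n_ca, 0.0, 0.0])
    theta = np.deg2rad(IDEAL_ANGLES_DEG[("N", "CA", "C")])
    c1 = ca1 + b_ca_c * np.array([-np.cos(theta), np.sin(theta), 0.0])
    set_atom(1, "N", n1)
    set_atom(1, "CA", ca1)
    set_atom(1, "C", c1)

    for r in range(2, len(sequence) + 1):
        psi_prev = phi_psi[r - 2, 1]
        phi = phi_psi[r - 1, 0]
        n = place_atom(get(r - 1, "N"), get(r - 1, "CA"), get(r - 1, "C"),
                       b_c_n, IDEAL_ANGLES_DEG[("CA", "C", "N")], psi_prev)
        set_atom(r, "N", n)
        ca = place_atom(get(r - 1, "CA"), get(r - 1, "C"), n,
                        b_n_ca, IDEAL_ANGLES_DEG[("C", "N", "CA")], 180.0)
        set_atom(r, "CA", ca)
        c = place_atom(get(r - 1, "C"), n, ca,
                       b_ca_c, IDEAL_ANGLES_DEG[("N", "CA", "C")], phi)
        set_atom(r, "C", c)

    # carbonyl O, CB and terminal OXT once the backbone exists
    for r in range(1, len(sequence) + 1):
        psi = phi_psi[r - 1, 1]
        o = place_atom(get(r, "N"), get(r, "CA"), get(r, "C"),
                       b_c_o, IDEAL_ANGLES_DEG[("CA", "C", "O")], psi + 180.0)
        set_atom(r, "O", o)
        try:
            cb_idx = table.atom_index(r, "CB")
        except KeyError:
            cb_idx = None  # glycine
        if cb_idx is not None:
            coords[cb_idx] = place_atom(
                get(r, "C"), get(r, "N"), get(r, "CA"),
                b_ca_cb, IDEAL_ANGLES_DEG[("N", "CA", "CB")], CB_DIHEDRAL_DEG,
            )
    last = len(sequence)
    oxt = place_atom(get(last, "N"), get(last, "CA"), get(last, "C"),
                     b_c_o, IDEAL_ANGLES_DEG[("CA", "C", "OXT")],
                     phi_psi[last - 1, 1])
    set_atom(last, "OXT", oxt)
    return Structure(table, coords)


def _clash_count(coords: np.ndarray, pairs: np.ndarray, radii: np.ndarray,
                 scale: float) -> int:
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    cut = scale * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    return int(np.sum(d < cut))


def generate_ensemble(spec: SyntheticSpec) -> Ensemble:
    """Sample an ensemble of clash-free, all-L conformations.

    Per frame: pick a metastable mode, flip each residue's state with
    ``switch_prob``, draw (phi, psi) from the state's Gaussian basin,
    build the backbone and add Cartesian noise.  Frames with any
    nonbonded heavy-atom pair closer than ``clash_scale`` times the vdW
    sum are resampled (bounded retries).  Reproducible under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_res = len(spec.sequence)
    state_names = sorted(spec.basins)
    # Metastable mode patterns: the first len(basins) modes are the uniform
    # states (all-helix, all-extended, ...), which keeps the modes well
    # separated in conformation space; further modes are random mixtures.
    mode_patterns = np.empty((spec.frame_modes, n_res), dtype=int)
    for m in range(spec.frame_modes):
        if m < len(state_names):
            mode_patterns[m] = m
        else:
            mode_patterns[m] = rng.choice(len(state_names), size=n_res)

    table = AtomTable.from_sequence(spec.sequence, cb_only=True, oxt=True)
    topo = Topology(table)
    pairs = topo.nonbonded_pairs()
    radii = radii_for(table.elements)

    frames = np.empty((spec.n_frames, table.n_atoms, 3))
    for f in range(spec.n_frames):
        for attempt in range(spec.max_retries):
            mode = mode_patterns[rng.integers(spec.frame_modes)]
            flip = rng.random(n_res) < spec.switch_prob
            states = (mode + flip) % len(state_names)
            means = np.array(
                [spec.basins[state_names[s]] for s in states], dtype=float
            )
            phi_psi = rng.normal(means, spec.basin_sigma_deg)
            structure = build_backbone(spec.sequence, phi_psi)
            coords = structure.coords
            if spec.coord_noise_sigma > 0:
                coords = coords + rng.normal(
                    0.0, spec.coord_noise_sigma, coords.shape
                )
            if _clash_count(coords, pairs, radii, spec.clash_scale) == 0:
                frames[f] = coords
                break
        else:
            raise RuntimeError(
                f"frame {f}: clash rejection failed after "
                f"{spec.max_retries} retries; relax basin or noise parameters"
            )
    return Ensemble(table, frames)


def make_training_fixture(spec: SyntheticSpec, path=None,
                          fractions=(0.72, 0.08, 0.20), scale: float = 1.1):
    """Generate, coarsen and split a training dataset in one call.

    Returns ``(ensemble, X, Y, split)``; if *path* is given the arrays are
    also persisted in the pipeline's HDF5 container format.
    """
    ensemble = generate_ensemble(spec)
    X, Y = coarsen_ensemble(ensemble, scale=scale)
    split = split_frames(ensemble.n_frames, fractions=fractions, seed=spec.seed)
    if path is not None:
        save_dataset(path, X, Y, ensemble.table)
    return ensemble, X, Y, split
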