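"""Reconstruction: distance matrix -> 3D coordinates -> stereochemical repair
-> steric relaxation.

A predicted PID vector is embedded into 3D by classical multidimensional
scaling (exact for true Euclidean distance matrices), optionally refined
by stress majorization.  Because a distance matrix is blind to handedness
the embedding can come out mirror-imaged: chirality of every alpha carbon
is assessed from the signed volume of its substituents, a global
reflection is applied when R centers outnumber S centers, remaining
isolated D residues have their side chains reflected through the local
backbone plane, and the result is relaxed by conjugate-gradient descent
on a minimal steric potential (bonds, angles, soft vdW repulsion, tether
to the input coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.manifold import smacof
from scipy.spatial.distance import pdist

from .atoms import radii_for
from .core import AtomTable, Structure, triangle_size_to_n, unflatten_upper
from .geometry import Topology
from . import metrics as _metrics

#: Sign of the chirality triple product chi = (N-CA).[(C-CA)x(CB-CA)] for an
#: S-configured (L) alpha carbon.  Calibrated once against an ideal
#: L-alanine fixture and frozen; the calibration is locked by a test.
S_CHI_SIGN = 1.0

BACKBONE_NAMES = ("N", "CA", "C", "O", "OXT")


# ---------------------------------------------------------------------------
# MDS embedding
# ---------------------------------------------------------------------------

def _stress(coords: np.ndarray, target: np.ndarray) -> float:
    """Raw stress: sum of squared differences between realised and target
    pairwise distances."""
    return float(np.sum((pdist(coords) - target) ** 2))


def embed_mds(pid: np.ndarray, n_atoms: int | None = None,
              refine: bool = True, seed: int = 0):
    """Embed a flattened distance vector into 3D coordinates.

    Stage 1 is classical (Torgerson) scaling: eigendecomposition of the
    double-centered squared-distance matrix, top three components.  Stage
    2 (``refine``) polishes by metric stress majorization (SMACOF)
    initialised from stage 1, which keeps the result deterministic and
    never increases the stress.  Returns ``(coords, stress)``.
    """
    pid = np.asarray(pid, dtype=float)
    if n_atoms is None:
        n_atoms = triangle_size_to_n(len(pid))
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms for a 3D embedding")
    if not np.all(np.isfinite(pid)):
        raise ValueError("non-finite distances in PID vector")
    if np.any(pid <= 0):
        raise ValueError("PID entries must be positive")
    D = unflatten_upper(pid, n_atoms)
    D2 = D ** 2
    J = np.eye(n_atoms) - np.full((n_atoms, n_atoms), 1.0 / n_atoms)
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    top = np.argsort(eigvals)[::-1][:3]
    lam = np.clip(eigvals[top], 0.0, None)
    coords = eigvecs[:, top] * np.sqrt(lam)
    stress = _stress(coords, pid)
    if refine:
        refined, _ = smacof(
            D, metric=True, n_components=3, init=coords, n_init=1,
            max_iter=300, eps=1e-9, random_state=seed, normalized_stress=False,
        )
        refined_stress = _stress(refined, pid)
        if refined_stress <= stress:
            coords, stress = refined, refined_stress
    return coords, stress


# ---------------------------------------------------------------------------
# Chirality
# ---------------------------------------------------------------------------

@dataclass
class ChiralityReport:
    """Per-residue R/S labels of the alpha carbons and the aggregate RS ratio.

    Residues without a CB (glycine) are labeled ``undefined`` and excluded
    from the counts.  An RS ratio above 1 signals a globally mirrored
    reconstruction (natural proteins are essentially all-S).
    """

    per_residue: dict = field(default_factory=dict)

    @property
    def n_R(self) -> int:
        return sum(1 for v in self.per_residue.values() if v == "R")

    @property
    def n_S(self) -> int:
        return sum(1 for v in self.per_residue.values() if v == "S")

    @property
    def rs_ratio(self) -> float:
        if self.n_S == 0:
            return float("inf") if self.n_R > 0 else 0.0
        return self.n_R / self.n_S


def assign_chirality(structure: Structure) -> ChiralityReport:
    """Label every alpha carbon R or S from the signed substituent volume.

    chi = (r_N - r_CA) . [(r_C - r_CA) x (r_CB - r_CA)]; the sign-to-label
    mapping is the frozen :data:`S_CHI_SIGN` calibration.  Residues
    lacking CB are ``undefined``.
    """
    report = ChiralityReport()
    table = structure.table
    for r in range(1, table.n_residues + 1):
        try:
            n = structure.coords[table.atom_index(r, "N")]
            ca = structure.coords[table.atom_index(r, "CA")]
            c = structure.coords[table.atom_index(r, "C")]
        except KeyError as exc:
            raise ValueError(f"residue {r} is missing a backbone atom: {exc}")
        try:
            cb = structure.coords[table.atom_index(r, "CB")]
        except KeyError:
            report.per_residue[r] = "undefined"
            continue
        chi = np.dot(n - ca, np.cross(c - ca, cb - ca))
        if chi == 0.0:
            report.per_residue[r] = "undefined"
        else:
            report.per_residue[r] = "S" if np.sign(chi) == S_CHI_SIGN else "R"
    return report


def correct_global_reflection(structure: Structure, report: ChiralityReport):
    """Undo a mirror-imaged embedding when R centers dominate.

    If the RS ratio exceeds 1, one coordinate axis is negated (an improper
    transform, equivalent to any planar reflection up to rotation) and the
    report recomputed; otherwise the structure is returned unchanged.
    Returns ``(structure, report)``.
    """
    if report.rs_ratio > 1:
        coords = structure.coords.copy()
        coords[:, 1] *= -1.0
        fixed = Structure(structure.table, coords)
        return fixed, assign_chirality(fixed)
    return structure, report


def correct_local_chirality(structure: Structure, report: ChiralityReport):
    """Fix isolated D residues by reflecting their side chains.

    Requires ``rs_ratio <= 1`` (global reflection already handled).  For
    every R-labeled residue, all side-chain atoms (CB and beyond) are
    reflected through the plane containing that residue's N, CA and C;
    backbone atoms never move.  Returns ``(structure, report)`` with the
    recomputed report, and errors if any R center survives (degenerate
    geometry).
    """
    if report.rs_ratio > 1:
        raise ValueError("global reflection must be applied before local fixes")
    bad = [r for r, lab in report.per_residue.items() if lab == "R"]
    if not bad:
        return structure, report
    table = structure.table
    coords = structure.coords.copy()
    for r in bad:
        n = coords[table.atom_index(r, "N")]
        ca = coords[table.atom_index(r, "CA")]
        c = coords[table.atom_index(r, "C")]
        normal = np.cross(n - ca, c - ca)
        norm = np.linalg.norm(normal)
        if norm < 1e-10:
            raise ValueError(f"residue {r}: degenerate N-CA-C plane")
        normal /= norm
        for idx in table.residue_atom_indices(r):
            if str(table.atom_names[idx]) in BACKBONE_NAMES:
                continue
            x = coords[idx]
            coords[idx] = x - 2.0 * np.dot(x - ca, normal) * normal
    fixed = Structure(table, coords)
    new_report = assign_chirality(fixed)
    if new_report.n_R != 0:
        raise ValueError(
            "local chirality correction failed to remove all R centers "
            "(degenerate geometry)"
        )
    return fixed, new_report


# ---------------------------------------------------------------------------
# Steric minimisation
# ---------------------------------------------------------------------------

@dataclass
class MinimizerConfig:
    """Conjugate-gradient relaxation parameters.

    Force constants are in arbitrary energy units per square Angstrom
    (bonds, repulsion, tether) or per square radian (angles); the
    defaults remove steric clashes without distorting the topology.
    """

    steps: int = 75
    bond_k: float = 300.0
    angle_k: float = 50.0
    repulsion_k: float = 25.0
    repulsion_scale: float = 0.85
    tether_k: float = 1.0
    gtol: float = 1e-8
    clash_scale: float = 0.7
    extension_increment: int = 5
    max_extension_steps: int = 100

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        for name in ("bond_k", "angle_k", "repulsion_k", "tether_k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class _StericPotential:
    """E = sum_b k_b (d-d0)^2 + sum_a k_a (th-th0)^2
         + sum_nb k_r (s(ri+rj) - d)^2 [d < s(ri+rj)]
         + k_t sum |x - x_in|^2"""

    def __init__(self, table: AtomTable, config: MinimizerConfig,
                 x_input: np.ndarray, radius_table=None):
        self.cfg = config
        topo = Topology(table)
        self.bond_idx = np.array([(i, j) for i, j, _ in topo.bonds], dtype=int)
        self.bond_d0 = np.array([d0 for _, _, d0 in topo.bonds])
        self.angles = topo.angles
        self.nb_pairs = topo.nonbonded_pairs()
        radii = radii_for(table.elements, radius_table)
        self.nb_cut = config.repulsion_scale * (
            radii[self.nb_pairs[:, 0]] + radii[self.nb_pairs[:, 1]]
        )
        self.clash_cut = config.clash_scale * (
            radii[self.nb_pairs[:, 0]] + radii[self.nb_pairs[:, 1]]
        )
        self.x_input = x_input.copy()

    def clash_count(self, coords: np.ndarray) -> int:
        d = np.linalg.norm(
            coords[self.nb_pairs[:, 0]] - coords[self.nb_pairs[:, 1]], axis=1
        )
        return int(np.sum(d < self.clash_cut))

    def energy_grad(self, coords: np.ndarray):
        cfg = self.cfg
        grad = np.zeros_like(coords)
        energy = 0.0
        # bonds
        if len(self.bond_idx):
            i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
            dvec = coords[i] - coords[j]
            d = np.linalg.norm(dvec, axis=1)
            dd = d - self.bond_d0
            energy += cfg.bond_k * np.sum(dd ** 2)
            f = (2.0 * cfg.bond_k * dd / np.maximum(d, 1e-12))[:, None] * dvec
            np.add.at(grad, i, f)
            np.add.at(grad, j, -f)
        # angles
        for ia, ja, ka, theta0 in self.angles:
            u = coords[ia] - coords[ja]
            v = coords[ka] - coords[ja]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-9 or nv < 1e-9:
                continue
            uh, vh = u / nu, v / nv
            cos_t = np.clip(np.dot(uh, vh), -1.0, 1.0)
            sin_t = np.sqrt(max(1.0 - cos_t ** 2, 1e-12))
            theta = np.arccos(cos_t)
            dE = 2.0 * cfg.angle_k * (theta - theta0)
            energy += cfg.angle_k * (theta - theta0) ** 2
            dth_di = (cos_t * uh - vh) / (nu * sin_t)
            dth_dk = (cos_t * vh - uh) / (nv * sin_t)
            grad[ia] += dE * dth_di
            grad[ka] += dE * dth_dk
            grad[ja] -= dE * (dth_di + dth_dk)
        # soft repulsion
        if len(self.nb_pairs):
            i, j = self.nb_pairs[:, 0], self.nb_pairs[:, 1]
            dvec = coords[i] - coords[j]
            d = np.linalg.norm(dvec, axis=1)
            overlap = self.nb_cut - d
            active = overlap > 0
            if active.any():
                ov = overlap[active]
                energy += cfg.repulsion_k * np.sum(ov ** 2)
                f = (-2.0 * cfg.repulsion_k * ov
                     / np.maximum(d[active], 1e-12))[:, None] * dvec[active]
                np.add.at(grad, i[active], f)
                np.add.at(grad, j[active], -f)
        # tether
        if cfg.tether_k > 0:
            diff = coords - self.x_input
            energy += cfg.tether_k * np.sum(diff ** 2)
            grad += 2.0 * cfg.tether_k * diff
        return energy, grad


def _cg_descent(potential: _StericPotential, coords: np.ndarray, steps: int,
                gtol: float, snapshot_interval: int | None = None):
    """Polak-Ribiere conjugate gradient with backtracking (Armijo) line
    search.  Returns (coords, energy_trace, snapshots)."""
    x = coords.copy()
    energy, grad = potential.energy_grad(x)
    trace = [energy]
    snapshots = {0: x.copy()}
    direction = -grad
    alpha = 1e-3
    for step in range(1, steps + 1):
        gnorm = np.linalg.norm(grad)
        if gnorm < gtol:
            break
        slope = float(np.sum(grad * direction))
        if slope >= 0:  # reset to steepest descent
            direction = -grad
            slope = -gnorm ** 2
        # backtracking line search, growing the initial trial step
        alpha = min(alpha * 2.0, 1.0)
        accepted = False
        for _ in range(60):
            x_new = x + alpha * direction
            e_new, g_new = potential.energy_grad(x_new)
            if e_new <= energy + 1e-4 * alpha * slope:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        beta = max(0.0, float(np.sum(g_new * (g_new - grad)) / max(gnorm ** 2, 1e-300)))
        direction = -g_new + beta * direction
        x, energy, grad = x_new, e_new, g_new
        trace.append(energy)
        if snapshot_interval and step % snapshot_interval == 0:
            snapshots[step] = x.copy()
    return x, np.array(trace), snapshots


def minimize(structure: Structure, config: MinimizerConfig | None = None,
             table=None):
    """Relax a structure by conjugate-gradient descent on the steric potential.

    Runs exactly ``config.steps`` iterations unless the gradient norm
    drops below tolerance (or no descent step can be found) earlier.  The
    energy trace is monotone non-increasing.  Returns
    ``(structure, energy_trace)``.
    """
    config = config or MinimizerConfig()
    potential = _StericPotential(structure.table, config, structure.coords, table)
    x, trace, _ = _cg_descent(potential, structure.coords, config.steps, config.gtol)
    return Structure(structure.table, x), trace


def minimize_until_clash_free(structure: Structure,
                              config: MinimizerConfig | None = None,
                              table=None):
    """Minimize for the configured steps, then extend in small increments
    while steric clashes (pairs closer than ``clash_scale`` times the vdW
    sum) remain, up to ``max_extension_steps`` extra steps.

    Returns ``(structure, energy_trace, extra_steps)``.
    """
    config = config or MinimizerConfig()
    potential = _StericPotential(structure.table, config, structure.coords, table)
    x, trace, _ = _cg_descent(potential, structure.coords, config.steps, config.gtol)
    extra = 0
    while (potential.clash_count(x) > 0
           and extra < config.max_extension_steps):
        x, more, _ = _cg_descent(potential, x, config.extension_increment,
                                 config.gtol)
        trace = np.concatenate([trace, more[1:]])
        extra += config.extension_increment
        if len(more) <= 1:  # no further descent possible
            break
    return Structure(structure.table, x), trace, extra


def clash_count(structure: Structure, scale: float = 0.7, table=None) -> int:
    """Number of nonbonded heavy-atom pairs closer than scale*(r_i+r_j)."""
    topo = Topology(structure.table)
    pairs = topo.nonbonded_pairs()
    radii = radii_for(structure.table.elements, table)
    d = np.linalg.norm(
        structure.coords[pairs[:, 0]] - structure.coords[pairs[:, 1]], axis=1
    )
    return int(np.sum(d < scale * (radii[pairs[:, 0]] + radii[pairs[:, 1]])))


def minimization_sweep(structure: Structure, reference: Structure,
                       config: MinimizerConfig | None = None,
                       max_steps: int = 520, interval: int = 20):
    """Score checkpoints along one minimisation run.

    Minimizes for ``max_steps`` conjugate-gradient steps, snapshotting
    every ``interval`` steps (checkpoint 0 included), and evaluates RMSD,
    TM-score, GDT_TS and LDDT against *reference* at every checkpoint.
    Returns ``(rows, best_steps)`` where *rows* is a list of dicts keyed
    by step and metric and *best_steps* maps each metric to its optimal
    checkpoint.
    """
    config = config or MinimizerConfig()
    potential = _StericPotential(structure.table, config, structure.coords)
    _, trace, snapshots = _cg_descent(
        potential, structure.coords, max_steps, config.gtol,
        snapshot_interval=interval,
    )
    rows = []
    for step in range(0, max_steps + 1, interval):
        # descent may terminate early; later checkpoints repeat the final state
        snap = snapshots.get(step)
        if snap is None:
            snap = snapshots[max(snapshots)]
        model = Structure(structure.table, snap)
        rows.append({
            "step": step,
            "rmsd": _metrics.kabsch_rmsd(reference, model),
            "tm": _metrics.tm_score(reference, model),
            "gdt_ts": _metrics.gdt_ts(reference, model),
            "lddt": _metrics.lddt(reference, model),
            "energy": float(trace[min(step, len(trace) - 1)]),
        })
    best_steps = {
        "rmsd": min(rows, key=lambda r: r["rmsd"])["step"],
        "tm": max(rows, key=lambda r: r["tm"])["step"],
        "gdt_ts": max(rows, key=lambda r: r["gdt_ts"])["step"],
        "lddt": max(rows, key=lambda r: r["lddt"])["step"],
    }
    return rows, best_steps


# ---------------------------------------------------------------------------
# Full per-frame rebuild
# ---------------------------------------------------------------------------

def rebuild_frame(pid: np.ndarray, atom_table: AtomTable,
                  minimizer: MinimizerConfig | None = None,
                  refine_mds: bool = True, seed: int = 0,
                  radius_table=None):
    """Reconstruct one structure from a (predicted) PID vector.

    Composition: MDS embedding -> chirality assessment -> global
    reflection -> local side-chain fixes -> clash-free minimisation.
    Returns ``(structure, log)`` where *log* records one entry per stage.
    """
    log = []
    n_atoms = atom_table.n_atoms
    if len(pid) != n_atoms * (n_atoms - 1) // 2:
        raise ValueError("PID length does not match the atom table")
    try:
        coords, stress = embed_mds(pid, n_atoms, refine=refine_mds, seed=seed)
        log.append({"stage": "embed_mds", "stress": stress})
        structure = Structure(atom_table, coords)
        report = assign_chirality(structure)
        log.append({"stage": "assign_chirality", "n_R": report.n_R,
                    "n_S": report.n_S, "rs_ratio": report.rs_ratio})
        structure, report = correct_global_reflection(structure, report)
        log.append({"stage": "correct_global_reflection",
                    "rs_ratio": report.rs_ratio})
        structure, report = correct_local_chirality(structure, report)
        log.append({"stage": "correct_local_chirality", "n_R": report.n_R})
        structure, trace, extra = minimize_until_clash_free(
            structure, minimizer, radius_table
        )
        log.append({"stage": "minimize", "initial_energy": float(trace[0]),
                    "final_energy": float(trace[-1]), "extra_steps": extra})
        # The steric potential is achiral, so relaxing a badly distorted
        # residue can flip its alpha carbon; re-check and re-correct until
        # the all-S guarantee holds.
        cfg = minimizer or MinimizerConfig()
        for retry in range(3):
            report = assign_chirality(structure)
            if report.n_R == 0:
                break
            structure, report = correct_global_reflection(structure, report)
            structure, report = correct_local_chirality(structure, report)
            touchup = replace(cfg, steps=cfg.extension_increment)
            structure, more, _ = minimize_until_clash_free(
                structure, touchup, radius_table
            )
            log.append({"stage": f"chirality_touchup_{retry + 1}",
                        "final_energy": float(more[-1])})
        report = assign_chirality(structure)
        if report.n_R > 0:
            # final correction without further relaxation: guarantees all-S
            structure, report = correct_local_chirality(structure, report)
            log.append({"stage": "final_chirality_fix", "n_R": report.n_R})
    except Exception as exc:
        stage = log[-1]["stage"] if log else "embed_mds"
        raise RuntimeError(f"rebuild failed after stage {stage!r}: {exc}") from exc
    return structure, log


def rebuild_frames(pids, atom_table: AtomTable, **kwargs):
    """Rebuild a batch of PID vectors; order preserved."""
    results = [rebuild_frame(p, atom_table, **kwargs) for p in pids]
    return [s for s, _ in results], [l for _, l in results]
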