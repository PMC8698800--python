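"""Distance-space error metrics and 3D structure-comparison scores.

PID errors (RMSE / MAE / MAPE) compare flattened distance vectors
directly, with no superposition.  The 3D scores are all-heavy-atom RMSD
after Kabsch superposition (proper rotations only, so mirror-image errors
stay visible), TM-score and GDT_TS over C-alpha atoms using a
fragment-seed iterative superposition search, and the superposition-free
LDDT over heavy-atom pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .core import Ensemble, Structure


# ---------------------------------------------------------------------------
# PID-space errors
# ---------------------------------------------------------------------------

@dataclass
class PIDErrorReport:
    rmse: float
    mae: float
    mape: float  # percent
    diff_histogram: tuple  # (counts, bin_edges) over |y - y_hat|


def pid_errors(y_true, y_pred, bin_edges=None) -> PIDErrorReport:
    """RMSE, MAE and MAPE between two flattened distance vectors (Angstrom).

    MAPE is reported in percent, relative to the true distances.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("PID vectors have different lengths")
    if np.any(y_true <= 0):
        raise ValueError("true distances must be positive")
    diff = np.abs(y_true - y_pred)
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 5.0, 21)
    counts, edges = np.histogram(diff, bins=bin_edges)
    return PIDErrorReport(
        rmse=float(np.sqrt(np.mean(diff ** 2))),
        mae=float(np.mean(diff)),
        mape=float(100.0 * np.mean(diff / y_true)),
        diff_histogram=(counts, edges),
    )


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(ref_xyz: np.ndarray, mob_xyz: np.ndarray):
    """Least-squares optimal proper rotation and translation.

    Returns ``(rotation, translation)`` mapping *mob_xyz* onto *ref_xyz*;
    reflections are never absorbed (the determinant is constrained to +1).
    """
    ref_xyz = np.asarray(ref_xyz, dtype=float)
    mob_xyz = np.asarray(mob_xyz, dtype=float)
    if ref_xyz.shape != mob_xyz.shape or ref_xyz.shape[0] < 3:
        raise ValueError("need two matched sets of at least 3 points")
    ref_c = ref_xyz.mean(axis=0)
    mob_c = mob_xyz.mean(axis=0)
    H = (mob_xyz - mob_c).T @ (ref_xyz - ref_c)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    t = ref_c - R @ mob_c
    return R, t


def _apply(R, t, xyz):
    return xyz @ R.T + t


def kabsch_rmsd(ref: Structure, model: Structure, atom_subset=None) -> float:
    """All-heavy-atom RMSD after optimal proper superposition (Angstrom)."""
    if ref.table != model.table:
        raise ValueError("structures have different atom tables")
    idx = np.arange(ref.n_atoms) if atom_subset is None else np.asarray(atom_subset)
    if len(idx) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    R, t = kabsch_superpose(ref.coords[idx], model.coords[idx])
    moved = _apply(R, t, model.coords[idx])
    return float(np.sqrt(np.mean(np.sum((moved - ref.coords[idx]) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Fragment-seed superposition search (TM-score, GDT_TS)
# ---------------------------------------------------------------------------

def _ca_coords(structure: Structure) -> np.ndarray:
    mask = structure.table.atom_names == "CA"
    ca = structure.coords[mask]
    if len(ca) != structure.n_residues:
        raise ValueError("structure lacks one CA per residue")
    return ca

_SEED_LENGTHS = (3, 5, 7)


def _seed_superpositions(ref_ca, mob_ca):
    """Yield (R, t) from every contiguous fragment seed plus the full chain."""
    L = len(ref_ca)
    lengths = [l for l in _SEED_LENGTHS if l <= L] + [L]
    for length in lengths:
        for start in range(0, L - length + 1):
            sl = slice(start, start + length)
            yield kabsch_superpose(ref_ca[sl], mob_ca[sl])


def _iterative_refine(ref_ca, mob_ca, R, t, cutoff, max_iter=20):
    """Re-superpose on the residues currently within *cutoff* until stable."""
    prev = None
    for _ in range(max_iter):
        d = np.linalg.norm(_apply(R, t, mob_ca) - ref_ca, axis=1)
        subset = np.flatnonzero(d < cutoff)
        if len(subset) < 3:
            break
        if prev is not None and np.array_equal(subset, prev):
            break
        prev = subset
        R, t = kabsch_superpose(ref_ca[subset], mob_ca[subset])
    return R, t


def tm_score(ref: Structure, model: Structure) -> float:
    """Template-modeling score over C-alpha atoms, normalized by reference length.

    The superposition is searched by iterative extension from contiguous
    fragment seeds; 1.0 means identical backbones, values near 0 mean
    dissimilar ones.
    """
    ref_ca = _ca_coords(ref)
    mob_ca = _ca_coords(model)
    if len(ref_ca) != len(mob_ca):
        raise ValueError("residue-count mismatch")
    L = len(ref_ca)
    d0 = 1.24 * np.cbrt(L - 15) - 1.8 if L > 15 else 0.5
    d0 = max(d0, 0.5)
    best = 0.0
    for R, t in _seed_superpositions(ref_ca, mob_ca):
        R, t = _iterative_refine(ref_ca, mob_ca, R, t, cutoff=max(d0, 1.0))
        d = np.linalg.norm(_apply(R, t, mob_ca) - ref_ca, axis=1)
        best = max(best, float(np.mean(1.0 / (1.0 + (d / d0) ** 2))))
    return best


def gdt_ts(ref: Structure, model: Structure) -> float:
    """Global distance test (total score) over C-alpha atoms, in [0, 1].

    Mean over the 1, 2, 4 and 8 Angstrom cutoffs of the maximal fraction
    of C-alpha atoms superposable within the cutoff, searched over
    fragment seeds with iterative refinement.
    """
    ref_ca = _ca_coords(ref)
    mob_ca = _ca_coords(model)
    if len(ref_ca) != len(mob_ca):
        raise ValueError("residue-count mismatch")
    L = len(ref_ca)
    cutoffs = (1.0, 2.0, 4.0, 8.0)
    best = {c: 0.0 for c in cutoffs}
    for R0, t0 in _seed_superpositions(ref_ca, mob_ca):
        for c in cutoffs:
            R, t = _iterative_refine(ref_ca, mob_ca, R0, t0, cutoff=c)
            d = np.linalg.norm(_apply(R, t, mob_ca) - ref_ca, axis=1)
            best[c] = max(best[c], float(np.mean(d < c)))
    return float(np.mean([best[c] for c in cutoffs]))


# ---------------------------------------------------------------------------
# LDDT
# ---------------------------------------------------------------------------

def lddt(ref: Structure, model: Structure, radius: float = 15.0,
         thresholds=(0.5, 1.0, 2.0, 4.0)) -> float:
    """Local distance difference test over heavy-atom pairs, in [0, 1].

    Considers every heavy-atom pair in different residues whose reference
    distance is below *radius*; scores the fraction preserved within each
    threshold and averages over thresholds.  Superposition-free.
    """
    if ref.table != model.table:
        raise ValueError("structures have different atom tables")
    d_ref = pdist(ref.coords)
    d_mod = pdist(model.coords)
    res = ref.table.res_ids
    iu, ju = np.triu_indices(ref.n_atoms, k=1)
    mask = (res[iu] != res[ju]) & (d_ref < radius)
    if not mask.any():
        raise ValueError("no qualifying atom pairs within the inclusion radius")
    delta = np.abs(d_ref[mask] - d_mod[mask])
    return float(np.mean([np.mean(delta < t) for t in thresholds]))


# ---------------------------------------------------------------------------
# Ensemble scoring
# ---------------------------------------------------------------------------

@dataclass
class StructureScoreReport:
    rmsd: float
    tm: float
    gdt_ts: float
    lddt: float


def score_structures(ref: Structure, model: Structure) -> StructureScoreReport:
    return StructureScoreReport(
        rmsd=kabsch_rmsd(ref, model),
        tm=tm_score(ref, model),
        gdt_ts=gdt_ts(ref, model),
        lddt=lddt(ref, model),
    )


def score_ensemble(refs: Ensemble, models: Ensemble):
    """Per-frame structure scores plus mean and normal-approximation 95% CI.

    Returns ``(per_frame, summary)`` where *per_frame* is a list of
    :class:`StructureScoreReport` and *summary* maps each metric to a dict
    with ``mean``, ``ci_low``, ``ci_high`` and ``n``.  With a single frame
    the CI degenerates to the point value and is flagged.
    """
    if refs.n_frames != models.n_frames:
        raise ValueError("ensembles have different frame counts")
    per_frame = [
        score_structures(refs.frame(i), models.frame(i))
        for i in range(refs.n_frames)
    ]
    summary = {}
    for metric in ("rmsd", "tm", "gdt_ts", "lddt"):
        vals = np.array([getattr(r, metric) for r in per_frame])
        n = len(vals)
        mean = float(vals.mean())
        if n > 1:
            sem = float(vals.std(ddof=1) / np.sqrt(n))
            summary[metric] = {
                "mean": mean, "ci_low": mean - 1.96 * sem,
                "ci_high": mean + 1.96 * sem, "n": n, "degenerate": False,
            }
        else:
            summary[metric] = {
                "mean": mean, "ci_low": mean, "ci_high": mean,
                "n": n, "degenerate": True,
            }
    return per_frame, summary
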