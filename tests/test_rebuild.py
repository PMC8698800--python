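"""MDS embedding, chirality repair and steric minimisation."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from netscale import (
    MinimizerConfig,
    Structure,
    assign_chirality,
    build_backbone,
    clash_count,
    compute_pid,
    correct_global_reflection,
    correct_local_chirality,
    embed_mds,
    kabsch_rmsd,
    minimization_sweep,
    minimize,
    minimize_until_clash_free,
    rebuild_frame,
    rebuild_frames,
)

from conftest import HELIX


def _mirror(structure):
    return Structure(structure.table, structure.coords * [-1.0, 1.0, 1.0])


class TestEmbedMDS:
    def test_exact_recovery_from_true_pid(self, small_ensemble):
        for i in range(3):
            frame = small_ensemble.frame(i)
            pid = compute_pid(frame)
            coords, stress = embed_mds(pid)
            assert np.abs(pdist(coords) - pid).max() < 1e-6
            assert stress < 1e-10

    def test_regular_tetrahedron(self):
        coords, _ = embed_mds(np.ones(6), 4)
        assert np.allclose(pdist(coords), 1.0, atol=1e-9)

    def test_refinement_never_worsens_stress(self, small_ensemble):
        frame = small_ensemble.frame(0)
        rng = np.random.default_rng(6)
        noisy = np.clip(compute_pid(frame) + rng.normal(0, 0.2, frame.n_atoms * (frame.n_atoms - 1) // 2), 0.3, None)
        _, stress_classical = embed_mds(noisy, refine=False)
        _, stress_refined = embed_mds(noisy, refine=True)
        assert stress_refined <= stress_classical

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            embed_mds(np.array([1.0, 1.0, 1.0]), 3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            embed_mds(np.array([1.0, np.nan] + [1.0] * 4), 4)


class TestChirality:
    def test_ideal_all_L_decapeptide(self, helix10):
        report = assign_chirality(helix10)
        assert report.n_R == 0
        assert report.rs_ratio == 0.0

    def test_mirror_flips_every_label(self, helix10):
        report = assign_chirality(_mirror(helix10))
        assert report.n_S == 0
        assert report.n_R == 10  # no glycine in this sequence
        assert report.rs_ratio == float("inf")
        assert report.rs_ratio > 1

    def test_glycine_undefined_and_excluded(self):
        s = build_backbone("AGA", [HELIX] * 3)
        report = assign_chirality(s)
        assert report.per_residue[2] == "undefined"
        assert report.n_R + report.n_S == 2

    def test_single_cb_reflection_flips_one_label(self, helix10):
        coords = helix10.coords.copy()
        table = helix10.table
        r = 5
        n, ca, c = (coords[table.atom_index(r, a)] for a in ("N", "CA", "C"))
        normal = np.cross(n - ca, c - ca)
        normal /= np.linalg.norm(normal)
        cb_idx = table.atom_index(r, "CB")
        coords[cb_idx] -= 2 * np.dot(coords[cb_idx] - ca, normal) * normal
        report = assign_chirality(Structure(table, coords))
        assert report.per_residue[r] == "R"
        assert report.n_R == 1


class TestChiralitySignCalibration:
    def test_frozen_sign_matches_cip_assignment(self):
        """The frozen sign convention agrees with an independent CIP oracle:
        an RDKit-embedded L-alanine (CIP label S) must have a chi triple
        product of the sign the package calls S."""
        from rdkit import Chem
        from rdkit.Chem import AllChem
        from netscale.rebuild import S_CHI_SIGN

        mol = Chem.AddHs(Chem.MolFromSmiles("N[C@@H](C)C(=O)O"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        labels = {a.GetIdx(): a.GetPropsAsDict().get("_CIPCode")
                  for a in mol.GetAtoms()}
        assert labels[1] == "S"  # atom 1 is the alpha carbon
        conf = mol.GetConformer()
        pos = lambda i: np.array(conf.GetAtomPosition(i))
        n, ca, cb, c = pos(0), pos(1), pos(2), pos(3)
        chi = np.dot(n - ca, np.cross(c - ca, cb - ca))
        assert np.sign(chi) == S_CHI_SIGN


class TestGlobalReflection:
    def test_restores_all_L(self, helix10):
        mirrored = _mirror(helix10)
        fixed, report = correct_global_reflection(mirrored, assign_chirality(mirrored))
        assert report.rs_ratio == 0.0

    def test_identity_on_all_L(self, helix10):
        fixed, _ = correct_global_reflection(helix10, assign_chirality(helix10))
        assert fixed is helix10  # returned unchanged, not a copy

    def test_idempotent(self, helix10):
        mirrored = _mirror(helix10)
        once, rep1 = correct_global_reflection(mirrored, assign_chirality(mirrored))
        twice, _ = correct_global_reflection(once, rep1)
        assert twice is once


class TestLocalChirality:
    def _with_one_d_residue(self, structure, r=4):
        coords = structure.coords.copy()
        table = structure.table
        n, ca, c = (coords[table.atom_index(r, a)] for a in ("N", "CA", "C"))
        normal = np.cross(n - ca, c - ca)
        normal /= np.linalg.norm(normal)
        cb = table.atom_index(r, "CB")
        coords[cb] -= 2 * np.dot(coords[cb] - ca, normal) * normal
        return Structure(table, coords)

    def test_single_d_residue_restored(self, helix10):
        bad = self._with_one_d_residue(helix10)
        fixed, report = correct_local_chirality(bad, assign_chirality(bad))
        assert report.n_R == 0

    def test_backbone_untouched(self, helix10):
        bad = self._with_one_d_residue(helix10)
        fixed, _ = correct_local_chirality(bad, assign_chirality(bad))
        backbone = np.isin(bad.table.atom_names, ("N", "CA", "C", "O", "OXT"))
        assert np.array_equal(fixed.coords[backbone], bad.coords[backbone])

    def test_all_L_input_unchanged(self, helix10):
        fixed, _ = correct_local_chirality(helix10, assign_chirality(helix10))
        assert fixed is helix10

    def test_requires_global_fix_first(self, helix10):
        mirrored = _mirror(helix10)
        with pytest.raises(ValueError, match="global"):
            correct_local_chirality(mirrored, assign_chirality(mirrored))


class TestMinimizer:
    def test_ideal_geometry_is_fixed_point(self, extended10):
        cfg = MinimizerConfig(tether_k=0.0)
        relaxed, trace = minimize(extended10, cfg)
        assert trace[0] < 1e-6
        assert np.abs(relaxed.coords - extended10.coords).max() < 1e-6

    def test_clashing_pair_separates(self, extended10):
        coords = extended10.coords.copy()
        table = extended10.table
        i = table.atom_index(1, "CB")
        j = table.atom_index(3, "CB")
        # drop residue 1's CB halfway into residue 3's CB vdW sphere
        coords[i] = coords[j] + np.array([0.5 * (1.70 + 1.70), 0, 0])
        clashed = Structure(table, coords)
        before = np.linalg.norm(clashed.coords[i] - clashed.coords[j])
        relaxed, _ = minimize(clashed, MinimizerConfig(steps=75))
        after = np.linalg.norm(relaxed.coords[i] - relaxed.coords[j])
        assert after > before

    def test_energy_trace_monotone_on_random_rebuilds(self, small_ensemble):
        rng = np.random.default_rng(13)
        for i in range(5):
            frame = small_ensemble.frame(i)
            pid = np.clip(compute_pid(frame) + rng.normal(0, 0.3, len(compute_pid(frame))), 0.5, None)
            coords, _ = embed_mds(pid)
            s = Structure(frame.table, coords)
            _, trace = minimize(s, MinimizerConfig(steps=75))
            assert np.all(np.diff(trace) <= 1e-9)

    def test_clash_extension_reaches_clash_free(self, small_ensemble):
        rng = np.random.default_rng(21)
        frame = small_ensemble.frame(3)
        pid = np.clip(compute_pid(frame) + rng.normal(0, 1.0, frame.n_atoms * (frame.n_atoms - 1) // 2), 0.5, None)
        coords, _ = embed_mds(pid)
        s = Structure(frame.table, coords)
        relaxed, trace, extra = minimize_until_clash_free(s)
        assert clash_count(relaxed) == 0
        assert np.all(np.diff(trace) <= 1e-9)


class TestSweep:
    def test_checkpoint_arithmetic_and_self_reference(self, helix10):
        rows, best = minimization_sweep(helix10, helix10, max_steps=520, interval=20)
        assert len(rows) == 27
        assert rows[0]["step"] == 0 and rows[-1]["step"] == 520
        assert rows[0]["rmsd"] == pytest.approx(0.0, abs=1e-9)

    def test_reports_argmin_rmsd_checkpoint(self, small_ensemble):
        frame = small_ensemble.frame(4)
        rng = np.random.default_rng(3)
        pid = np.clip(compute_pid(frame) + rng.normal(0, 0.3, len(compute_pid(frame))), 0.5, None)
        coords, _ = embed_mds(pid)
        start = Structure(frame.table, coords)
        rows, best = minimization_sweep(start, frame, max_steps=100, interval=20)
        rmsds = {r["step"]: r["rmsd"] for r in rows}
        assert best["rmsd"] == min(rmsds, key=rmsds.get)
        steps = [r["step"] for r in rows]
        assert steps == sorted(steps)


class TestRebuildFrame:
    def test_noiseless_pid_rebuilds_below_half_angstrom(self, small_ensemble):
        for i in range(3):
            frame = small_ensemble.frame(i)
            rebuilt, log = rebuild_frame(compute_pid(frame), frame.table)
            assert kabsch_rmsd(frame, rebuilt) < 0.5
            stages = [entry["stage"] for entry in log]
            assert stages[:4] == ["embed_mds", "assign_chirality",
                                  "correct_global_reflection",
                                  "correct_local_chirality"]

    def test_output_is_all_L_even_for_mirrorable_input(self, small_ensemble):
        # a raw distance matrix is blind to handedness, so the embedding is
        # free to come out mirrored; the pipeline must always return all-L
        frame = small_ensemble.frame(5)
        rebuilt, _ = rebuild_frame(compute_pid(frame), frame.table)
        assert assign_chirality(rebuilt).n_R == 0

    def test_batch_order_preserved(self, small_ensemble):
        pids = [compute_pid(small_ensemble.frame(i)) for i in range(3)]
        structures, logs = rebuild_frames(pids, small_ensemble.table)
        assert len(structures) == len(logs) == 3
        for i, s in enumerate(structures):
            assert kabsch_rmsd(small_ensemble.frame(i), s) < 0.5
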