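"""PID-space errors and 3D structure-comparison scores."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from netscale import (
    Structure,
    gdt_ts,
    kabsch_rmsd,
    lddt,
    pid_errors,
    score_ensemble,
    score_structures,
    tm_score,
)
from netscale.core import AtomTable, Ensemble
from netscale.synthetic import build_backbone

from conftest import HELIX, EXTENDED, random_rigid_transform


def _transformed(structure, seed=0):
    Q, t = random_rigid_transform(np.random.default_rng(seed))
    return Structure(structure.table, structure.coords @ Q.T + t)


class TestPIDErrors:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = pid_errors(y, y)
        assert rep.rmse == rep.mae == rep.mape == 0.0

    def test_hand_arithmetic(self):
        rep = pid_errors([2.0, 2.0], [1.0, 3.0])
        assert rep.rmse == pytest.approx(1.0)
        assert rep.mae == pytest.approx(1.0)
        assert rep.mape == pytest.approx(50.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(1, 30, 200)
        yh = y + rng.normal(0, 2, 200)
        rep = pid_errors(y, yh)
        assert rep.rmse == pytest.approx(np.sqrt(np.mean((y - yh) ** 2)))
        assert rep.mae == pytest.approx(np.mean(np.abs(y - yh)))
        assert rep.mape == pytest.approx(100 * np.mean(np.abs(y - yh) / y))
        assert rep.rmse >= rep.mae  # power-mean inequality

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pid_errors([1.0, 2.0], [1.0])


class TestKabschRMSD:
    def test_rigid_copy_is_zero(self, helix10):
        assert kabsch_rmsd(helix10, _transformed(helix10, 3)) < 1e-9

    def test_symmetry(self, helix10, extended10):
        a = kabsch_rmsd(helix10, extended10)
        b = kabsch_rmsd(extended10, helix10)
        assert a == pytest.approx(b, abs=1e-9)

    def test_rotation_grid_oracle_on_four_atom_toy(self):
        table = AtomTable(["N", "CA", "C", "O"], ["N", "C", "C", "O"],
                          [1, 1, 1, 1], ["GLY"] * 4)
        rng = np.random.default_rng(11)
        ref = Structure(table, rng.normal(size=(4, 3)) * 3)
        model = Structure(table, ref.coords + rng.normal(0, 0.8, (4, 3)))
        # coarse-to-fine grid search over proper rotations
        p = model.coords - model.coords.mean(axis=0)
        q = ref.coords - ref.coords.mean(axis=0)

        def rmsd_of(rots):
            moved = np.einsum("rij,aj->rai", rots.as_matrix(), p)
            return np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=2), axis=1))

        best = Rotation.identity()
        span, steps = 180.0, 13
        for _ in range(8):
            offsets = np.linspace(-span, span, steps)
            grid = np.stack(np.meshgrid(offsets, offsets, offsets),
                            -1).reshape(-1, 3)
            rots = Rotation.from_euler("zyx", grid, degrees=True) * best
            vals = rmsd_of(rots)
            best = rots[int(np.argmin(vals))]
            span /= 4.0
        grid_value = float(rmsd_of(Rotation.concatenate([best]))[0])
        assert kabsch_rmsd(ref, model) == pytest.approx(grid_value, abs=1e-3)


class TestTMScore:
    def test_identity_is_one(self, helix10):
        assert tm_score(helix10, helix10) == pytest.approx(1.0)

    def test_rigid_invariance(self, helix10):
        assert tm_score(helix10, _transformed(helix10, 8)) == pytest.approx(1.0, abs=1e-6)

    def test_matches_exhaustive_seed_oracle_on_small_toy(self):
        ref = build_backbone("ADSERKLV", [HELIX] * 8)
        model = build_backbone("ADSERKLV", [HELIX] * 4 + [EXTENDED] * 4)
        # independent oracle: explicit loops over every seed fragment
        from netscale.metrics import (
            _ca_coords, _apply, _iterative_refine, kabsch_superpose,
        )
        ref_ca, mob_ca = _ca_coords(ref), _ca_coords(model)
        L, d0 = 8, 0.5
        best = 0.0
        for length in (3, 5, 7, 8):
            for start in range(0, L - length + 1):
                sl = slice(start, start + length)
                R, t = kabsch_superpose(ref_ca[sl], mob_ca[sl])
                R, t = _iterative_refine(ref_ca, mob_ca, R, t, cutoff=1.0)
                d = np.linalg.norm(_apply(R, t, mob_ca) - ref_ca, axis=1)
                best = max(best, float(np.mean(1 / (1 + (d / d0) ** 2))))
        assert tm_score(ref, model) == pytest.approx(best, abs=1e-12)

    def test_residue_count_mismatch(self, helix10):
        other = build_backbone("ADSERKLV", [HELIX] * 8)
        with pytest.raises(ValueError):
            tm_score(helix10, other)


class TestGDT:
    def test_identity_is_one(self, helix10):
        assert gdt_ts(helix10, helix10) == pytest.approx(1.0)

    def test_rigid_invariance(self, extended10):
        assert gdt_ts(extended10, _transformed(extended10, 12)) == pytest.approx(1.0)

    def test_at_least_fraction_under_one_angstrom(self, helix10):
        rng = np.random.default_rng(2)
        noisy = Structure(helix10.table,
                          helix10.coords + rng.normal(0, 1.5, helix10.coords.shape))
        score = gdt_ts(helix10, noisy)
        # GDT_TS averages laxer cutoffs in, so it dominates the 1 A fraction
        from netscale.metrics import _ca_coords, _apply, kabsch_superpose
        R, t = kabsch_superpose(_ca_coords(helix10), _ca_coords(noisy))
        d = np.linalg.norm(
            _apply(R, t, _ca_coords(noisy)) - _ca_coords(helix10), axis=1
        )
        assert score >= np.mean(d < 1.0)

    def test_dissimilar_conformations_score_low(self):
        ref = build_backbone("ADSERKLVFYADSERKLVFY", [EXTENDED] * 20)
        # mirror the extended chain: no proper superposition matches it
        mirrored = Structure(ref.table, ref.coords * [-1, 1, 1])
        helix = build_backbone("ADSERKLVFYADSERKLVFY", [HELIX] * 20)
        assert gdt_ts(ref, helix) < 0.6
        assert gdt_ts(ref, mirrored) <= 1.0


class TestLDDT:
    def test_identity_and_rigid_invariance(self, helix10):
        assert lddt(helix10, helix10) == pytest.approx(1.0)
        assert lddt(helix10, _transformed(helix10, 5)) == pytest.approx(1.0)

    def test_hand_enumerated_toy(self):
        # 5 atoms in 5 residues on a line, one displaced in the model
        table = AtomTable(["CA"] * 5, ["C"] * 5, [1, 2, 3, 4, 5], ["GLY"] * 5)
        ref = Structure(table, np.array(
            [[0, 0, 0], [3, 0, 0], [6, 0, 0], [9, 0, 0], [12, 0, 0]], float))
        model_coords = ref.coords.copy()
        model_coords[4, 0] += 1.5  # perturbs 4 pairs by exactly 1.5 A
        model = Structure(table, model_coords)
        # 10 pairs, 4 with |dd|=1.5: thresholds 0.5,1 keep 6/10; 2,4 keep 10/10
        expected = np.mean([6 / 10, 6 / 10, 1.0, 1.0])
        assert lddt(ref, model) == pytest.approx(expected)

    def test_mirror_dissociation(self, helix10):
        """A mirrored structure preserves all distances (LDDT = 1) while the
        proper-rotation RMSD stays large."""
        mirrored = Structure(helix10.table, helix10.coords * [-1, 1, 1])
        assert lddt(helix10, mirrored) == pytest.approx(1.0)
        assert kabsch_rmsd(helix10, mirrored) > 1.0


class TestNoiseMonotonicity:
    def test_scores_degrade_with_noise(self, helix10):
        sigmas = (0.1, 0.5, 2.0)
        means = {"tm": [], "gdt_ts": [], "lddt": [], "rmsd": []}
        for sigma in sigmas:
            reps = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                noisy = Structure(
                    helix10.table,
                    helix10.coords + rng.normal(0, sigma, helix10.coords.shape),
                )
                reps.append(score_structures(helix10, noisy))
            for key in means:
                means[key].append(np.mean([getattr(r, key if key != "gdt_ts" else "gdt_ts") for r in reps]))
        assert means["rmsd"] == sorted(means["rmsd"])
        for key in ("tm", "gdt_ts", "lddt"):
            assert means[key] == sorted(means[key], reverse=True)


class TestScoreEnsemble:
    def test_self_comparison_summary(self, small_ensemble):
        sub = Ensemble(small_ensemble.table, small_ensemble.coords[:4])
        per_frame, summary = score_ensemble(sub, sub)
        assert len(per_frame) == 4
        assert summary["rmsd"]["mean"] == pytest.approx(0.0, abs=1e-9)
        for m in ("tm", "gdt_ts", "lddt"):
            assert summary[m]["mean"] == pytest.approx(1.0)
            assert summary[m]["ci_high"] - summary[m]["ci_low"] == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_ci_flagged(self, helix10):
        ens = Ensemble(helix10.table, helix10.coords[None])
        _, summary = score_ensemble(ens, ens)
        assert summary["tm"]["degenerate"] is True
        assert summary["tm"]["ci_low"] == summary["tm"]["mean"]

    def test_summary_means_are_column_means(self, small_ensemble):
        refs = Ensemble(small_ensemble.table, small_ensemble.coords[:3])
        rng = np.random.default_rng(1)
        models = Ensemble(small_ensemble.table,
                          small_ensemble.coords[:3] + rng.normal(0, 0.3, (3,) + small_ensemble.coords.shape[1:]))
        per_frame, summary = score_ensemble(refs, models)
        assert summary["lddt"]["mean"] == pytest.approx(
            np.mean([r.lddt for r in per_frame])
        )
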