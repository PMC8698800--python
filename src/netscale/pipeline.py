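"""End-to-end orchestration: simulate -> coarsen -> train -> predict ->
rebuild -> evaluate, as one reproducible run with a machine-readable
manifest."""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .coarsen import coarsen_ensemble, save_dataset
from .core import Ensemble
from .io import read_pdb_ensemble, write_pdb_ensemble
from .metrics import pid_errors, score_ensemble
from .neural import (
    ModelConfig,
    baseline_mean_predictor,
    build_model,
    predict,
    save_checkpoint,
    split_frames,
    train,
)
from .rebuild import MinimizerConfig, rebuild_frames
from .synthetic import SyntheticSpec, generate_ensemble

logger = logging.getLogger(__name__)

STAGES = ("simulate", "coarsen", "train", "predict", "rebuild", "evaluate")


@dataclass
class PipelineConfig:
    """One reproducible run: a synthetic spec (or input PDB), model and
    minimizer settings, contact scale and a single global seed that fans
    out deterministically to the per-stage seeds."""

    outdir: str = "netscale_run"
    input_pdb: str | None = None  # if None, simulate synthetically
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    minimizer: MinimizerConfig = field(default_factory=MinimizerConfig)
    scale: float = 1.1
    fractions: tuple = (0.72, 0.08, 0.20)
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + STAGES.index(stage) + 1) % (2 ** 31)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = SyntheticSpec(**d["synthetic"])
        if "model" in d:
            d["model"] = ModelConfig(**d["model"])
        if "minimizer" in d:
            d["minimizer"] = MinimizerConfig(**d["minimizer"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    Artifacts (ensemble PDB, HDF5 data container, model checkpoint,
    rebuilt PDB, per-frame score TSV, manifest JSON) are written under
    ``config.outdir``.  The manifest is rewritten after every stage, so a
    partial failure leaves completed-stage artifacts plus a resumable
    state marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "stages": {},
        "config": {
            "scale": config.scale,
            "fractions": list(config.fractions),
            "model": config.model.to_dict(),
            "synthetic": None if config.input_pdb else vars(config.synthetic).copy(),
            "input_pdb": config.input_pdb,
        },
    }
    manifest["config"].setdefault("synthetic", None)
    if manifest["config"]["synthetic"]:
        manifest["config"]["synthetic"]["basins"] = {
            k: list(v) for k, v in manifest["config"]["synthetic"]["basins"].items()
        }

    def mark(stage: str, **info):
        manifest["stages"][stage] = {"status": "complete", **info}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("[%s] complete %s", stage, info if info else "")

    t0 = time.time()
    # simulate ------------------------------------------------------------
    if config.input_pdb:
        ensemble = read_pdb_ensemble(config.input_pdb)
    else:
        spec = config.synthetic
        spec.seed = config.stage_seed("simulate")
        ensemble = generate_ensemble(spec)
    ensemble_path = outdir / "ensemble.pdb"
    write_pdb_ensemble(ensemble, ensemble_path)
    manifest["atom_fingerprint"] = ensemble.table.fingerprint()
    mark("simulate", n_frames=ensemble.n_frames, n_atoms=ensemble.table.n_atoms,
         path=str(ensemble_path))

    # coarsen -------------------------------------------------------------
    X, Y = coarsen_ensemble(ensemble, scale=config.scale)
    data_path = outdir / "data.h5"
    save_dataset(data_path, X, Y, ensemble.table)
    mark("coarsen", input_dim=X.shape[1], output_dim=Y.shape[1],
         path=str(data_path))

    # train ---------------------------------------------------------------
    split = split_frames(ensemble.n_frames, config.fractions,
                         seed=config.stage_seed("train"))
    model_cfg = config.model
    model_cfg.seed = config.stage_seed("train")
    model = build_model(model_cfg, X.shape[1], Y.shape[1],
                        ensemble.table.fingerprint())
    train(model, X[split.train_ids], Y[split.train_ids],
          X[split.val_ids], Y[split.val_ids])
    ckpt_path = outdir / "model.ckpt.npz"
    save_checkpoint(model, ckpt_path)
    mark("train", n_parameters=model.n_parameters,
         final_train_loss=model.history["train_loss"][-1],
         final_val_loss=(model.history["val_loss"][-1]
                         if model.history["val_loss"] else None),
         path=str(ckpt_path))

    # predict -------------------------------------------------------------
    Y_pred = predict(model, X[split.test_ids])
    pid_report = pid_errors(
        np.asarray(Y[split.test_ids], dtype=float).ravel(), Y_pred.ravel()
    )
    baseline = baseline_mean_predictor(Y[split.train_ids])
    base_report = pid_errors(
        np.asarray(Y[split.test_ids], dtype=float).ravel(),
        np.tile(baseline, (len(split.test_ids), 1)).ravel(),
    )
    np.savez(outdir / "pred.npz", Y_pred=Y_pred, test_ids=split.test_ids)
    mark("predict", test_rmse=pid_report.rmse, test_mae=pid_report.mae,
         test_mape=pid_report.mape, baseline_rmse=base_report.rmse)

    # rebuild -------------------------------------------------------------
    structures, logs = rebuild_frames(
        Y_pred, ensemble.table, minimizer=config.minimizer,
        seed=config.stage_seed("rebuild"),
    )
    rebuilt = Ensemble.from_structures(structures)
    rebuilt_path = outdir / "rebuilt.pdb"
    write_pdb_ensemble(rebuilt, rebuilt_path)
    with open(outdir / "rebuild_log.jsonl", "w") as fh:
        for frame_id, log in zip(split.test_ids, logs):
            fh.write(json.dumps({"frame": int(frame_id), "stages": log}) + "\n")
    mark("rebuild", n_frames=rebuilt.n_frames, path=str(rebuilt_path))

    # evaluate ------------------------------------------------------------
    refs = Ensemble(ensemble.table, ensemble.coords[split.test_ids])
    per_frame, summary = score_ensemble(refs, rebuilt)
    tsv_path = outdir / "scores.tsv"
    with open(tsv_path, "w") as fh:
        fh.write("frame_id\trmsd\ttm\tgdt_ts\tlddt\n")
        for frame_id, rep in zip(split.test_ids, per_frame):
            fh.write(f"{frame_id}\t{rep.rmsd:.4f}\t{rep.tm:.4f}"
                     f"\t{rep.gdt_ts:.4f}\t{rep.lddt:.4f}\n")
    mark("evaluate", summary=summary, path=str(tsv_path))
    manifest["runtime_seconds"] = time.time() - t0
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
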