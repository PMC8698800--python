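"""Rebuild 3D structures from distance vectors and score them.

Takes a true PID (noiseless) and a noise-corrupted one, runs the full
reconstruction (MDS -> chirality repair -> steric relaxation) and scores
both against the source conformation."""

import numpy as np

from netscale import (
    SyntheticSpec,
    assign_chirality,
    clash_count,
    compute_pid,
    generate_ensemble,
    rebuild_frame,
    score_structures,
)

ensemble = generate_ensemble(SyntheticSpec(n_frames=5, seed=2))
frame = ensemble.frame(0)
pid = compute_pid(frame)

for label, vector in [
    ("noiseless PID", pid),
    ("PID + 1.0 A noise", np.clip(pid + np.random.default_rng(0).normal(0, 1.0, len(pid)), 0.5, None)),
]:
    rebuilt, log = rebuild_frame(vector, frame.table, seed=0)
    scores = score_structures(frame, rebuilt)
    chir = assign_chirality(rebuilt)
    print(f"{label}:")
    print(f"  RMSD {scores.rmsd:.2f} A | TM {scores.tm:.2f} | "
          f"GDT_TS {scores.gdt_ts:.2f} | LDDT {scores.lddt:.2f}")
    print(f"  clashes {clash_count(rebuilt)}, R centers {chir.n_R} "
          f"(all-L guaranteed), stages: {[e['stage'] for e in log]}")
# A noiseless distance matrix rebuilds essentially exactly (RMSD well
# under 0.5 A); noise degrades the scores smoothly while the chirality
# and clash guarantees continue to hold.
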