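"""How many conjugate-gradient steps does the relaxation need?

Reconstructs one frame from a noisy distance vector, then scores the
structure every 20 minimisation steps up to 520, reporting the best
checkpoint per metric."""

import numpy as np

from netscale import (
    Structure,
    SyntheticSpec,
    compute_pid,
    embed_mds,
    generate_ensemble,
    minimization_sweep,
)

ensemble = generate_ensemble(SyntheticSpec(n_frames=1, seed=4))
frame = ensemble.frame(0)
pid = compute_pid(frame)
noisy = np.clip(pid + np.random.default_rng(1).normal(0, 0.4, len(pid)), 0.5, None)
coords, _ = embed_mds(noisy)
start = Structure(frame.table, coords)

rows, best = minimization_sweep(start, frame, max_steps=520, interval=20)
print(f"{len(rows)} checkpoints (steps 0..520 every 20)")
print("step  rmsd   tm    gdt   lddt  energy")
for r in rows[::4]:
    print(f"{r['step']:4d}  {r['rmsd']:.2f}  {r['tm']:.2f}  "
          f"{r['gdt_ts']:.2f}  {r['lddt']:.2f}  {r['energy']:.1f}")
print("best step per metric:", best)
# Most of the metric improvement arrives in the first 50-100 steps;
# further minimisation mainly polishes the energy.
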