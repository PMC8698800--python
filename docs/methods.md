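# Methods

## The model

`netscale` treats backmapping as supervised regression on one protein.
For each conformation the input is the flattened strict upper triangle of
the residue-level contact adjacency matrix (entries x_ij in {0,1}; two
residues are adjacent when some heavy-atom pair lies at distance
<= s (r_a + r_b), vdW radii from the Bondi table, boundary inclusive,
default scale s = 1.1; the radius table is user-overridable via a plain
two-column text file).  The output is the flattened upper triangle of
the heavy-atom pairwise interatomic distance (PID) matrix in Angstrom.
Both triangles use one fixed row-major order — pairs (0,1), (0,2), ...,
(n-2,n-1) — identical to scipy's `pdist` convention, so the coarsening
and reconstruction stages are bijective by construction.

The regressor is a fully connected network: ReLU hidden layers with
inverted dropout (rate 0.2) after each, a linear output layer, mean
squared error loss, minibatch AMSGrad (batch 50, 100 epochs).  The
reference architecture uses hidden sizes [2000, 2000, 2000, 8000]; the
desk-scale experiments in the tests use [200, 200, 200, 800] against the
20-residue synthetic peptide (input 190, output 4950).  Inputs are raw
bits and outputs raw distances — no normalisation — so predictions are
directly in Angstrom.  Forward and backward passes are plain numpy;
training is bit-reproducible for a fixed (data, config, seed) triple on
one device.

Choices the method statement leaves open, fixed here as package defaults:

* **learning rate** 1e-3 (AMSGrad), configurable.  Note that adaptive-
  moment steps are bounded by the learning rate, so very short runs on
  large-magnitude targets need a larger rate (the overfit sanity test
  uses 0.05 full-batch for exactly this reason).
* **weight initialisation** He-normal, seeded.
* **epoch selection** final-epoch weights; the full train/validation
  loss history is retained on the model object.
* **splits** frames are split i.i.d. at random, 72% train / 8%
  validation / 20% test, sizes rounded to whole frames; k-fold
  cross-validation re-splits the non-test frames 90/10 to mirror that
  ratio.  Temporal block splitting is not used.
* **negative outputs** a linear output layer can predict non-physical
  distances early in training; predictions are clamped at a 0.5 A floor
  (MDS needs positive dissimilarities) and the clamp count is logged.

## Reconstruction

A predicted PID vector is embedded by classical (Torgerson) scaling —
eigendecomposition of the double-centered squared-distance matrix, top
three components — optionally refined by metric stress majorization
(SMACOF) initialised from the classical solution.  The deterministic
initialisation removes the random-restart nondeterminism of generic MDS
and guarantees the refined raw stress never exceeds the classical one;
for exact Euclidean inputs the classical embedding is already exact to
eigensolver precision.

Distance matrices carry no handedness, so the embedding may be the
mirror image of the true structure.  Each Calpha is labeled R or S from
chi = (r_N - r_CA) . [(r_C - r_CA) x (r_CB - r_CA)]; the sign-to-label
mapping was calibrated once against an ideal L-alanine and frozen as a
tested constant (chi > 0 for S).  Glycine (no CB) is labeled undefined
and excluded from counts.  If the R:S ratio exceeds 1 (strictly), one
coordinate axis is negated — equivalent to any planar reflection up to a
proper rotation, which every downstream score ignores — and the report
recomputed.  Remaining isolated R residues have their side-chain atoms
(CB and beyond) reflected through the residue's N–CA–C plane; backbone
atoms never move.

Relaxation minimises E = sum_b k_b (d-d0)^2 + sum_a k_a (th-th0)^2 +
sum_{nonbonded, d < s_r (r_i+r_j)} k_r (s_r (r_i+r_j) - d)^2 +
k_t sum |x - x_in|^2 by Polak–Ribiere conjugate gradient with a
backtracking (Armijo) line search, which makes the energy trace monotone
non-increasing by construction.  Defaults: 75 steps, k_b = 300,
k_a = 50, k_r = 25, k_t = 1 (arbitrary energy units), repulsion onset
s_r = 0.85, clash definition d < 0.7 (r_i + r_j).  Nonbonded pairs
exclude 1-2 and 1-3 neighbours.  Bonded topology and ideal values come
from one embedded template table (N-CA 1.458, CA-C 1.525, C-N 1.329,
C-O 1.231, CA-CB 1.530 A; standard trans-peptide angles); the same table
drives the synthetic builder, so ideal-geometry structures are exact
fixed points of the minimizer.  The carbonyl closure angles and the CB
dihedral are derived from the other table entries at import time to keep
the template internally consistent.  Angle terms cover the backbone and
CB only; full side chains get bond terms plus the soft repulsion, which
is sufficient for clash removal — the potential makes no claim to be a
physical force field, and equivalence to an external minimiser is
qualitative (clash removal), not energetic.

If clashes persist after the configured steps, minimisation continues in
5-step increments up to a 100-step cap.  Because the potential is
achiral, relaxing a badly distorted residue can occasionally flip its
alpha carbon; the full rebuild therefore re-checks chirality after
minimisation and re-applies the correction (up to three short touch-up
rounds), which restores the all-S output guarantee.

## Scoring

PID errors (RMSE, MAE, MAPE, absolute-difference histogram) compare
distance vectors directly, with no superposition.  3D scores:

* **RMSD** over all heavy atoms after Kabsch superposition restricted to
  proper rotations, so mirror-image errors remain visible;
* **TM-score** over Calpha, d0 = 1.24 (L-15)^(1/3) - 1.8 floored at 0.5;
* **GDT_TS** mean over {1,2,4,8} A cutoffs of the maximal superposable
  Calpha fraction;
* **LDDT** superposition-free, heavy-atom pairs in different residues
  within a 15 A inclusion radius, thresholds {0.5,1,2,4} A.

TM-score and GDT_TS maximise over superpositions seeded from all
contiguous Calpha fragments of lengths {3,5,7} plus the full chain, each
refined by iterative re-superposition on the in-cutoff subset.  This is
the standard fragment-seed heuristic, a lower-bound-style approximation
to the full search; it is locked by regression tests against exhaustive
seed enumeration on small chains.  Ensemble summaries report the mean
and a normal-approximation 95% CI (mean +- 1.96 SEM); a single-frame
summary degenerates to the point value and is flagged.

## The synthetic generator

The generator emulates the target regime — many frames of one disordered
peptide with variable, transient secondary structure — without any
external data.  Per frame: pick one of `frame_modes` metastable state
patterns (the first two are the uniform all-helix and all-extended
patterns, keeping modes well separated in conformation space; additional
modes are random mixtures), flip each residue's state with probability
`switch_prob` (default 0.05), draw (phi, psi) from the state's Gaussian
basin (helix (-63, -42), extended (-120, +135), sigma 8 deg), build the
chain by internal-coordinate (NeRF) construction with ideal trans-peptide
geometry, and add Cartesian noise (default sigma 0.1 A).  Frames with
any nonbonded pair closer than 0.7 (r_i + r_j) are resampled (bounded
retries).  Side chains are truncated at CB (plus backbone O and terminal
OXT), capping the atom count at 5 per residue so the full pipeline
trains in minutes; the default sequence is the 20 N-terminal residues of
amyloid-beta 1-40, and the full-length sequence ships as a named
constant whose complete heavy-atom table (306 atoms, PID length 46,665)
is supported by every other module.

What the generator does *not* emulate: realistic side-chain packing,
solvent effects, energetic weighting of conformations, and temporal
autocorrelation between frames.  Passing tests therefore demonstrate
that the machinery — coarsening, learning, embedding, repair, scoring —
is correct and end-to-end learnable on ensembles with genuine two-state
structure, not that the learned accuracies transfer quantitatively to
real MD data.

## Problem sizes used by the test suite

The distance-geometry and minimizer properties run over 100 synthetic
frames each.  The learning experiment uses 500 frames of the default
20-mer (split 360/40/100), hidden sizes [200, 200, 200, 800], 100
epochs; its trained network must beat the mean-PID constant baseline by
at least 25% test RMSE, and its rebuilt test frames must beat the
baseline rebuild on mean GDT_TS.  Five-fold cross-validation runs the
same configuration on the same fixture; the claim under test is
fold-to-fold stability of validation RMSE (spread under 20% of the
mean).  Under-converged models are deliberately not used here: short
training adds fold-dependent optimisation noise that would measure
convergence scatter rather than split robustness.  Note that with only
a few hundred training frames the trained models themselves remain
sensitive to the data division (the per-fold error is bimodal across
the helix-like and extended-like frames), so fold spread at this scale
reflects small-sample training variability as much as split bias; the
corresponding test documents the measured spread.

## Known limitations

* Single chain, heavy atoms only; hydrogens are discarded on read and
  never re-added.
* One model learns one protein (one atom table); checkpoints carry an
  atom-table fingerprint and refuse mismatched inputs.
* The steric potential is minimal by design; relaxed structures are
  clash-free and topologically sound but not force-field quality.
* GDT_TS/TM superposition search is heuristic; scores are lower bounds
  of the exhaustive-search values (exact on the tested small chains).
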