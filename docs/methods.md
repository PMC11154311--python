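# Methods

This note documents the models, conventions, and design choices behind
`rasstates`, in the spirit of the methods documentation of established
analysis packages.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## State model and classifier

Frames are assigned by a fixed decision cascade over five inter-atomic
distances (see README for the table).  The cascade order encodes
specificity: state 1 is detected first from the broken Thr35–Mg²⁺ bond;
among state-2 substates, 2OX and 2OY have the sharpest signatures (a
*small* OH32–Oγ or OH32–O18 distance respectively), while 2OZ is the
residual bulk-facing orientation, bounded above by `t_oz_max`.  Frames
matching no signature are reported as UNASSIGNED, never silently merged.

Default thresholds sit between the characteristic per-state distance
centers, which are distribution modes rather than published cutoffs:

| threshold | default | placed between |
|---|---|---|
| `t_mg` | 2.6 Å | intact bond ≈ 2.0 Å + thermal margin; broken trajectories jump well above 3 Å |
| `t_ox` | 4.5 Å | 2.7 Å (2OX) and 7.5 Å (2OZ) |
| `t_oy` | 6.5 Å | 4.3 Å (2OY) and the > 12 Å of other substates |
| `t_oz_max` | 10.0 Å | 7.5 Å 2OZ center (with its larger fluctuations) and 11.3 Å (2OY) |

All are configurable (`ClassifierConfig`), and the threshold-monotonicity
property (raising `t_mg` never shrinks the state-2 fraction) is covered by
tests.

**Smoothing.**  Raw labels are debounced with a centered label-mode filter
(default window 5 frames, truncated at the edges).  Ties go to the
previous frame's smoothed label, then to the frame's own raw label, then
to canonical label order — a deterministic rule chosen because dwell
segments, not per-frame flicker, are the physically meaningful objects.
A clean step edge passes through the filter unmoved; isolated spikes
shorter than half the window are erased, which slightly biases against
states with sub-window dwells (negligible at the default mean dwell of 50
frames).

**Occupancy.**  Fractions are frame-weighted over all pooled trajectories
and always sum to 1 over the five labels (UNASSIGNED included).

## Features

Distances are plain Euclidean in double precision; when a periodic box is
present the minimum-image convention is applied (via
`MDAnalysis.lib.distances`).  For intra-protein distances the choice is
immaterial in any realistic box, but ion counting requires the image
correction.  The β1 tilt is the angle in [0°, 180°] between the first
principal axis of the four Cα positions of residues 2–5 — oriented from
residue 2 toward residue 5 — and the membrane normal (laboratory +z by
default, configurable).  The principal-axis construction is robust to
local strand bends and reduces to the end-to-end vector for collinear
points.  The HVR-stretch coordinate is the Cα–Cα distance E132–L184 and
is absent (NaN column) for solution-only systems without an HVR.

## Ensemble statistics

* **Superposition** is least-squares rigid-body fitting (QCP via
  MDAnalysis), cross-checked in tests against SciPy's independent Kabsch
  solver.  The fit set defaults to the G-domain core *excluding* switch I
  (residues 30–40) and switch II (58–76; standard Ras literature ranges,
  configurable), so that switch mobility does not leak into core
  statistics; RMSD may be reported over a different residue set than the
  fit set.
* **Mean-structure iteration** for RMSF/PCA/DCCM is two-pass (fit to the
  first frame → mean → refit to the mean), the standard convergence
  shortcut; full fixed-point iteration is available via a flag.
* **RMSF** is `sqrt(⟨|r_i − ⟨r_i⟩|²⟩)` per residue over pooled,
  superposed frames of one state, frame-weighted across trajectories.
* **PCA** diagonalises the 3N×3N population covariance of superposed Cα
  deviations (`numpy.linalg.eigh`).  The full eigenvalue spectrum is kept
  (its sum equals the covariance trace to 1e-6 relative — a tested
  invariant); the top 10 eigenvectors are retained by default.  Per-residue
  mobility of mode *k* is defined as `sqrt(λ_k) · |v_k,residue|` (Å), so
  that a residue with zero eigenvector components has zero mobility.
* **DCCM** is `C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`; the matrix
  is symmetrised, clipped to [−1, 1], and residues with zero variance get
  zero rows/columns (diagonal 1) with a warning.

## Ion accessibility

An ion counts as "near the GTP" when its minimum-image distance to the
*nearest* GTP atom is ≤ 4.5 Å — a contact-shell reading of "vicinity of
the GTP molecule"; restricting to phosphate atoms is possible through the
role map.  Per-state summaries use the population standard deviation
(divisor n) because they describe the realised frame counts; states with
no frames are omitted from the summary.

## Atom-role resolution

Roles are bound by residue number (5UHV crystal numbering, never
renumbered) and PDB atom-name conventions: Thr35 hydroxyl = `OG1`, Tyr
ring hydroxyl = `OH`, backbone oxygen = `O`.  The GTP γ-oxygen role
accepts `O1G`/`O2G`/`O3G` and binds the candidate closest to OH32 in the
reference structure, fixed thereafter, so the OH32–Oγ series refers to one
atom across all frames.  HETATM residues (GTP, Mg, Na) match by residue
name case-insensitively with configurable synonyms (e.g. `SOD`).  In G12V
systems the residue-12 backbone oxygen resolves on Val12 at the same
position.  Structures with insertion codes are rejected to keep the
numbering unambiguous.

## Synthetic-trajectory generator

The generator is a *feature-level* emulator: it reproduces the statistics
the pipeline consumes, not protein physics.

**State sequence.**  A Markov chain that, at every frame, redraws the
state from the stationary distribution π with probability 1/τ and stays
put otherwise.  This kernel has stationary law exactly π, never emits
zero-probability states, and has integrated autocorrelation factor exactly
2τ−1, so occupancy estimates carry an effective sample size of
n/(2τ−1) — the formula used by all recovery tests.  (A kernel that
jumps only to *other* states in proportion to π was considered and
rejected: its stationary law is ∝ π_i(1−π_i), which would distort the
very occupancies the generator must realise.)

**Geometry.**  Per frame, the Mg sits at the origin, the chosen γ-oxygen
at a fixed 2.0 Å coordination offset, OG35 along +x at the sampled
Thr35–Mg distance, and OH32, O18, O12, OH40 on spheres realising their
sampled distances.  The construction is tree-structured — each classifier
distance constrains exactly one new atom relative to an already-placed
one — so every sampled distance is realised *exactly* and no rejection
sampling is needed; infeasibility reduces to non-positive or non-finite
distance parameters, rejected at spec validation.  Distance draws are
Gaussians resampled until positive.  The Cα trace is a fixed helix-like
template curve (165 residues; 186 with HVR) with Gaussian noise whose
scale on the switch residues depends on the state (state 1 noisiest, 2OZ
quietest), so per-state RMSF orderings are reproduced qualitatively.  The
β1 strand is laid collinear at the sampled tilt angle; L184 is placed at
the sampled distance from E132.

**Presets.**  Distance means per state are the characteristic centers
(README table); no published widths exist, so the standard deviations are
calibration choices: 0.4 Å default, 0.15 Å for the intact Thr35–Mg bond,
1.0–2.0 Å for the loose state-1 and bulk-facing-2OZ distances.  The 2OY
OH32–OH40 mean (not separately published) is set to the 2OX/2OZ value of
11.6 Å; it plays no role in classification.  Ion counts are Poisson with
the published per-scenario, per-state means (the background state's mean
is unconstrained and set to 0.5); each frame also carries 10 decoy ions
parked 25–35 Å from the origin, well outside the 8 Å moat, plus a
12-slot shell pool so the trajectory has a fixed atom count.
Reaction-coordinate distributions are qualitative encodings of the
published contour descriptions (narrow/specific for WT state 1 and the
compact-HVR substates, medium-stretched 2OX, wide ranges under G12V).

**Occupancy presets and the residual.**  The published "~" percentages do
not sum to 100 in every scenario.  Each *printed* percentage is kept
exactly; the residual is handled explicitly rather than smeared over the
printed values: a positive residual becomes a background state whose
geometry matches no classifier signature (the pipeline reports it as
UNASSIGNED — e.g. 7% in solution WT, 23% in membrane G12V); in the
membrane scenarios, where state 1 has no printed percentage (it is only
said to be unaffected by the membrane and equal between genotypes),
state 1 absorbs the remainder (0.37 in both).  G12V scenarios set the
2OZ weight to exactly zero, encoding the reported absence of the
GAP-compatible substate under the mutation.

**Determinism.**  One seed drives three spawned substreams (states,
geometry, ions), so toggling ion placement cannot perturb the state
sequence; identical seeds give byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic protein geometry and sterics,
membrane and solvent structure, correlated switch motions beyond
amplitude scaling, state-dependent kinetics beyond a single mean dwell
time, RMSD magnitudes relative to crystal structures, and ion dynamics
(placements are i.i.d. per frame).  Conclusions about classifier
robustness on real trajectories rest on the distance separations between
states, which the generator shares with the published characterisation.

## Problem sizes and numerical tolerances

Recovery tests in the suite use a single 20,000-frame trajectory per
scenario (mean dwell τ = 50 frames) and accept deviations within 3
standard errors at the effective sample size n/(2τ−1); pure-substate
distance recovery uses 5,000 frames at σ = 0.4 Å.  The acceptance script
pools 50 independent 20,000-frame trajectories per scenario — occupancies
are ensemble properties accumulated over all performed runs, and pooling
shrinks the Markov-chain sampling error by √50.  Exact numeric contracts:
superposition RMSD on rigid copies ≤ 1e-9 Å; RMSF closed-form case to
1e-8 Å; DCCM ±1 constructions to 1e-10; PCA trace identity to 1e-6
relative.  Degenerate inputs (coincident β1 points, < 3 or collinear fit
points, zero-variance residues, empty series) raise typed errors or warn,
as documented per function.

## Known limitations

* Classifier thresholds are constructed from distance centers, not fitted
  to labeled data; systems with atypical switch geometries may need
  re-tuning.
* The mode filter can erase genuinely short dwells (< window/2 frames).
* PBC handling assumes the box provided by the trajectory reader;
  trajectories are not unwrapped.
* Per-state PCA/DCCM require enough frames in a state
  (`min_state_frames`, default 10) and are skipped otherwise.
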