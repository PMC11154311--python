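# rasstates

Conformational state and substate analysis of GTP-bound N-Ras from
molecular-dynamics trajectories.

## What this package does

GTP-bound Ras proteins interconvert between two main conformational
states: the "inactive" **state 1**, in which the hydrogen bond between the
Thr35 side-chain oxygen and the catalytic Mg²⁺ ion is broken, and the
"active" **state 2**, in which it is intact.  In N-Ras, state 2 further
splits into three substates defined by the orientation of the Tyr32 side
chain: toward the GTP pocket (**2OX**), parallel to the pocket toward
Ala18 (**2OY**), and toward bulk solvent (**2OZ**, the GAP-binding
compatible orientation).  These states control the activation cycle —
state 1 interacts with exchange factors (GEFs), 2OZ is required for
GAP-accelerated hydrolysis — so their relative occupancies, and how the
plasma membrane and the oncogenic G12V mutation shift them, are of direct
biological interest.

`rasstates` classifies every trajectory frame from five inter-atomic
distances (Å):

| distance | meaning | characteristic values |
|---|---|---|
| OG35–Mg | Thr35 Oγ1 to Mg²⁺ | ≈ 2.0 intact (state 2); large when broken (state 1) |
| OH32–Oγ | Tyr32 ring OH to GTP γ-oxygen | 2.7 (2OX) / 7.5 (2OZ) / 11.3 (2OY) |
| OH32–O18 | Tyr32 OH to Ala18 backbone O | 4.3 (2OY); > 12 otherwise |
| O12–Oγ | residue-12 backbone O to γ-oxygen | ≈ 5.3 (WT); > 8 (G12V) |
| OH32–OH40 | Tyr32 OH to Tyr40 OH | ≈ 4.4 (state 1); ≈ 11.6 (2OX/2OZ) |

with the decision cascade

```
S1     if  d(OG35, Mg)  >  t_mg       (default 2.6 Å)
S2_OX  if  d(OH32, Oγ)  ≤  t_ox       (default 4.5 Å)
S2_OY  if  d(OH32, O18) ≤  t_oy       (default 6.5 Å)
S2_OZ  if  d(OH32, Oγ)  ≤  t_oz_max   (default 10.0 Å)
UNASSIGNED otherwise
```

followed by a centered label-mode filter (default 5 frames) to remove
single-frame flicker.  On top of the labels the package computes occupancy
distributions and dwell statistics, per-state Cα RMSF, essential-dynamics
PCA (covariance eigendecomposition with per-residue mode mobility),
dynamic cross-correlation matrices, Na⁺ counts within 4.5 Å of the GTP,
and the two membrane reaction coordinates (β1-strand tilt against the
membrane normal; E132–L184 Cα distance measuring HVR stretch).

Because no trajectories of this system are publicly deposited, the package
ships a seeded synthetic-trajectory generator (`rasstates.synthetic`) that
emulates the per-state distance distributions, a Markov state-switching
sequence with prescribed occupancies, and per-state Poisson ion placement
for four preset scenarios: `solution_WT`, `solution_G12V`, `membrane_WT`,
`membrane_G12V`.

## Worked example

```bash
rasstates synthesize --scenario membrane_WT --n-frames 5000 --tau 50 --seed 7 --out syn
rasstates analyze --structure syn/model.pdb --trajectory syn/traj.dcd --out out
```

prints the pooled state fractions (one 5000-frame trajectory, mean dwell
50 frames):

```json
{
  "S1": 0.4904,
  "S2_OX": 0.424,
  "S2_OY": 0.0386,
  "S2_OZ": 0.047,
  "UNASSIGNED": 0.0
}
```

i.e. roughly half the frames are in state 1 and 2OX dominates state 2, as
expected for membrane-bound wild type (a single short trajectory carries
substantial sampling noise; occupancies converge when pooling runs).
`out/` additionally contains `features.csv` (per-frame distances and
reaction coordinates), `labels.csv`, `transitions.csv`, per-state
`rmsf_*.csv` / `pca_*` / `dccm_*` files, `rc_histogram.txt`, an
`ion_summary.json` such as

```json
"S2_OX": {"mean": 0.424, "sd": 0.638, "n": 2120}
```

(mean Na⁺ within 4.5 Å of the GTP over 2OX frames), and a `manifest.json`
with a checksum of every output.  `rasstates compare out_a/occupancy.json
out_b/occupancy.json` tabulates per-state deltas and ratios (e.g. the
OY fold-change between genotypes).

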