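# cdrflex

Trajectory post-processing for CDR-loop flexibility and protein–protein
interface analysis, built around the TREM2–ApoE system.

TREM2 is a microglial receptor whose Ig-like ectodomain binds ligands —
notably apolipoprotein E (ApoE) — through its complementarity-determining
region (CDR) loops. The disease-associated R47H variant rigidifies CDR2,
and ApoE isoforms (E2/E3/E4) present different hinge-region interfaces.
Characterising this quantitatively from molecular-dynamics trajectories
requires a specific chain of computations, which this package implements
as a tested, reusable library with a CLI:

* **Loop-distance metrics** — per-frame Cα–Cα distances between anchor
  residues: *Loop 1* (R46–L71) measures how far CDR2 extends from the
  Ig-like domain, *Loop 2* (H67–W78) its internal shape, plus the OLS
  regression of Loop 2 on Loop 1 (slope, intercept, R²).
* **SD-threshold conformational clustering** — with pooled per-variant
  statistics (μ, σ) of Loop 1, each frame is labelled
  **A** (d > μ+σ), **B** (μ−σ ≤ d ≤ μ+σ) or **C** (d < μ−σ);
  cluster representatives are medoids under pairwise superposed Cα RMSD.
* **RMSD/RMSF** — Kabsch least-squares superposition (SVD, reflection
  corrected), per-frame RMSD and per-residue RMSF about a fixed
  reference structure.
* **Ramachandran secondary-structure counting** — backbone (φ, ψ)
  torsions classified into β-strand and right/left-handed helix regions,
  counted per frame over named residue regions.
* **Docking-model selection filter** — fraction of CDR residues
  (CDR1 aa40–47, CDR2 aa67–78, CDR3 aa115–120; 26 residues) with any
  heavy atom within 4.0 Å of ApoE hinge residues (aa167–231); candidate
  poses are ranked by this fraction, with artifact exclusions.
* **Cluster-resolved energy statistics** — per-frame interaction free
  energies over the 450–500 ns window (every 0.5 ns; 101 frames per
  complex, 1818 records over 18 complexes) are classified by Loop 1
  cluster, summarised per (variant, isoform, cluster), compared by
  two-way ANOVA (Type II SS) with Tukey–Kramer tests, reduced to
  occupancy-weighted ensemble energies
  ⟨ΔG⟩ = Σ_c n_c ΔG_c / Σ_c n_c and most-populated-cluster energies,
  and rank-compared against experimental affinities (Spearman ρ of
  −ΔG vs 1/K_D).

Because MD trajectories of this size are rarely redistributable, the
`synthetic_data` module generates inputs with the same statistical
structure (two-state open/closed loop dynamics with Gaussian jitter,
docked poses with an exact number of interface contacts, cluster-
conditional energy tables, canonical-motif dihedral sets), so the whole
pipeline runs and is validated end to end without the original data.

## Worked example

```python
import numpy as np
from cdrflex.synthetic_data import LoopDynamicsParams, generate_two_state_loop_trajectory
from cdrflex.geometry_metrics import pair_distance_series
from cdrflex.conformational_clustering import loop_stats, assign_clusters, cluster_occupancy

params = LoopDynamicsParams(mu_closed=10.0, mu_open=16.0, sigma=0.8,
                            switch_prob=0.01, n_frames=2000, seed=7)
traj, states = generate_two_state_loop_trajectory(params)
loop1 = pair_distance_series(traj, ("A", 10), ("A", 25))
stats = loop_stats([loop1], variant="WT")
occ = cluster_occupancy(assign_clusters(loop1, stats))
print(f"Loop 1: mean = {stats.mean:.2f} A, sd = {stats.sd:.2f} A over {stats.n_frames} frames")
for lab in "ABC":
    print(f"cluster {lab}: {occ[lab]['count']:4d} frames ({100*occ[lab]['fraction']:.1f}%)")
print(f"open-state fraction in the generator: {np.mean(states == 'open'):.3f}")
```

prints

```
Loop 1: mean = 13.96 A, sd = 2.97 A over 2000 frames
cluster A:  168 frames (8.4%)
cluster B: 1218 frames (60.9%)
cluster C:  614 frames (30.7%)
open-state fraction in the generator: 0.659
```

The trajectory spent about 66% of its frames in the open state, so the
pooled mean sits between the closed (10 Å) and open (16 Å) modes and the
bimodal spread gives σ ≈ 3 Å; the beyond-1σ clusters (A+C ≈ 39%) pick up
the state excursions plus the Gaussian-jitter tails, while B holds the
frames near the pooled mean.

The same analysis runs from the shell:

```
cdrflex all --out run_dir --seed 1        # full pipeline on synthetic inputs
cdrflex plan                              # sampling-design bookkeeping
cdrflex cluster --out run_dir             # re-run a single stage from run_dir
```

Stages exchange data only through files in the output directory
(`loop_metrics.csv`, `cluster_assignments.csv`, `energy_records.csv`,
`dock_selection.json`, `energy_stats.json`, `report.json`, …), so any
stage can be re-run in isolation.

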