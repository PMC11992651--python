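# Methods

This note documents the models, conventions and numerical choices
behind `cdrflex`, the parameters that matter, and what the synthetic
data does and does not establish about real trajectories.

## Structural model and PDB I/O

Structures are ordered atom lists in author numbering; a trajectory is
a stack of coordinate frames over one topology with strictly increasing
frame times (ns). Multi-model PDB (MODEL/ENDMDL blocks sharing one atom
ordering) is the trajectory interchange format. The parser enforces the
fixed-column PDB layout and reports the offending line number on
malformed fields; insertion codes are rejected (the analysis targets
renumbered simulation constructs, which never carry them), and for
alternate locations the first-seen altloc per atom site is kept.
Hydrogens are parsed but excluded from heavy-atom selections.

Region schemes name residue-range sets: the TREM2 CDR loops
(CDR1 aa40–47, CDR2 aa67–78, CDR3 aa115–120), the ApoE canonical hinge
(aa167–191), the extended hinge (aa192–231) and their union
(`hinge_full`, aa167–231) used by the docking filter. Residue numbering
conventions differ between deposited structures and expression
constructs, so schemes carry an explicit per-chain offset (default 0)
rather than renumbering structures. Regions may be chain-qualified or
chain-agnostic; selections skip (and report) residues absent from the
structure and warn on an empty intersection instead of failing, since a
truncated construct is a legitimate input.

## Geometry

* **Loop distances** are plain per-frame Euclidean Cα–Cα distances; no
  superposition, since the metric is internal to the frame.
* **Superposition** is the Kabsch algorithm via SVD of the weighted
  covariance, with the reflection corrected by sign-flipping the
  smallest singular direction, so the rotation is always proper.
  Weights are uniform over the selection by default. Degenerate point
  sets (fewer than 3 points, collinear) are rejected. The test suite
  cross-checks the minimum against Horn's quaternion closed form and
  `scipy`'s rotation alignment.
* **RMSD** is computed per frame over the selection Cαs after an
  optional (default on) Kabsch fit.
* **RMSF** is the per-residue root-mean-square displacement from a
  *fixed reference structure* (the energy-minimised starting structure
  of a simulation), after per-frame Kabsch fitting of the selection
  onto that reference. Fluctuation about the trajectory mean — the more
  common convention — is available with `reference="mean"`; the fixed-
  reference form is the package default because it is the quantity the
  downstream flexibility comparison is defined on. The two differ by
  the displacement of the mean from the reference, so fixed-reference
  RMSF is systematically the larger.
* **Torsions** use the standard atan2 construction with the IUPAC
  sign convention (right-handed positive, trans = 180°), range
  (−180°, 180°]. φ(i) = C(i−1)–N(i)–CA(i)–C(i);
  ψ(i) = N(i)–CA(i)–C(i)–N(i+1). Termini and residues with missing
  backbone atoms yield absent values with a per-residue report; no
  residue types are excluded.
* **Ramachandran motif regions** are rectangles chosen to contain the
  canonical motif angles with ≥ 20° margins while staying pairwise
  disjoint: right-handed helix φ ∈ [−100, −30), ψ ∈ [−80, −5);
  left-handed helix φ ∈ (30, 100], ψ ∈ (5, 80]; β-strand
  φ ∈ [−180, −45), ψ ∈ [90, 180] ∪ [−180, −150). Anything else is
  `other`. Dihedral-region counting is deliberately simple — no
  hydrogen-bond-pattern (DSSP-style) assignment — because the counted
  quantity is defined on the (φ, ψ) plane.
* **Loop regression** is OLS with intercept; r² = 1 − SS_res/SS_tot.
  Constant response is given slope 0 and r² = 0 by convention; constant
  predictor is an error (undefined slope).

## Conformational clustering

Loop 1 statistics are pooled over **all frames of all replicates of a
variant** (SD with the n−1 denominator). Pooling, rather than
per-replicate thresholds, is what makes the cluster labels comparable
across replicates of a variant — a single (μ−σ, μ+σ) threshold pair per
variant. Labels: A strictly above μ+σ, C strictly below μ−σ, B
otherwise; values exactly at a threshold are "within" and go to B. A
zero SD degenerates to all-B with a warning.

The representative structure of a frame set is the **medoid**: the
frame minimising summed pairwise superposed Cα RMSD to the other
members, ties broken by the earliest frame. This is a deterministic
criterion chosen over neighbour-counting trajectory clustering (which
needs a cutoff choice); a gromos-style RMSD-linkage mode is provided
for comparison. In the pipeline, medoid sets larger than 40 frames are
evenly subsampled before the quadratic pairwise computation; the
problem sizes in the shipped configurations keep this stage under a
second.

## Interface analysis

Contact maps store the minimum inter-residue atom-pair distance, by
default over heavy atoms (crystal structures lack most hydrogens, and
heavy-atom "within" matches the usual visualisation-tool semantics);
Cα-only and all-atom modes exist. Contacts are pairs at or below the
cutoff (inclusive). The docking filter scores a pose by the fraction of
CDR residues (26 when all three loops are present) with at least one
heavy atom within 4.0 Å of any hinge-span residue; models are ranked by
fraction (stable sort, ties by model id) and the top non-excluded model
is selected. Artifact exclusion ("spuriously interconnected loops") was
a visual judgement in practice, so exclusions are taken as input flags
rather than detected. Literature-residue agreement is reported as
intersection count and Jaccard index.

## Energy statistics

Energies are consumed from per-frame tables (time, complex identity,
ΔG in kcal/mol); the end-state free-energy solver that produces them is
out of scope, replaced by a documented CSV contract. The analysis
window is an inclusive arithmetic grid — (450, 500, 0.5) ns gives 101
frames per complex, hence 1818 records over 18 complexes and 909 per
receptor variant — and the energy and loop-metric time grids must agree
exactly (mismatches are alignment errors listing the offending times).

Group comparisons use two-way ANOVA with **Type II sums of squares**,
appropriate for the unbalanced cluster-occupancy design (cluster sizes
are data, not design); the interaction term is dropped when empty cells
make it unestimable. Pairwise comparisons are Tukey–Kramer (pooled MSE
with per-pair harmonic sample sizes, studentized-range reference
distribution). SEM is reported alongside SD because the single-point
energy comparisons are plotted with standard errors. The ensemble
energy of a complex is the occupancy-weighted cluster mean, which is
algebraically the record-wise mean — the identity is asserted in the
tests to 1e-12. The most-populated (MP) cluster is the one with the
largest frame count, ties broken towards the lower mean energy (a tie
means the occupancy signal is uninformative, so the energetically
dominant conformation is the defensible representative). Rank
concordance with experiments is Spearman's ρ between −ΔG and 1/K_D;
experimental K_D values are user inputs, not package constants.

## Synthetic data: what it emulates, and what it does not

* **Two-state loop trajectories**: a Cα-only toy Ig-like domain (rigid
  20-residue core ring, 12-residue loop) whose loop block is rigidly
  translated along a fixed axis so the anchor-pair distance equals
  `state_mean(t) + N(0, σ²)` *exactly*; the hidden state follows a
  symmetric two-state Markov chain. Defaults — μ_closed = 10 Å,
  μ_open = 16 Å, σ = 0.8 Å, switch probability 0.01/frame, 0.5 ns/frame
  — put the state separation at 7.5σ (well past the 4σ needed for SD
  thresholds to track the states), sit the closed distance near a
  crystal-like loop separation, and make switching rare on the frame
  timescale, mirroring stochastic open/closed loop dynamics. Dwell
  lengths are geometric with mean 1/p; long-run occupancy is 1/2.
* **Energy tables**: per-cluster Gaussian energies with exact requested
  occupancies, each frame paired with a loop distance constructed to
  map back to its generating cluster under the threshold rule — so
  downstream classification must recover the labels with zero
  mismatches.
* **Docked poses**: two chains (CDR-numbered query, hinge-numbered
  target), one Cα plus one pseudo side-chain heavy atom per residue;
  exactly k query residues are placed within the cutoff and the rest at
  least cutoff + 2 Å away, so the contact fraction k/n is exact ground
  truth.
* **Dihedral sets**: canonical motif angles (−57, −47), (57, 47),
  (−120, 135) plus bounded uniform jitter; jitter beyond the 20° region
  margin triggers a warning.

All generators are pure functions of (parameters, seed) with one
explicit RNG stream per call; no global RNG state.

What passing on synthetic data shows: the bookkeeping, thresholds,
estimators and tests behave exactly as specified under the assumed
statistical structure. What it does not show: anything about force
fields, sampling convergence, solvent effects, side-chain packing or
the biological claims themselves — real trajectories are bimodal only
approximately, their jitter is neither Gaussian nor i.i.d., and real
interfaces are not constructed with a known contact count.

A known property worth stating: with Gaussian jitter, the beyond-1σ
cluster occupancy (A+C) on two-state data equals the state occupancy
only up to the tail mass each state's jitter leaks past the pooled
thresholds (a systematic 2–5 percentage points depending on the state
split; exactly computable from the two-component mixture). The tests
check the clustering against this closed-form expectation, and against
raw state occupancy with the predicted leak included in the band.

## Pipeline

Stages (`simulate → loops → cluster → repstruct → dockselect →
contacts → energystats → ss → report`) exchange data only through
files in the output directory, so re-running any stage from the
persisted intermediates reproduces the end-to-end result; the report
records configuration, seeds and per-stage counts. Configuration is
TOML with every validation error collected (not fail-fast) and defaults
echoed; CLI flags override config values. Every random draw derives
from the single configured seed via per-stage, per-task seed sequences,
making same-config runs byte-identical. The shipped configurations use
scaled-down pre-docking trajectories (hundreds of frames per replicate)
— the analysis-window bookkeeping (101 frames/complex, 1818 records) is
independent of that choice, and all statistical checks are sized to
their own convergence requirements (e.g. 1e5 samples for the occupancy
law, 500 replications for the ANOVA null).

## Known limitations

* The PDB reader handles ATOM/HETATM/MODEL records only — no mmCIF, no
  compressed trajectory formats (XTC/DCD); those belong behind the same
  trajectory contract later.
* Ramachandran regions are configuration, not truth; boundary placement
  between motifs is conventional and alternative rectangles are
  legitimate.
* The docking filter evaluates poses it is given; it does not dock, and
  the optional artifact heuristics are deliberately not part of the
  selection path.
* Medoid subsampling beyond 40 members trades exactness of the
  representative for quadratic cost; the exact medoid is available by
  passing the full member set directly to `select_representative`.
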