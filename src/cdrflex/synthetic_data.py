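"""Synthetic inputs with the statistical structure the analysis assumes.

The study's trajectories are not deposited, so every downstream stage is
exercised on generated data that reproduces the relevant statistics:

* Cα trajectories of a toy Ig-like domain whose anchor-pair loop
  distance follows two-state (open/closed) Markov dynamics with
  Gaussian jitter — the stochastic loop-opening behaviour the loop
  metrics and SD-threshold clustering are built to detect;
* docked two-chain poses with an exact, known number of interface
  residues within a distance cutoff — ground truth for the contact
  filter;
* per-frame interaction-energy tables whose means differ by loop
  cluster — ground truth for the energy statistics;
* backbone dihedral sets drawn around canonical secondary-structure
  motifs — ground truth for Ramachandran counting.

All generators are pure functions of their parameters and seed; no
global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, Structure, Trajectory

__all__ = [
    "LoopDynamicsParams",
    "EnergyTableParams",
    "generate_two_state_loop_trajectory",
    "generate_gaussian_loop_series",
    "generate_energy_table",
    "generate_complex_pose",
    "generate_phi_psi_set",
    "CANONICAL_MOTIF_ANGLES",
    "CORE_SIZE",
    "LOOP_SIZE",
    "ANCHOR_CORE_RESIDUE",
    "ANCHOR_LOOP_RESIDUE",
]

# Toy Ig-like domain: a rigid 20-residue core plus a 12-residue mobile
# loop (the CDR2 stand-in).  Residues are Cα-only.
CORE_SIZE = 20
LOOP_SIZE = 12
# Anchor pair measured by the loop-extension metric: a core residue and
# a loop residue, mirroring an R46-L71-style Cα-Cα distance.
ANCHOR_CORE_RESIDUE = 10
ANCHOR_LOOP_RESIDUE = 25


@dataclass(frozen=True)
class LoopDynamicsParams:
    """Two-state loop dynamics: closed/open means with Gaussian jitter.

    Defaults emulate a loop whose closed state sits near the crystal
    distance and whose open state is well separated (|Δμ| = 7.5σ), with
    rare stochastic switching — the regime in which SD-threshold
    clustering recovers the hidden state.
    """

    mu_closed: float = 10.0   # Å
    mu_open: float = 16.0     # Å
    sigma: float = 0.8        # Å Gaussian jitter
    switch_prob: float = 0.01  # per-frame state-change probability
    n_frames: int = 1000
    dt: float = 0.5           # ns between frames
    seed: int = 0
    start_state: str = "closed"

    def __post_init__(self):
        if self.mu_open <= self.mu_closed:
            raise ValueError("mu_open must exceed mu_closed")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.start_state not in ("closed", "open"):
            raise ValueError("start_state must be 'closed' or 'open'")


@dataclass(frozen=True)
class EnergyTableParams:
    """Cluster-conditional energy distributions for one docked complex."""

    cluster_means: Mapping[str, float] = field(
        default_factory=lambda: {"A": -20.0, "B": -35.0, "C": -30.0}
    )
    cluster_sds: Mapping[str, float] = field(
        default_factory=lambda: {"A": 5.0, "B": 5.0, "C": 5.0}
    )
    occupancies: Mapping[str, int] = field(
        default_factory=lambda: {"A": 16, "B": 69, "C": 16}
    )
    seed: int = 0

    def __post_init__(self):
        keys = set(self.cluster_means)
        if set(self.cluster_sds) != keys or set(self.occupancies) != keys:
            raise ValueError("cluster_means/cluster_sds/occupancies keys must match")
        if any(sd <= 0 for sd in self.cluster_sds.values()):
            raise ValueError("cluster sds must be positive")
        if any((n < 0 or int(n) != n) for n in self.occupancies.values()):
            raise ValueError("occupancies must be non-negative integers")
        if sum(self.occupancies.values()) == 0:
            raise ValueError("occupancies must sum to a positive frame count")


def _toy_topology() -> tuple[Structure, np.ndarray]:
    """Base coordinates of the toy domain (closed-ish geometry).

    Core residues 1-20 sit on a ring of radius 6 Å in the z=0 plane;
    loop residues 21-32 form a short arc displaced along +x.  Returns
    the topology Structure and the base coordinate array.
    """
    coords = np.zeros((CORE_SIZE + LOOP_SIZE, 3))
    theta = np.linspace(0.0, 2 * np.pi, CORE_SIZE, endpoint=False)
    coords[:CORE_SIZE, 0] = 6.0 * np.cos(theta)
    coords[:CORE_SIZE, 1] = 6.0 * np.sin(theta)
    arc = np.linspace(-0.6, 0.6, LOOP_SIZE)
    coords[CORE_SIZE:, 0] = 12.0 + 2.0 * np.cos(arc)
    coords[CORE_SIZE:, 1] = 4.0 * np.sin(arc)
    coords[CORE_SIZE:, 2] = 1.5

    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            residue_name="GLY" if i >= CORE_SIZE else "ALA",
            chain_id="A",
            residue_number=i + 1,
            xyz=coords[i],
            element="C",
        )
        for i in range(CORE_SIZE + LOOP_SIZE)
    ]
    return Structure(atoms), coords


def generate_two_state_loop_trajectory(
    params: LoopDynamicsParams,
) -> tuple[Trajectory, np.ndarray]:
    """Simulate two-state loop opening on the toy Cα domain.

    The hidden state follows a symmetric two-state Markov chain with
    per-frame switch probability ``params.switch_prob``.  At frame t the
    loop block is rigidly translated along the (fixed) core-anchor →
    loop-anchor unit vector so that the anchor-pair Cα distance equals
    ``state_mean(t) + N(0, sigma²)`` exactly.

    Returns the trajectory and the hidden state labels per frame
    (``"closed"`` / ``"open"``).
    """
    topology, base = _toy_topology()
    rng = np.random.default_rng(params.seed)

    state = np.empty(params.n_frames, dtype=np.int8)
    state[0] = 0 if params.start_state == "closed" else 1
    switches = rng.random(params.n_frames - 1) < params.switch_prob
    for t in range(1, params.n_frames):
        state[t] = state[t - 1] ^ switches[t - 1]

    means = np.where(state == 0, params.mu_closed, params.mu_open)
    targets = means + rng.normal(0.0, params.sigma, size=params.n_frames)
    targets = np.maximum(targets, 0.1)  # physical distances stay positive

    anchor_core = base[ANCHOR_CORE_RESIDUE - 1]
    anchor_loop = base[ANCHOR_LOOP_RESIDUE - 1]
    axis = anchor_loop - anchor_core
    base_dist = float(np.linalg.norm(axis))
    axis = axis / base_dist

    frames = np.broadcast_to(base, (params.n_frames, *base.shape)).copy()
    shift = (targets - base_dist)[:, None] * axis[None, :]
    frames[:, CORE_SIZE:, :] += shift[:, None, :]

    times = params.dt * np.arange(params.n_frames)
    labels = np.where(state == 0, "closed", "open")
    return Trajectory(topology, frames, times), labels


def generate_gaussian_loop_series(
    mu: float, sigma: float, n: int, seed: int = 0
) -> np.ndarray:
    """i.i.d. N(mu, sigma²) loop-distance series (null model for occupancy laws)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(mu, sigma, size=n)


def generate_energy_table(
    params: EnergyTableParams,
    loop_stats: tuple[float, float],
    t_start: float = 450.0,
    dt: float = 0.5,
    complex_id: str = "synthetic",
    trem2_variant: str = "WT",
    trem2_conformation: str = "B",
    apoe_isoform: str = "E4",
) -> pd.DataFrame:
    """Per-frame energy table with cluster-consistent loop-distance values.

    For each cluster label, ``occupancies[label]`` frames draw energies
    from N(cluster_mean, sd²).  Each frame is paired with a loop
    distance guaranteed to map back to its generating label under the
    given ``loop_stats = (mean, sd)`` threshold rule (A strictly above
    mean+sd, B within, C strictly below mean−sd), so downstream
    classification recovers the labels exactly.
    """
    mean, sd = loop_stats
    if sd <= 0:
        raise ValueError("loop_stats sd must be positive")
    rng = np.random.default_rng(params.seed)

    rows = []
    for label in sorted(params.occupancies):
        n = int(params.occupancies[label])
        if n == 0:
            continue
        energies = rng.normal(params.cluster_means[label], params.cluster_sds[label], n)
        if label == "A":
            loop1 = mean + sd * rng.uniform(1.2, 3.0, n)
        elif label == "B":
            loop1 = mean + sd * rng.uniform(-0.9, 0.9, n)
        elif label == "C":
            loop1 = mean - sd * rng.uniform(1.2, 3.0, n)
        else:
            raise ValueError(f"unknown cluster label {label!r}")
        for e, l1 in zip(energies, loop1):
            rows.append((e, l1, label))
    rng.shuffle(rows)

    n_total = len(rows)
    times = t_start + dt * np.arange(n_total)
    table = pd.DataFrame(
        {
            "time_ns": times,
            "complex_id": complex_id,
            "trem2_variant": trem2_variant,
            "trem2_conformation": trem2_conformation,
            "apoe_isoform": apoe_isoform,
            "energy_kcal_mol": [r[0] for r in rows],
            "loop1_A": [r[1] for r in rows],
            "true_cluster": [r[2] for r in rows],
        }
    )
    return table


# CDR residue numbers in analysis order (CDR1 40-47, CDR2 67-78, CDR3
# 115-120: 26 residues total); hinge span numbering for the target chain.
_CDR_RESIDUE_NUMBERS = (
    list(range(40, 48)) + list(range(67, 79)) + list(range(115, 121))
)
_HINGE_FIRST_RESIDUE = 167


def generate_complex_pose(
    n_query_residues: int,
    k_in_contact: int,
    cutoff: float = 4.0,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """A docked two-chain pose with exactly ``k`` query residues in contact.

    Chain A carries ``n_query_residues`` residues numbered into the CDR
    ranges (at most 26); chain B carries a hinge-numbered target strand.
    Each residue has a Cα and one pseudo side-chain heavy atom.  The
    first ``k_in_contact`` query residues are placed with their
    side-chain atom strictly within ``cutoff`` of a target atom; the
    rest sit at least ``cutoff + 2`` Å from every target atom.
    """
    if not 0 <= k_in_contact <= n_query_residues:
        raise ValueError("need 0 <= k_in_contact <= n_query_residues")
    if n_query_residues > len(_CDR_RESIDUE_NUMBERS):
        raise ValueError(
            f"at most {len(_CDR_RESIDUE_NUMBERS)} query residues supported"
        )
    if n_query_residues < 1:
        raise ValueError("need at least one query residue")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(seed)

    n_target = max(n_query_residues, 8)
    spacing = 3.8
    atoms_b: list[AtomRecord] = []
    serial = 1
    for j in range(n_target):
        x = spacing * j
        atoms_b.append(AtomRecord(serial, "CA", "GLY", "B",
                                  _HINGE_FIRST_RESIDUE + j,
                                  np.array([x, 0.0, 0.0]), "C"))
        serial += 1
        atoms_b.append(AtomRecord(serial, "CB", "GLY", "B",
                                  _HINGE_FIRST_RESIDUE + j,
                                  np.array([x, 1.5, 0.0]), "C"))
        serial += 1

    contact_gap = cutoff * 0.7
    far_gap = cutoff + 2.0 + 1.5  # CB-to-plane margin keeps every atom pair clear
    atoms_a: list[AtomRecord] = []
    serial = 1
    for i, resnum in enumerate(_CDR_RESIDUE_NUMBERS[:n_query_residues]):
        x = spacing * (i % n_target)
        if i < k_in_contact:
            # side-chain atom a contact_gap above the nearest target CB
            cb = np.array([x, 1.5 + contact_gap, 0.0])
            ca = cb + np.array([0.0, 1.5, 0.0])
        else:
            jitter = rng.uniform(-0.3, 0.3)
            cb = np.array([x, 1.5 + far_gap + jitter, 0.0])
            ca = cb + np.array([0.0, 1.5, 0.0])
        atoms_a.append(AtomRecord(serial, "CA", "ALA", "A", resnum, ca, "C"))
        serial += 1
        atoms_a.append(AtomRecord(serial, "CB", "ALA", "A", resnum, cb, "C"))
        serial += 1

    return Structure(atoms_a), Structure(atoms_b)


CANONICAL_MOTIF_ANGLES: dict[str, tuple[float, float]] = {
    "rh_helix": (-57.0, -47.0),
    "lh_helix": (57.0, 47.0),
    "beta": (-120.0, 135.0),
}

# Margin (deg) by which each canonical angle clears its motif-region
# boundary under the classifier's default rectangles; jitter beyond this
# can cross a boundary.
_SAFE_JITTER_DEG = 20.0


def generate_phi_psi_set(
    composition: Mapping[str, int],
    jitter_deg: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Backbone (φ, ψ) pairs around canonical motif angles, with labels.

    ``composition`` maps motif name (``rh_helix``, ``lh_helix``,
    ``beta``) to a count.  Each pair is the canonical motif angle plus
    independent uniform jitter in [−jitter_deg, +jitter_deg].  Jitter
    large enough to cross a motif-region boundary emits a warning.
    """
    import warnings

    if jitter_deg < 0:
        raise ValueError("jitter_deg must be non-negative")
    if jitter_deg > _SAFE_JITTER_DEG:
        warnings.warn(
            f"jitter {jitter_deg}° exceeds the {_SAFE_JITTER_DEG}° margin of the "
            "default motif regions; generated angles may cross boundaries",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    angles: list[tuple[float, float]] = []
    labels: list[str] = []
    for motif in sorted(composition):
        if motif not in CANONICAL_MOTIF_ANGLES:
            raise ValueError(f"unknown motif {motif!r}")
        n = int(composition[motif])
        phi0, psi0 = CANONICAL_MOTIF_ANGLES[motif]
        jit = rng.uniform(-jitter_deg, jitter_deg, size=(n, 2)) if jitter_deg else np.zeros((n, 2))
        for d in jit:
            angles.append((phi0 + d[0], psi0 + d[1]))
            labels.append(motif)
    return np.asarray(angles, dtype=float).reshape(-1, 2), labels
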