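"""SD-threshold conformational clustering on the loop-extension metric.

Frames are partitioned by the pooled per-variant Loop 1 statistics into
three clusters: A (more than one standard deviation above the mean),
B (within mean ± one SD, boundaries inclusive), and C (more than one SD
below the mean).  The representative structure of a frame set is its
medoid under pairwise superposed Cα RMSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry_metrics import LoopMetricSeries, rmsd
from .structure_io import Residue, Trajectory, ca_coordinates

__all__ = [
    "LoopStats",
    "ClusterAssignment",
    "DegenerateClusteringWarning",
    "loop_stats",
    "assign_clusters",
    "cluster_occupancy",
    "select_representative",
    "gromos_cluster",
    "CLUSTER_LABELS",
]

CLUSTER_LABELS = ("A", "B", "C")


class DegenerateClusteringWarning(UserWarning):
    """Zero loop-distance variance: every frame lands in cluster B."""


@dataclass(frozen=True)
class LoopStats:
    """Pooled mean/SD of the loop-extension metric for one variant."""

    mean: float
    sd: float
    n_frames: int
    variant: str = ""

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")

    @property
    def upper(self) -> float:
        return self.mean + self.sd

    @property
    def lower(self) -> float:
        return self.mean - self.sd


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-frame A/B/C labels with the thresholds that produced them."""

    labels: np.ndarray  # array of "A"/"B"/"C"
    lower: float        # mean − sd
    upper: float        # mean + sd

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype="U1"))

    def __len__(self) -> int:
        return len(self.labels)

    def frames_in(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def loop_stats(series: Sequence[LoopMetricSeries] | Sequence[np.ndarray],
               variant: str = "") -> LoopStats:
    """Pooled mean and SD of Loop 1 over all replicates of one variant.

    All frames of all replicates are pooled into one sample; the SD uses
    the n−1 denominator.  A zero SD emits
    :class:`DegenerateClusteringWarning` (clustering would be all-B).
    """
    if not series:
        raise ValueError("need at least one series")
    arrays = [
        s.loop1 if isinstance(s, LoopMetricSeries) else np.asarray(s, float)
        for s in series
    ]
    pooled = np.concatenate(arrays)
    if len(pooled) < 2:
        raise ValueError("need at least two frames in total")
    sd = float(np.std(pooled, ddof=1))
    if sd == 0.0:
        warnings.warn(
            "loop distances have zero variance; cluster assignment is degenerate",
            DegenerateClusteringWarning,
            stacklevel=2,
        )
    return LoopStats(mean=float(np.mean(pooled)), sd=sd,
                     n_frames=len(pooled), variant=variant)


def assign_clusters(loop1: np.ndarray, stats: LoopStats) -> ClusterAssignment:
    """Label each frame A/B/C by the mean±SD thresholds.

    A: strictly above mean+sd; C: strictly below mean−sd; B otherwise —
    values exactly at a threshold are "within" and go to B.  With sd = 0
    every frame is B (with a warning).
    """
    values = np.asarray(loop1, float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("loop1 must be a non-empty 1-D array")
    if stats.sd == 0.0:
        warnings.warn(
            "sd is zero: assigning every frame to cluster B",
            DegenerateClusteringWarning,
            stacklevel=2,
        )
        labels = np.full(len(values), "B", dtype="U1")
        return ClusterAssignment(labels, stats.lower, stats.upper)
    labels = np.full(len(values), "B", dtype="U1")
    labels[values > stats.upper] = "A"
    labels[values < stats.lower] = "C"
    return ClusterAssignment(labels, stats.lower, stats.upper)


def cluster_occupancy(assignment: ClusterAssignment) -> dict[str, dict[str, float]]:
    """Counts and fractions per cluster label.

    Returns ``{label: {"count": int, "fraction": float}}`` over the
    fixed label set A/B/C; counts sum to the frame count and fractions
    to 1.
    """
    n = len(assignment)
    if n == 0:
        raise ValueError("empty assignment")
    out: dict[str, dict[str, float]] = {}
    for label in CLUSTER_LABELS:
        count = int(np.sum(assignment.labels == label))
        out[label] = {"count": count, "fraction": count / n}
    return out


def _pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between coordinate frames."""
    n = coords.shape[0]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rmsd(coords[i], coords[j], superpose=True)
    return mat


def select_representative(
    traj: Trajectory,
    member_frames: Sequence[int],
    selection: Sequence[Residue],
) -> int:
    """Medoid frame of a cluster: minimal summed pairwise Cα RMSD.

    Every member frame's selection Cαs are compared to every other
    member's after Kabsch superposition; the frame minimising the sum of
    RMSDs is returned, ties broken by the earliest frame index.
    """
    members = sorted(set(int(f) for f in member_frames))
    if not members:
        raise ValueError("member frame set is empty")
    if len(members) == 1:
        return members[0]
    coords = ca_coordinates(traj, list(selection))[members]
    mat = _pairwise_rmsd_matrix(coords)
    totals = mat.sum(axis=1)
    best = int(np.argmin(totals))  # argmin takes the first minimum: earliest frame
    return members[best]


def gromos_cluster(
    traj: Trajectory,
    selection: Sequence[Residue],
    cutoff: float,
    frames: Sequence[int] | None = None,
) -> list[list[int]]:
    """RMSD-linkage clustering (gromos-style) as an optional comparison mode.

    Repeatedly takes the frame with the most neighbours within
    ``cutoff`` RMSD as a cluster centre, removes the cluster, and
    recurses on the remainder.  This mirrors the common
    neighbour-counting trajectory clustering; it is a comparison tool,
    not the A/B/C assignment used by the main analysis.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    all_frames = list(range(traj.n_frames)) if frames is None else sorted(set(frames))
    coords = ca_coordinates(traj, list(selection))[all_frames]
    mat = _pairwise_rmsd_matrix(coords)
    remaining = set(range(len(all_frames)))
    clusters: list[list[int]] = []
    while remaining:
        rem = sorted(remaining)
        neighbor_counts = [
            sum(1 for j in rem if mat[i, j] <= cutoff) for i in rem
        ]
        centre = rem[int(np.argmax(neighbor_counts))]
        members = [j for j in rem if mat[centre, j] <= cutoff]
        clusters.append([all_frames[j] for j in members])
        remaining -= set(members)
    return clusters
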