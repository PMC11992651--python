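"""Core trajectory geometry.

Loop Cα–Cα distance series, least-squares rigid superposition (Kabsch),
RMSD/RMSF, backbone torsions, Ramachandran motif classification and
counting, and the inter-loop linear regression.

Conventions
-----------
* Distances in Å, times in ns, angles in degrees on (−180, 180].
* Torsion sign is IUPAC right-handed positive; trans = 180°.
* RMSF is computed about a fixed reference structure (the
  energy-minimised starting structure of a simulation), not about the
  trajectory mean; a mean-reference mode is available via
  ``reference="mean"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import (
    MissingAtomError,
    Residue,
    Structure,
    Trajectory,
    ca_coordinates,
)

__all__ = [
    "LoopMetricSeries",
    "SSCounts",
    "DegenerateGeometryError",
    "pair_distance_series",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "rmsf_profile",
    "dihedral",
    "phi_psi_series",
    "classify_ss",
    "count_ss_residues",
    "fit_linear",
]


class DegenerateGeometryError(ValueError):
    """Input geometry does not determine the requested quantity."""


@dataclass(frozen=True)
class LoopMetricSeries:
    """Per-frame Loop 1 / Loop 2 distances for one replicate."""

    times: np.ndarray   # ns
    loop1: np.ndarray   # Å; loop-extension metric (anchor pair 1)
    loop2: np.ndarray   # Å; loop-shape metric (anchor pair 2)
    variant: str = ""
    replicate: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, float)
        l1 = np.asarray(self.loop1, float)
        l2 = np.asarray(self.loop2, float)
        if not (len(t) == len(l1) == len(l2)):
            raise ValueError("times/loop1/loop2 lengths must match")
        if np.any(l1 < 0) or np.any(l2 < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "loop1", l1)
        object.__setattr__(self, "loop2", l2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "loop1_A": self.loop1,
                "loop2_A": self.loop2,
                "variant": self.variant,
                "replicate": self.replicate,
            }
        )


@dataclass(frozen=True)
class SSCounts:
    """Per-frame secondary-structure residue counts in a named region."""

    times: np.ndarray
    region: str
    counts: pd.DataFrame  # columns: beta, rh_helix, lh_helix (ints per frame)

    @property
    def window_means(self) -> pd.Series:
        """Mean residue count per motif over the analysis window."""
        return self.counts.mean(axis=0)


def _ca_pair(traj: Trajectory, res_a: tuple[str, int], res_b: tuple[str, int]) -> tuple[np.ndarray, np.ndarray]:
    residues = [traj.topology.residue(*res_a), traj.topology.residue(*res_b)]
    coords = ca_coordinates(traj, residues)
    return coords[:, 0, :], coords[:, 1, :]


def pair_distance_series(
    traj: Trajectory, res_a: tuple[str, int], res_b: tuple[str, int]
) -> np.ndarray:
    """Euclidean Cα–Cα distance per frame between two residues.

    Distances are frame-internal; no superposition is applied.
    """
    a, b = _ca_pair(traj, res_a, res_b)
    return np.linalg.norm(a - b, axis=1)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, transformed)`` with
    ``transformed = mobile @ rotation.T + translation``.  The rotation
    is proper (det = +1); reflections are corrected by sign-flipping the
    smallest singular vector.  Requires ≥3 non-collinear points.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition requires at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_m = w @ mobile
    mu_r = w @ reference
    pm = mobile - mu_m
    pr = reference - mu_r
    h = pm.T @ (pr * w[:, None])
    if np.linalg.matrix_rank(h, tol=1e-10) < 2:
        raise DegenerateGeometryError("point set is rank-deficient (collinear)")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = mu_r - rotation @ mu_m
    transformed = mobile @ rotation.T + translation
    return rotation, translation, transformed


def rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    superpose: bool = True,
) -> float:
    """RMSD between two conformations of the same point set (Å)."""
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    if superpose:
        _, _, coords_a = kabsch_superpose(coords_a, coords_b)
    return float(np.sqrt(np.mean(np.sum((coords_a - coords_b) ** 2, axis=1))))


def _selection_cas(
    traj: Trajectory, reference: Structure, selection: list[Residue]
) -> tuple[np.ndarray, np.ndarray]:
    if not selection:
        raise ValueError("selection is empty")
    traj_ca = ca_coordinates(traj, selection)
    ref_residues = [reference.residue(*r.key) for r in selection]
    ref_ca = np.asarray([r.atom("CA").xyz for r in ref_residues])
    return traj_ca, ref_ca


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    selection: list[Residue],
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame Cα RMSD (Å) of ``selection`` against the reference structure."""
    traj_ca, ref_ca = _selection_cas(traj, reference, selection)
    return np.array(
        [rmsd(traj_ca[t], ref_ca, superpose=superpose) for t in range(traj.n_frames)]
    )


def rmsf_profile(
    traj: Trajectory,
    reference: Structure | str,
    selection: list[Residue],
) -> np.ndarray:
    """Per-residue Cα fluctuation (Å) over the trajectory.

    Each frame's selection is Kabsch-fitted onto the reference, then the
    per-residue root-mean-square displacement from the reference
    position is taken over frames.  Pass ``reference="mean"`` to use the
    fitted-trajectory mean position instead of a fixed structure.
    """
    about_mean = isinstance(reference, str)
    if about_mean and reference != "mean":
        raise ValueError("reference must be a Structure or the string 'mean'")

    if about_mean:
        traj_ca = ca_coordinates(traj, selection)
        ref_ca = traj_ca[0]
    else:
        traj_ca, ref_ca = _selection_cas(traj, reference, selection)

    fitted = np.empty_like(traj_ca)
    for t in range(traj.n_frames):
        _, _, fitted[t] = kabsch_superpose(traj_ca[t], ref_ca)
    target = fitted.mean(axis=0) if about_mean else ref_ca
    sq = np.sum((fitted - target) ** 2, axis=2)  # (frames, residues)
    return np.sqrt(sq.mean(axis=0))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, (−180, 180]) through four points.

    Standard atan2 construction; positive is a right-handed rotation of
    the p3→p4 bond about p2→p3 viewed from p2, with trans = 180°.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("dihedral undefined for degenerate points")
    x = n1 @ n2
    y = (np.cross(n1, n2) @ b2) / b2n
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def phi_psi_series(
    traj: Trajectory, chain_id: str
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Backbone (φ, ψ) per frame and residue for one chain.

    φ(i) = C(i−1)–N(i)–CA(i)–C(i); ψ(i) = N(i)–CA(i)–C(i)–N(i+1).
    Chain termini and residues missing backbone atoms yield NaN; the
    second return value reports (residue_number, reason) for every
    absent angle source.

    Returns a long-form DataFrame with columns
    ``frame, time_ns, residue_number, phi, psi``.
    """
    chains = traj.topology.chains
    if chain_id not in chains:
        raise KeyError(f"no chain {chain_id!r} in topology")
    residues = chains[chain_id]
    atom_index = {
        (a.chain_id, a.residue_number, a.name): i
        for i, a in enumerate(traj.topology.atoms)
    }

    def idx(res: Residue, name: str) -> int | None:
        return atom_index.get((res.chain_id, res.residue_number, name))

    report: list[tuple[int, str]] = []
    rows = []
    for t in range(traj.n_frames):
        frame = traj.frames[t]
        for i, res in enumerate(residues):
            phi = np.nan
            psi = np.nan
            n_i, ca_i, c_i = idx(res, "N"), idx(res, "CA"), idx(res, "C")
            backbone_ok = None not in (n_i, ca_i, c_i)
            if not backbone_ok:
                if t == 0:
                    report.append((res.residue_number, "missing backbone atom"))
            else:
                if i > 0:
                    c_prev = idx(residues[i - 1], "C")
                    if c_prev is not None:
                        phi = dihedral(frame[c_prev], frame[n_i], frame[ca_i], frame[c_i])
                    elif t == 0:
                        report.append((res.residue_number, "preceding residue lacks C"))
                elif t == 0:
                    report.append((res.residue_number, "N-terminal: no phi"))
                if i < len(residues) - 1:
                    n_next = idx(residues[i + 1], "N")
                    if n_next is not None:
                        psi = dihedral(frame[n_i], frame[ca_i], frame[c_i], frame[n_next])
                    elif t == 0:
                        report.append((res.residue_number, "following residue lacks N"))
                elif t == 0:
                    report.append((res.residue_number, "C-terminal: no psi"))
            rows.append((t, traj.times[t], res.residue_number, phi, psi))
    table = pd.DataFrame(
        rows, columns=["frame", "time_ns", "residue_number", "phi", "psi"]
    )
    return table, report


def classify_ss(phi: float, psi: float) -> str:
    """Assign a (φ, ψ) pair to a secondary-structure motif.

    Regions (degrees): right-handed helix φ∈[−100,−30), ψ∈[−80,−5);
    left-handed helix φ∈(30,100], ψ∈(5,80]; β-strand φ∈[−180,−45),
    ψ∈[90,180]∪[−180,−150).  Everything else is ``"other"``.
    """
    if np.isnan(phi) or np.isnan(psi):
        return "other"
    if -100.0 <= phi < -30.0 and -80.0 <= psi < -5.0:
        return "rh_helix"
    if 30.0 < phi <= 100.0 and 5.0 < psi <= 80.0:
        return "lh_helix"
    if -180.0 <= phi < -45.0 and (90.0 <= psi <= 180.0 or -180.0 <= psi < -150.0):
        return "beta"
    return "other"


def count_ss_residues(
    angles: pd.DataFrame,
    region_residue_numbers: set[int] | None = None,
    region_name: str = "all",
) -> SSCounts:
    """Count region residues per motif and frame from a φ/ψ table.

    ``angles`` is the long-form output of :func:`phi_psi_series`.
    Residues with NaN angles count as no motif.  Returns per-frame
    integer counts plus the window means (the "true average" over the
    analysis window).
    """
    table = angles
    if region_residue_numbers is not None:
        table = table[table["residue_number"].isin(region_residue_numbers)]
    frames = sorted(angles["frame"].unique())
    motifs = ("beta", "rh_helix", "lh_helix")
    counts = np.zeros((len(frames), len(motifs)), dtype=int)
    if not table.empty:
        labels = [
            classify_ss(phi, psi)
            for phi, psi in zip(table["phi"].to_numpy(), table["psi"].to_numpy())
        ]
        lab_frame = pd.DataFrame({"frame": table["frame"].to_numpy(), "motif": labels})
        pivot = (
            lab_frame[lab_frame["motif"].isin(motifs)]
            .groupby(["frame", "motif"])
            .size()
            .unstack(fill_value=0)
        )
        for j, m in enumerate(motifs):
            if m in pivot.columns:
                for fi, f in enumerate(frames):
                    if f in pivot.index:
                        counts[fi, j] = pivot.loc[f, m]
    import warnings as _warnings

    if region_residue_numbers is not None and table.empty:
        _warnings.warn(
            f"region {region_name!r} matched no residues in the angle table",
            UserWarning,
            stacklevel=2,
        )
    times = (
        angles.drop_duplicates("frame").sort_values("frame")["time_ns"].to_numpy()
    )
    return SSCounts(
        times=times,
        region=region_name,
        counts=pd.DataFrame(counts, columns=list(motifs)),
    )


def fit_linear(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of y on x with intercept.

    Returns ``(slope, intercept, r_squared)`` with
    r² = 1 − SS_res/SS_tot.  Constant ``y`` gives slope 0 and r² = 0 by
    convention; constant ``x`` raises :class:`DegenerateGeometryError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 2:
        raise ValueError("need at least two points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise DegenerateGeometryError("x has zero variance; slope undefined")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0, float(y.mean()), 0.0
    ss_res = np.sum((y - (slope * x + intercept)) ** 2)
    return float(slope), float(intercept), float(1.0 - ss_res / ss_tot)
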