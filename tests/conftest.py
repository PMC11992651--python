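"""Shared fixtures and independent oracle helpers.

The oracle helpers here deliberately avoid the package's own code
paths: quaternion-based optimal-rotation RMSD (Horn's closed form),
NeRF backbone construction from target torsions, and brute-force
distance searches.
"""

from __future__ import annotations

import numpy as np
import pytest

from cdrflex.structure_io import AtomRecord, Structure, Trajectory


# ---------------------------------------------------------------------------
# structure builders

def make_ca_structure(positions, chain="A", start_resnum=1):
    """Cα-only structure from a list of xyz positions."""
    atoms = [
        AtomRecord(i + 1, "CA", "ALA", chain, start_resnum + i,
                   np.asarray(p, float), "C")
        for i, p in enumerate(positions)
    ]
    return Structure(atoms)


def make_ca_trajectory(frames, chain="A", dt=0.5):
    """Trajectory over a Cα-only topology from (n_frames, n_res, 3) coords."""
    frames = np.asarray(frames, float)
    topo = make_ca_structure(frames[0], chain=chain)
    return Trajectory(topo, frames, dt * np.arange(frames.shape[0]))


@pytest.fixture
def three_residue_structure():
    return make_ca_structure([[0, 0, 0], [3, 4, 0], [6, 0, 0]])


# ---------------------------------------------------------------------------
# quaternion (Horn) optimal-rotation RMSD oracle

def horn_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over proper rotations+translations, by Horn's
    quaternion closed form — independent of the SVD Kabsch route."""
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)
    s = p.T @ q
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    n = len(p)
    msd = (np.sum(p**2) + np.sum(q**2) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


# ---------------------------------------------------------------------------
# NeRF backbone construction (independent torsion oracle)

def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d with |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]):
    """Backbone N/CA/C coordinates for a chain with the given (φ, ψ).

    ω is fixed trans (180°).  Returns a list of (N, CA, C) coordinate
    triples, one per residue.  φ of the first residue and ψ of the last
    are not constructible and the supplied values there are ignored.
    """
    n_ca, ca_c, c_n = 1.458, 1.525, 1.329
    ang_n_ca_c, ang_ca_c_n, ang_c_n_ca = 111.2, 116.2, 121.7
    coords = [
        np.array([0.0, 0.0, 0.0]),                      # N1
        np.array([n_ca, 0.0, 0.0]),                     # CA1
    ]
    # C1 at the N-CA-C angle in the xy plane
    ang = np.radians(180.0 - ang_n_ca_c)
    coords.append(coords[1] + ca_c * np.array([np.cos(ang), np.sin(ang), 0.0]))
    for i in range(1, len(phi_psi)):
        psi_prev = phi_psi[i - 1][1]
        phi = phi_psi[i][0]
        n_prev, ca_prev, c_prev = coords[-3], coords[-2], coords[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, c_n, ang_ca_c_n, psi_prev)
        ca_i = _place_atom(ca_prev, c_prev, n_i, n_ca, ang_c_n_ca, 180.0)
        c_i = _place_atom(c_prev, n_i, ca_i, ca_c, ang_n_ca_c, phi)
        coords.extend([n_i, ca_i, c_i])
    return [tuple(coords[3 * i: 3 * i + 3]) for i in range(len(phi_psi))]


def backbone_structure(phi_psi, chain="A"):
    """Full-backbone Structure (N, CA, C per residue) from target torsions."""
    triples = build_backbone(phi_psi)
    atoms = []
    serial = 1
    for i, (n, ca, c) in enumerate(triples):
        for name, xyz in (("N", n), ("CA", ca), ("C", c)):
            atoms.append(AtomRecord(serial, name, "ALA", chain, i + 1,
                                    xyz, name[0]))
            serial += 1
    return Structure(atoms)


# ---------------------------------------------------------------------------
# two-state mixture closed form

def mixture_extreme_fraction(f_open, mu_closed, mu_open, sigma, lower, upper):
    """Expected beyond-1-SD fraction of a two-component Gaussian mixture.

    Closed form for the probability that a frame's loop distance falls
    above ``upper`` or below ``lower`` given the state occupancy and the
    per-state Gaussian jitter — the law the SD-threshold clustering is
    expected to follow on two-state data."""
    from scipy.stats import norm

    p_a = (f_open * norm.sf(upper, mu_open, sigma)
           + (1 - f_open) * norm.sf(upper, mu_closed, sigma))
    p_c = (f_open * norm.cdf(lower, mu_open, sigma)
           + (1 - f_open) * norm.cdf(lower, mu_closed, sigma))
    return p_a + p_c


# ---------------------------------------------------------------------------
# brute-force searches

def brute_force_contact_pairs(struct_a, sel_a, struct_b, sel_b, cutoff,
                              heavy_only=True):
    """All residue pairs with any atom pair within cutoff, O(atoms²)."""
    pairs = set()
    for ra in sel_a:
        atoms_a = [a for a in ra.atoms if (a.is_heavy or not heavy_only)]
        for rb in sel_b:
            atoms_b = [b for b in rb.atoms if (b.is_heavy or not heavy_only)]
            for a in atoms_a:
                for b in atoms_b:
                    if np.linalg.norm(a.xyz - b.xyz) <= cutoff:
                        pairs.add((ra.key, rb.key))
    return pairs
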