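"""Coarse-grained backbone geometry kernels.

A residue carries five main-chain centres (N, amide H, CA, C, carbonyl O)
plus a single side-chain pseudo-atom written as CB.  Chains are built from
torsions by sequential natural-extension-of-reference-frame (NeRF)
placement with a fixed ideal-geometry table; torsions measured back from
the coordinates reproduce the inputs to well below 1e-6 degrees.

Atom layout: coordinates are stored as an (n_res, 6, 3) float64 array with
the atom order N, H, CA, C, O, CB (indices in ``ATOM_ORDER``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._nerf import place_scalar

ATOM_ORDER = ("N", "H", "CA", "C", "O", "CB")
AT_N, AT_H, AT_CA, AT_C, AT_O, AT_CB = range(6)

# Ideal bond lengths (Angstrom) and angles (degrees), Engh-Huber style.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.500  # pseudo side-chain centre offset

ANG_N_CA_C = 111.2
ANG_CA_C_N = 116.2
ANG_C_N_CA = 121.7
ANG_CA_C_O = 120.8
ANG_C_N_H = 119.0
ANG_N_CA_CB = 110.4
DIH_C_N_CA_CB = -122.6  # improper fixing L-chirality of the pseudo-atom

# Steric radii (Angstrom) for the coarse atom set; the pseudo-atom uses
# the Val side-chain value.
RADII = {"N": 1.55, "H": 1.00, "CA": 1.90, "C": 1.70, "O": 1.40, "CB": 2.00}
PSEUDO_ATOM_RADIUS = RADII["CB"]

_DEG = np.pi / 180.0


@njit(cache=True, fastmath=True)
def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.empty(3)
    n1[0] = b0[1] * b1[2] - b0[2] * b1[1]
    n1[1] = b0[2] * b1[0] - b0[0] * b1[2]
    n1[2] = b0[0] * b1[1] - b0[1] * b1[0]
    n2 = np.empty(3)
    n2[0] = b1[1] * b2[2] - b1[2] * b2[1]
    n2[1] = b1[2] * b2[0] - b1[0] * b2[2]
    n2[2] = b1[0] * b2[1] - b1[1] * b2[0]
    b1n = np.sqrt(b1[0] * b1[0] + b1[1] * b1[1] + b1[2] * b1[2])
    m1 = np.empty(3)
    m1[0] = (n1[1] * b1[2] - n1[2] * b1[1]) / b1n
    m1[1] = (n1[2] * b1[0] - n1[0] * b1[2]) / b1n
    m1[2] = (n1[0] * b1[1] - n1[1] * b1[0]) / b1n
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    y = m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]
    ang = -np.arctan2(y, x) / _DEG
    if ang <= -180.0:
        ang += 360.0
    return ang


@njit(cache=True, fastmath=True)
def build_coords(torsions, coords, start):
    """(Re)build coordinates from residue ``start`` to the end of the chain.

    ``torsions`` is (n, 3): per-residue (phi, psi, omega); phi of residue 0
    and psi/omega of the last residue still parameterise derived-atom
    placement but do not move main-chain atoms.  ``coords`` is (n, 6, 3)
    and is modified in place from ``start`` onwards (earlier residues are
    required to be valid when start > 0).
    """
    n = torsions.shape[0]
    if n == 0:
        return
    if start == 0:
        # canonical frame for residue 0
        coords[0, AT_N, 0] = 0.0
        coords[0, AT_N, 1] = 0.0
        coords[0, AT_N, 2] = 0.0
        coords[0, AT_CA, 0] = BOND_N_CA
        coords[0, AT_CA, 1] = 0.0
        coords[0, AT_CA, 2] = 0.0
        ang = ANG_N_CA_C * _DEG
        coords[0, AT_C, 0] = BOND_N_CA - BOND_CA_C * np.cos(ang)
        coords[0, AT_C, 1] = BOND_CA_C * np.sin(ang)
        coords[0, AT_C, 2] = 0.0
    first = start if start > 0 else 1
    for i in range(first, n):
        x, y, z = place_scalar(
            coords[i - 1, AT_N, 0], coords[i - 1, AT_N, 1],
            coords[i - 1, AT_N, 2],
            coords[i - 1, AT_CA, 0], coords[i - 1, AT_CA, 1],
            coords[i - 1, AT_CA, 2],
            coords[i - 1, AT_C, 0], coords[i - 1, AT_C, 1],
            coords[i - 1, AT_C, 2],
            BOND_C_N, ANG_CA_C_N, torsions[i - 1, 1])  # psi(i-1)
        coords[i, AT_N, 0] = x
        coords[i, AT_N, 1] = y
        coords[i, AT_N, 2] = z
        x, y, z = place_scalar(
            coords[i - 1, AT_CA, 0], coords[i - 1, AT_CA, 1],
            coords[i - 1, AT_CA, 2],
            coords[i - 1, AT_C, 0], coords[i - 1, AT_C, 1],
            coords[i - 1, AT_C, 2],
            coords[i, AT_N, 0], coords[i, AT_N, 1], coords[i, AT_N, 2],
            BOND_N_CA, ANG_C_N_CA, torsions[i - 1, 2])  # omega(i-1)
        coords[i, AT_CA, 0] = x
        coords[i, AT_CA, 1] = y
        coords[i, AT_CA, 2] = z
        x, y, z = place_scalar(
            coords[i - 1, AT_C, 0], coords[i - 1, AT_C, 1],
            coords[i - 1, AT_C, 2],
            coords[i, AT_N, 0], coords[i, AT_N, 1], coords[i, AT_N, 2],
            coords[i, AT_CA, 0], coords[i, AT_CA, 1], coords[i, AT_CA, 2],
            BOND_CA_C, ANG_N_CA_C, torsions[i, 0])  # phi(i)
        coords[i, AT_C, 0] = x
        coords[i, AT_C, 1] = y
        coords[i, AT_C, 2] = z
    # derived atoms (O, H, CB) for every rebuilt residue and the one before
    dstart = start - 1 if start > 0 else 0
    for i in range(dstart, n):
        # carbonyl O: trans to psi (anti to the next N)
        x, y, z = place_scalar(
            coords[i, AT_N, 0], coords[i, AT_N, 1], coords[i, AT_N, 2],
            coords[i, AT_CA, 0], coords[i, AT_CA, 1], coords[i, AT_CA, 2],
            coords[i, AT_C, 0], coords[i, AT_C, 1], coords[i, AT_C, 2],
            BOND_C_O, ANG_CA_C_O, torsions[i, 1] + 180.0)
        coords[i, AT_O, 0] = x
        coords[i, AT_O, 1] = y
        coords[i, AT_O, 2] = z
        # amide H: anti to the preceding carbonyl (DSSP convention)
        if i > 0:
            cox = coords[i - 1, AT_C, 0] - coords[i - 1, AT_O, 0]
            coy = coords[i - 1, AT_C, 1] - coords[i - 1, AT_O, 1]
            coz = coords[i - 1, AT_C, 2] - coords[i - 1, AT_O, 2]
            f = BOND_N_H / np.sqrt(cox * cox + coy * coy + coz * coz)
            coords[i, AT_H, 0] = coords[i, AT_N, 0] + cox * f
            coords[i, AT_H, 1] = coords[i, AT_N, 1] + coy * f
            coords[i, AT_H, 2] = coords[i, AT_N, 2] + coz * f
        else:
            x, y, z = place_scalar(
                coords[i, AT_C, 0], coords[i, AT_C, 1], coords[i, AT_C, 2],
                coords[i, AT_CA, 0], coords[i, AT_CA, 1],
                coords[i, AT_CA, 2],
                coords[i, AT_N, 0], coords[i, AT_N, 1], coords[i, AT_N, 2],
                BOND_N_H, ANG_C_N_H, 180.0)
            coords[i, AT_H, 0] = x
            coords[i, AT_H, 1] = y
            coords[i, AT_H, 2] = z
        # side-chain pseudo-atom, fixed chirality off the N-CA-C frame
        x, y, z = place_scalar(
            coords[i, AT_C, 0], coords[i, AT_C, 1], coords[i, AT_C, 2],
            coords[i, AT_N, 0], coords[i, AT_N, 1], coords[i, AT_N, 2],
            coords[i, AT_CA, 0], coords[i, AT_CA, 1], coords[i, AT_CA, 2],
            BOND_CA_CB, ANG_N_CA_CB, DIH_C_N_CA_CB)
        coords[i, AT_CB, 0] = x
        coords[i, AT_CB, 1] = y
        coords[i, AT_CB, 2] = z


@njit(cache=True, fastmath=True)
def measure_torsions(coords):
    """Measure (phi, psi, omega) per residue from an (n, 6, 3) array.

    Undefined entries (phi of residue 0; psi/omega of the last residue)
    are reported as 180.0 by convention.
    """
    n = coords.shape[0]
    t = np.full((n, 3), 180.0)
    for i in range(n):
        if i > 0:
            t[i, 0] = dihedral(coords[i - 1, AT_C], coords[i, AT_N],
                               coords[i, AT_CA], coords[i, AT_C])
        if i < n - 1:
            t[i, 1] = dihedral(coords[i, AT_N], coords[i, AT_CA],
                               coords[i, AT_C], coords[i + 1, AT_N])
            t[i, 2] = dihedral(coords[i, AT_CA], coords[i, AT_C],
                               coords[i + 1, AT_N], coords[i + 1, AT_CA])
    return t


def build_from_torsion_array(torsions: np.ndarray) -> np.ndarray:
    """Build a fresh (n, 6, 3) coordinate array from an (n, 3) torsion array."""
    torsions = np.ascontiguousarray(torsions, dtype=np.float64)
    n = torsions.shape[0]
    coords = np.zeros((n, 6, 3))
    build_coords(torsions, coords, 0)
    return coords


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Both are (m, 3) point sets in correspondence.  Returns the transformed
    copy of ``mobile`` and the RMSD after fitting.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (rot @ a.T).T + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b - tc) ** 2, axis=1))))
    return moved, rmsd


def apply_rigid(coords: np.ndarray, rotation: np.ndarray,
                translation: np.ndarray) -> np.ndarray:
    """Apply a rigid motion to an (n, 6, 3) coordinate array."""
    flat = coords.reshape(-1, 3)
    out = (rotation @ flat.T).T + translation
    return out.reshape(coords.shape)
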