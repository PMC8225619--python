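"""Cyclic coordinate descent (CCD) loop closure.

Torsions of a mobile chain segment are adjusted one bond at a time; each
rotation about an N-CA (phi) or CA-C (psi) axis takes the closed-form
angle that best superposes the three moving anchor atoms (N, CA, C of the
first fixed downstream residue) onto their target positions (Canutescu &
Dunbrack).  The kernel applies each rotation rigidly to all downstream
atoms, which is exactly equivalent to rebuilding the chain with the
changed torsion.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import geometry as geo


@njit(cache=True, fastmath=True)
def _ccd_kernel(torsions, coords, lo, hi, anchor, targets, mobile,
                max_iterations, tol):
    n_atoms = 6

    def _dev():
        acc = 0.0
        for m in range(3):
            at = geo.AT_N if m == 0 else (geo.AT_CA if m == 1 else geo.AT_C)
            for c in range(3):
                d = coords[anchor, at, c] - targets[m, c]
                acc += d * d
        return np.sqrt(acc / 3.0)

    dev = _dev()
    it = 0
    for it in range(1, max_iterations + 1):
        if dev < tol:
            break
        for r in range(lo, hi + 1):
            if not mobile[r - lo]:
                continue
            for tor_idx in range(2):
                if r == 0 and tor_idx == 0:
                    continue
                if tor_idx == 0:
                    ox, oy, oz = coords[r, geo.AT_N, 0], \
                        coords[r, geo.AT_N, 1], coords[r, geo.AT_N, 2]
                    ax = coords[r, geo.AT_CA, 0] - ox
                    ay = coords[r, geo.AT_CA, 1] - oy
                    az = coords[r, geo.AT_CA, 2] - oz
                else:
                    ox, oy, oz = coords[r, geo.AT_CA, 0], \
                        coords[r, geo.AT_CA, 1], coords[r, geo.AT_CA, 2]
                    ax = coords[r, geo.AT_C, 0] - ox
                    ay = coords[r, geo.AT_C, 1] - oy
                    az = coords[r, geo.AT_C, 2] - oz
                norm = np.sqrt(ax * ax + ay * ay + az * az)
                ax /= norm
                ay /= norm
                az /= norm
                # closed-form optimal angle over the 3 anchor atoms
                num = 0.0
                den = 0.0
                for m in range(3):
                    at = geo.AT_N if m == 0 else \
                        (geo.AT_CA if m == 1 else geo.AT_C)
                    mx = coords[anchor, at, 0] - ox
                    my = coords[anchor, at, 1] - oy
                    mz = coords[anchor, at, 2] - oz
                    par = mx * ax + my * ay + mz * az
                    rx = mx - par * ax
                    ry = my - par * ay
                    rz = mz - par * az
                    rlen = np.sqrt(rx * rx + ry * ry + rz * rz)
                    if rlen < 1e-9:
                        continue
                    rhx, rhy, rhz = rx / rlen, ry / rlen, rz / rlen
                    shx = ay * rhz - az * rhy
                    shy = az * rhx - ax * rhz
                    shz = ax * rhy - ay * rhx
                    fx = targets[m, 0] - (ox + par * ax)
                    fy = targets[m, 1] - (oy + par * ay)
                    fz = targets[m, 2] - (oz + par * az)
                    num += (fx * shx + fy * shy + fz * shz) * rlen
                    den += (fx * rhx + fy * rhy + fz * rhz) * rlen
                if num == 0.0 and den == 0.0:
                    continue
                ang = np.arctan2(num, den)
                if abs(ang) < 1e-10:
                    continue
                ca, sa = np.cos(ang), np.sin(ang)
                # rotate everything downstream of the bond rigidly
                for rr in range(r, anchor + 1):
                    for at in range(n_atoms):
                        if rr == r:
                            if tor_idx == 0:
                                # phi moves C, O, CB of r
                                if at not in (geo.AT_C, geo.AT_O,
                                              geo.AT_CB):
                                    continue
                            else:
                                # psi moves only O of r
                                if at != geo.AT_O:
                                    continue
                        px = coords[rr, at, 0] - ox
                        py = coords[rr, at, 1] - oy
                        pz = coords[rr, at, 2] - oz
                        par = px * ax + py * ay + pz * az
                        wx = px - par * ax
                        wy = py - par * ay
                        wz = pz - par * az
                        cxx = ay * wz - az * wy
                        cxy = az * wx - ax * wz
                        cxz = ax * wy - ay * wx
                        coords[rr, at, 0] = ox + par * ax + wx * ca \
                            + cxx * sa
                        coords[rr, at, 1] = oy + par * ay + wy * ca \
                            + cxy * sa
                        coords[rr, at, 2] = oz + par * az + wz * ca \
                            + cxz * sa
                deg = ang * 180.0 / np.pi
                v = torsions[r, tor_idx] + deg
                if v > 180.0:
                    v -= 360.0
                elif v <= -180.0:
                    v += 360.0
                torsions[r, tor_idx] = v
        dev = _dev()
    return dev, it


def ccd_close(torsions: np.ndarray, segment, targets,
              max_iterations: int = 100, tol: float = 0.2,
              mobile_mask=None, coords_init=None):
    """Close a chain segment onto fixed anchor targets.

    Parameters
    ----------
    torsions : (n, 3) array
        Chain torsions through the anchor residue; modified copies are
        returned, the input is untouched.
    segment : (first, last)
        Inclusive 0-based residue range whose phi/psi may move.
    targets : (3, 3) array
        Target positions for N, CA, C of residue ``last + 1``.
    mobile_mask : bool array over the segment, optional
        Per-residue flag; False freezes that residue's phi/psi (used to
        keep helix torsions ideal while loops absorb closure).
    coords_init : (n, 6, 3) array, optional
        Existing coordinates; entries before ``first`` are kept fixed and
        the segment is (re)built outward from that anchor.  When omitted
        the whole chain is rebuilt from the torsions.

    Returns
    -------
    (torsions, coords, deviation, iterations)
        ``deviation`` is the RMS distance of the three anchor atoms from
        their targets after closure.
    """
    first, last = segment
    t = np.ascontiguousarray(np.array(torsions, dtype=float))
    n = t.shape[0]
    anchor = last + 1
    if anchor >= n:
        raise ValueError("segment must leave a downstream anchor residue")
    if coords_init is None:
        coords = geo.build_from_torsion_array(t)
    else:
        coords = np.ascontiguousarray(np.array(coords_init, dtype=float))
        geo.build_coords(t, coords, first)
    targets = np.ascontiguousarray(np.asarray(targets, dtype=float))
    if mobile_mask is None:
        mobile_mask = np.ones(last - first + 1, dtype=bool)
    mobile_mask = np.ascontiguousarray(np.asarray(mobile_mask, bool))
    dev, it = _ccd_kernel(t, coords, first, last, anchor, targets,
                          mobile_mask, max_iterations, tol)
    # resynchronise derived atoms with the final torsions
    geo.build_coords(t, coords, first)
    return t, coords, dev, it


def closure_feasible(anchor_gap: float, n_moving: int) -> bool:
    """Rough reachability test: the fully extended moving segment spans
    about 3.8 A per residue."""
    return anchor_gap <= 3.8 * (n_moving + 1)
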