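"""Allocation-free scalar NeRF placement kernel."""

import numpy as np
from numba import njit

_DEG = np.pi / 180.0


@njit(cache=True, fastmath=True, inline="always")
def place_scalar(ax, ay, az, bx, by, bz, cx, cy, cz,
                 bond, angle_deg, torsion_deg):
    """NeRF placement of atom d given a-b-c; returns (dx, dy, dz)."""
    ang = angle_deg * _DEG
    tor = torsion_deg * _DEG
    bcx = cx - bx
    bcy = cy - by
    bcz = cz - bz
    ilen = 1.0 / np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx *= ilen
    bcy *= ilen
    bcz *= ilen
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    ilen = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
    nx *= ilen
    ny *= ilen
    nz *= ilen
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * np.cos(ang)
    sa = bond * np.sin(ang)
    d1 = sa * np.cos(tor)
    d2 = sa * np.sin(tor)
    return (cx + d0 * bcx + d1 * mx + d2 * nx,
            cy + d0 * bcy + d1 * my + d2 * ny,
            cz + d0 * bcz + d1 * mz + d2 * nz)
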