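"""Shrake-Rupley accessible surface area over the coarse atom set."""

from __future__ import annotations

import numpy as np
from numba import njit

from . import geometry as geo

PROBE_RADIUS = 2.0     # Angstrom
DEFAULT_POINTS = 128


def sphere_points(n: int) -> np.ndarray:
    """Near-uniform unit-sphere points (Fibonacci spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


@njit(cache=True, fastmath=True)
def _atom_sasa(centers, radii, eval_idx, points, probe):
    m = eval_idx.shape[0]
    npts = points.shape[0]
    out = np.zeros(m)
    for k in range(m):
        a = eval_idx[k]
        ra = radii[a] + probe
        acc = 0
        for p in range(npts):
            px = centers[a, 0] + ra * points[p, 0]
            py = centers[a, 1] + ra * points[p, 1]
            pz = centers[a, 2] + ra * points[p, 2]
            free = True
            for b in range(centers.shape[0]):
                if b == a:
                    continue
                rb = radii[b] + probe
                dx = px - centers[b, 0]
                dy = py - centers[b, 1]
                dz = pz - centers[b, 2]
                if dx * dx + dy * dy + dz * dz < rb * rb:
                    free = False
                    break
            if free:
                acc += 1
        out[k] = 4.0 * np.pi * ra * ra * acc / npts
    return out


def atom_set(structure, residues):
    """Coarse atom centres and radii for a residue subset (all six
    centres per residue)."""
    residues = np.asarray(sorted(residues), dtype=np.int64)
    coords = structure.coords[residues].reshape(-1, 3)
    radii = np.tile(np.array([geo.RADII[a] for a in geo.ATOM_ORDER]),
                    len(residues))
    return residues, np.ascontiguousarray(coords), \
        np.ascontiguousarray(radii)


def residue_sasa(structure, eval_residues, context_residues,
                 probe: float = PROBE_RADIUS,
                 n_points: int = DEFAULT_POINTS) -> np.ndarray:
    """Accessible surface area per evaluated residue.

    The occluding atom set is ``eval_residues | context_residues``;
    areas are summed over the six coarse centres of each evaluated
    residue.
    """
    eval_residues = sorted(set(eval_residues))
    all_res = sorted(set(eval_residues) | set(context_residues))
    res_arr, centers, radii = atom_set(structure, all_res)
    pos = {r: k for k, r in enumerate(res_arr)}
    na = len(geo.ATOM_ORDER)
    eval_idx = np.concatenate(
        [np.arange(pos[r] * na, (pos[r] + 1) * na) for r in eval_residues]
    ).astype(np.int64)
    pts = np.ascontiguousarray(sphere_points(n_points))
    per_atom = _atom_sasa(centers, radii, eval_idx, pts, probe)
    return per_atom.reshape(len(eval_residues), na).sum(axis=1)
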