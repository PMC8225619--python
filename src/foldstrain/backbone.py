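"""Backbone structures, hydrogen bonds and secondary-structure assignment.

The chain model is deliberately coarse: five main-chain centres per
residue plus one side-chain pseudo-sphere.  Backbone hydrogen bonds are
scored with the Kabsch-Sander electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and a bond is reported where E falls below a (configurable) threshold of
-0.5 kcal/mol, keeping at most one bond per donor NH.  Secondary structure
follows a minimal DSSP: i->i+4 turns make helices, ladder bridges make
strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import geometry as geo
from .abego import classify_abego

KS_FACTOR = 0.084 * 332.0
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol; "formed" criterion
HBOND_CA_PREFILTER = 9.0    # Angstrom
SR_SEPARATION = 4           # |i-j| <= 4 -> short-range hydrogen bond
KINK_ANGLE_DEG = 25.0


@dataclass
class HBond:
    donor: int      # residue index (0-based) donating through NH
    acceptor: int   # residue index accepting at C=O
    energy: float   # kcal/mol, < 0
    separation: int = 0

    def __post_init__(self):
        self.separation = abs(self.donor - self.acceptor)


class BackboneStructure:
    """A coarse-grained backbone chain.

    Parameters
    ----------
    torsions : (n, 3) array
        Per-residue (phi, psi, omega) in degrees.
    coords : (n, 6, 3) array, optional
        Coordinates in the :mod:`foldstrain.geometry` atom order; rebuilt
        from the torsions when omitted.
    provenance : dict, optional
        Free-form tags (blueprint name, seed, build stage, ...).
    """

    def __init__(self, torsions, coords=None, provenance=None):
        self.torsions = np.ascontiguousarray(torsions, dtype=np.float64)
        if self.torsions.ndim != 2 or self.torsions.shape[1] != 3:
            raise ValueError("torsions must be (n, 3)")
        if coords is None:
            coords = geo.build_from_torsion_array(self.torsions)
        self.coords = np.ascontiguousarray(coords, dtype=np.float64)
        if self.coords.shape != (len(self.torsions), 6, 3):
            raise ValueError("coords must be (n, 6, 3)")
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.torsions)

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, geo.AT_CA, :]

    def measured_torsions(self) -> np.ndarray:
        return geo.measure_torsions(self.coords)

    def abego(self, extended: bool = True) -> list:
        t = self.torsions
        return [classify_abego(t[i, 0], t[i, 1], t[i, 2], extended)
                for i in range(len(t))]

    def transformed(self, rotation, translation) -> "BackboneStructure":
        return BackboneStructure(
            self.torsions.copy(),
            geo.apply_rigid(self.coords, np.asarray(rotation, float),
                            np.asarray(translation, float)),
            provenance=dict(self.provenance))

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(self.torsions.copy(), self.coords.copy(),
                                 dict(self.provenance))


def build_from_torsions(torsions, provenance=None) -> BackboneStructure:
    """Build a chain from (phi, psi, omega) triples with ideal geometry."""
    return BackboneStructure(np.asarray(torsions, float).reshape(-1, 3),
                             provenance=provenance)


@njit(cache=True, fastmath=True)
def _hbond_scan(coords, cutoff, prefilter):
    """Per-donor best Kabsch-Sander bond. Returns (n,) acceptor index
    (-1 when none) and (n,) energy arrays."""
    n = coords.shape[0]
    best_j = np.full(n, -1, dtype=np.int64)
    best_e = np.zeros(n)
    pre2 = prefilter * prefilter
    for i in range(1, n):  # residue 0 has no amide proton donor
        hi = coords[i, geo.AT_H]
        ni = coords[i, geo.AT_N]
        for j in range(n):
            if abs(i - j) < 2:
                continue
            d = coords[i, geo.AT_CA] - coords[j, geo.AT_CA]
            if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] > pre2:
                continue
            oj = coords[j, geo.AT_O]
            cj = coords[j, geo.AT_C]
            r_on = np.sqrt(np.sum((ni - oj) ** 2))
            r_ch = np.sqrt(np.sum((hi - cj) ** 2))
            r_oh = np.sqrt(np.sum((hi - oj) ** 2))
            r_cn = np.sqrt(np.sum((ni - cj) ** 2))
            if r_on < 2.2 or r_oh < 1.2:
                e = 0.0     # steric overlap, not a hydrogen bond
            else:
                e = KS_FACTOR * (1.0 / r_on + 1.0 / r_ch
                                 - 1.0 / r_oh - 1.0 / r_cn)
            if e < cutoff and e < best_e[i]:
                best_e[i] = e
                best_j[i] = j
    return best_j, best_e


def compute_hbonds(s: BackboneStructure,
                   cutoff: float = HBOND_ENERGY_CUTOFF,
                   prefilter: float = HBOND_CA_PREFILTER) -> list:
    """Detect backbone hydrogen bonds (one per donor, lowest energy)."""
    if len(s) < 2:
        return []
    best_j, best_e = _hbond_scan(s.coords, cutoff, prefilter)
    return [HBond(i, int(best_j[i]), float(best_e[i]))
            for i in range(len(s)) if best_j[i] >= 0]


def hbond_energy(s: BackboneStructure, donor: int, acceptor: int) -> float:
    """Kabsch-Sander energy of one directed donor->acceptor pair."""
    if donor == 0 or abs(donor - acceptor) < 2:
        return 0.0
    c = s.coords
    ni, hi = c[donor, geo.AT_N], c[donor, geo.AT_H]
    oj, cj = c[acceptor, geo.AT_O], c[acceptor, geo.AT_C]
    r = lambda a, b: float(np.linalg.norm(a - b))
    if r(ni, oj) < 2.2 or r(hi, oj) < 1.2:
        return 0.0          # steric overlap, not a hydrogen bond
    return KS_FACTOR * (1.0 / r(ni, oj) + 1.0 / r(hi, cj)
                        - 1.0 / r(hi, oj) - 1.0 / r(ni, cj))


@njit(cache=True, fastmath=True)
def _hbond_matrix_scan(coords, cutoff, prefilter):
    """Boolean matrix hb[i, j]: NH of i donates to C=O of j (all pairs
    below the energy cutoff, not only per-donor bests — DSSP keeps
    multiple bonds per residue)."""
    n = coords.shape[0]
    hb = np.zeros((n, n), dtype=np.bool_)
    pre2 = prefilter * prefilter
    for i in range(1, n):
        hi = coords[i, geo.AT_H]
        ni = coords[i, geo.AT_N]
        for j in range(n):
            if abs(i - j) < 2:
                continue
            d = coords[i, geo.AT_CA] - coords[j, geo.AT_CA]
            if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] > pre2:
                continue
            oj = coords[j, geo.AT_O]
            cj = coords[j, geo.AT_C]
            r_on = np.sqrt(np.sum((ni - oj) ** 2))
            r_ch = np.sqrt(np.sum((hi - cj) ** 2))
            r_oh = np.sqrt(np.sum((hi - oj) ** 2))
            r_cn = np.sqrt(np.sum((ni - cj) ** 2))
            if r_on < 2.2 or r_oh < 1.2:
                e = 0.0     # steric overlap, not a hydrogen bond
            else:
                e = KS_FACTOR * (1.0 / r_on + 1.0 / r_ch
                                 - 1.0 / r_oh - 1.0 / r_cn)
            if e < cutoff:
                hb[i, j] = True
    return hb


def _hbond_matrix(s: BackboneStructure, cutoff: float):
    """Boolean matrix hb[i, j]: NH of i donates to C=O of j."""
    return _hbond_matrix_scan(s.coords, cutoff, HBOND_CA_PREFILTER)


def assign_secondary_structure(s: BackboneStructure,
                               cutoff: float = HBOND_ENERGY_CUTOFF) -> str:
    """Minimal DSSP assignment: 'H' (alpha helix), 'E' (strand), 'L'.

    A 4-turn at i means NH(i+4) donates to CO(i); two consecutive turns
    make residues i+1..i+4 helical.  Ladder bridges (parallel or
    antiparallel, sequence separation >= 3) mark strand residues.
    """
    n = len(s)
    if n == 0:
        return ""
    hb = _hbond_matrix(s, cutoff)

    def bond(i, j):  # NH(j) -> CO(i), DSSP's Hbond(i, j)
        if 0 <= i < n and 0 <= j < n:
            return hb[j, i]
        return False

    ss = np.array(["L"] * n, dtype="U1")
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        turn4[i] = bond(i, i + 4)
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            helix[i + 1:i + 5] = True
    strand = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 3, n):
            par = (bond(i - 1, j) and bond(j, i + 1)) or \
                  (bond(j - 1, i) and bond(i, j + 1))
            anti = (bond(i, j) and bond(j, i)) or \
                   (bond(i - 1, j + 1) and bond(j - 1, i + 1))
            if par or anti:
                strand[i] = True
                strand[j] = True
    ss[strand] = "E"
    ss[helix] = "H"  # helix wins where both patterns hold
    return "".join(ss)


def fit_helix_axis(s: BackboneStructure, span) -> tuple:
    """Helix axis through the CA trace of a span (>= 4 residues).

    Interior chord bisectors (which point from each CA toward the axis)
    give the direction as the common perpendicular (smallest singular
    vector); the axis position comes from an algebraic circle fit of the
    CAs projected onto the normal plane.  Exact for noiseless ideal
    helices.  Returns (point_on_axis, unit_direction), direction N->C.
    """
    first, last = span
    m = last - first + 1
    if m < 4:
        raise ValueError("helix span must contain at least 4 residues")
    ca = s.ca[first:last + 1]
    bis = []
    for k in range(1, m - 1):
        v1 = ca[k - 1] - ca[k]
        v2 = ca[k + 1] - ca[k]
        b = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        nb = np.linalg.norm(b)
        if nb > 1e-9:
            bis.append(b / nb)
    bis = np.asarray(bis)
    _, _, vt = np.linalg.svd(bis)
    direction = vt[-1]
    if np.dot(direction, ca[-1] - ca[0]) < 0:
        direction = -direction
    # project CAs onto the plane normal to the axis, fit a circle (Kasa)
    e1 = np.cross(direction, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(direction, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    x = ca @ e1
    y = ca @ e2
    a_mat = np.column_stack([2 * x, 2 * y, np.ones(m)])
    rhs = x * x + y * y
    (cx, cy, _), *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    height = float(np.mean(ca @ direction))
    point = cx * e1 + cy * e2 + height * direction
    return point, direction


def helix_axis_segment(s: BackboneStructure, span) -> tuple:
    """Axis segment clipped to the helix extent (projection of end CAs)."""
    centroid, direction = fit_helix_axis(s, span)
    first, last = span
    t0 = float(np.dot(s.ca[first] - centroid, direction))
    t1 = float(np.dot(s.ca[last] - centroid, direction))
    lo, hi = min(t0, t1), max(t0, t1)
    return centroid + lo * direction, centroid + hi * direction


def detect_helix_kink(s: BackboneStructure, span,
                      angle_threshold: float = KINK_ANGLE_DEG,
                      ss: str | None = None, trim: int = 3) -> bool:
    """True if a designated helix span is kinked.

    Kinked means: any residue in the span interior (``trim`` residues
    ignored at each terminus) is not assigned 'H', or — for spans of
    >= 8 residues — the axes of the two half-spans diverge by more than
    the threshold.
    """
    first, last = span
    if ss is None:
        ss = assign_secondary_structure(s)
    inner = ss[first + trim:last - trim + 1]
    if any(c != "H" for c in inner):
        return True
    m = last - first + 1
    if m >= 12:
        # half-axes need >= 6 CA each; shorter fits see single-turn spiral
        # curvature as spurious bend
        mid = first + m // 2
        _, d1 = fit_helix_axis(s, (first, min(mid + 2, last)))
        _, d2 = fit_helix_axis(s, (max(mid - 2, first), last))
        cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
        if np.degrees(np.arccos(cosang)) > angle_threshold:
            return True
    return False
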