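"""Global backbone-strain metrics over ensembles.

Frustration between a blueprint and its global tertiary structure shows
up statistically in a sequence-independent backbone ensemble: designated
sheet hydrogen bonds that fail to form, and terminal helices that sit too
far apart to pack.  This module quantifies both, plus the beta-sheet bend
angle, and computes the two-pass averaged (and idealised) ensemble
structure.

Definitions
-----------
* P_i — formation probability of the i-th designated intra-sheet hydrogen
  bond across the ensemble (Kabsch-Sander energy below the formation
  cutoff), floored at 1/(2N) so the log is finite.
* formability F = sum_i ln P_i  (<= 0; 0 means every designated bond
  forms in every member).
* terminal-helix distance d — minimum distance between the fitted axis
  segments of the N- and C-terminal helices, clipped to their extents.
* packability = ln P(d < 11 A), the log ensemble probability that the
  terminal helices are close enough for side chains to pack (count
  floored at 1/2).
* bend angle — angle between the normals of least-squares planes fitted
  to the strand CA sets of the two halves of the sheet (split at the
  central strand, which belongs to both); 0 is flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .backbone import (BackboneStructure, helix_axis_segment, hbond_energy)
from .blueprint import Blueprint, SheetHBondTopology, sheet_hbond_topology


HBOND_FORMED_CUTOFF = -0.5   # kcal/mol Kabsch-Sander
PACKING_DISTANCE = 11.0      # Angstrom


@dataclass
class EnsembleMetrics:
    """Summary of the strain metrics for one ensemble."""
    blueprint: str
    n: int
    bond_probabilities: np.ndarray   # per designated bond, topology order
    formability: float               # sum of ln P_i, <= 0
    distances: np.ndarray            # terminal-helix distance per member
    packability: float               # ln P(d < threshold), <= 0
    bend_angles: np.ndarray          # degrees per member
    packing_threshold: float = PACKING_DISTANCE

    @property
    def median_distance(self) -> float:
        return float(np.median(self.distances))

    @property
    def mean_bend_angle(self) -> float:
        return float(np.mean(self.bend_angles))

    def summary(self) -> dict:
        return {
            "blueprint": self.blueprint,
            "N": self.n,
            "formability": self.formability,
            "packability": self.packability,
            "median_distance": self.median_distance,
            "mean_bend_angle": self.mean_bend_angle,
        }


def hbond_probabilities(ensemble, topology: SheetHBondTopology,
                        cutoff: float = HBOND_FORMED_CUTOFF) -> np.ndarray:
    """Per-designated-bond formation probabilities P_i.

    A bond counts as formed in a member when its Kabsch-Sander energy is
    below ``cutoff``.  Probabilities are floored at 1/(2N); excluded
    bonds (broken by construction in both experiment and simulation) are
    skipped and reported as NaN.
    """
    members = list(ensemble)
    n = len(members)
    if n == 0:
        raise ValueError("empty ensemble")
    out = np.empty(len(topology.bonds))
    for k, bond in enumerate(topology.bonds):
        if bond.excluded:
            out[k] = np.nan
            continue
        formed = sum(1 for m in members
                     if hbond_energy(m, bond.donor, bond.acceptor) < cutoff)
        out[k] = max(formed / n, 1.0 / (2 * n))
    return out


def formability(probabilities) -> float:
    """Sheet formability F = sum of ln P_i (natural log, <= 0)."""
    p = np.asarray(probabilities, dtype=float)
    p = p[~np.isnan(p)]
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    return float(np.sum(np.log(p)))


def terminal_helix_distance(s: BackboneStructure, bp: Blueprint) -> float:
    """Minimum distance between the clipped axis segments of the N- and
    C-terminal helices (A); symmetric and rigid-motion invariant."""
    span_n, span_c = bp.terminal_helix_spans()
    a0, a1 = helix_axis_segment(s, span_n)
    b0, b1 = helix_axis_segment(s, span_c)
    return _segment_distance(a0, a1, b0, b1)


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 3D segments."""
    u = p2 - p1
    v = q2 - q1
    w = p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        sc = (b * e - c * d) / denom
        tc = (a * e - b * d) / denom
    else:
        sc, tc = 0.0, e / c if c > 1e-12 else 0.0
    sc = min(max(sc, 0.0), 1.0)
    tc = min(max(tc, 0.0), 1.0)
    # clamped values may not be jointly optimal; refine once each way
    best = np.inf
    for s_ in (0.0, 1.0, sc):
        t_ = np.clip(((p1 + s_ * u - q1) @ v) / c if c > 1e-12 else 0.0,
                     0.0, 1.0)
        best = min(best, float(np.linalg.norm(p1 + s_ * u - (q1 + t_ * v))))
    for t_ in (0.0, 1.0, tc):
        s_ = np.clip(((q1 + t_ * v - p1) @ u) / a if a > 1e-12 else 0.0,
                     0.0, 1.0)
        best = min(best, float(np.linalg.norm(p1 + s_ * u - (q1 + t_ * v))))
    return best


def packability(ensemble, bp: Blueprint,
                threshold: float = PACKING_DISTANCE,
                distances=None) -> float:
    """ln of the ensemble probability that the terminal-helix distance is
    below ``threshold`` (count floored at 1/2)."""
    if distances is None:
        distances = [terminal_helix_distance(m, bp) for m in ensemble]
    distances = np.asarray(distances, dtype=float)
    n = len(distances)
    if n == 0:
        raise ValueError("empty ensemble")
    count = max(float(np.sum(distances < threshold)), 0.5)
    return float(np.log(count / n))


def sheet_bend_angle(s: BackboneStructure, bp: Blueprint) -> float:
    """Bend angle (degrees) between the two halves of the beta-sheet.

    Least-squares planes are fitted to the strand CA sets of the two
    sheet halves (split at the spatially central strand, which belongs
    to both); the reported angle is between the plane normals, in
    [0, 90], with 0 for a flat sheet.
    """
    order = bp.sheet_order()
    if len(order) < 3:
        raise ValueError("bend angle needs at least 3 strands")
    mid = len(order) // 2
    halves = (order[:mid + 1], order[mid:])
    normals = []
    for half in halves:
        pts = np.concatenate([
            s.ca[bp.element_span(e)[0]:bp.element_span(e)[1] + 1]
            for e in half])
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred)
        normals.append(vt[2])
    cosang = abs(float(np.dot(normals[0], normals[1])))
    return float(np.degrees(np.arccos(min(cosang, 1.0))))


def ensemble_metrics(ensemble, bp: Blueprint | None = None,
                     packing_threshold: float = PACKING_DISTANCE,
                     hbond_cutoff: float = HBOND_FORMED_CUTOFF
                     ) -> EnsembleMetrics:
    """All strain metrics for one ensemble."""
    bp = bp or ensemble.blueprint
    topo = sheet_hbond_topology(bp)
    probs = hbond_probabilities(ensemble, topo, cutoff=hbond_cutoff)
    if bp.terminal_helices is not None:
        dists = np.array([terminal_helix_distance(m, bp)
                          for m in ensemble])
        pack = packability(ensemble, bp, packing_threshold,
                           distances=dists)
    else:
        dists = np.full(len(ensemble), np.nan)
        pack = np.nan
    if len(bp.sheet_order()) >= 3:
        bends = np.array([sheet_bend_angle(m, bp) for m in ensemble])
    else:
        bends = np.full(len(ensemble), np.nan)
    return EnsembleMetrics(
        blueprint=bp.name, n=len(ensemble), bond_probabilities=probs,
        formability=formability(probs), distances=dists,
        packability=pack, bend_angles=bends,
        packing_threshold=packing_threshold)


@dataclass
class AveragedStructure:
    structure: BackboneStructure      # idealised averaged backbone
    mean_coords: np.ndarray           # raw mean main-chain coordinates
    spread: np.ndarray                # per-atom rms deviation from mean
    rmsd_to_mean: float               # CA rmsd of the idealised model


MAINCHAIN = (geo.AT_N, geo.AT_CA, geo.AT_C, geo.AT_O)


def average_structure(ensemble, seed: int = 0) -> AveragedStructure:
    """Two-pass superpose-and-average, then idealisation.

    Members are superposed onto a randomly chosen reference and averaged;
    the procedure repeats with the average as the reference.  The
    averaged backbone is then idealised: torsions measured from the mean
    coordinates are rebuilt with ideal bond lengths/angles and the
    rebuilt chain is superposed back onto the mean.
    """
    members = list(ensemble)
    if len(members) < 2:
        raise ValueError("averaging needs at least two members")
    n = len(members[0])
    if any(len(m) != n for m in members):
        raise ValueError("ensemble members differ in length")
    rng = np.random.default_rng(seed)
    ref_idx = int(rng.integers(len(members)))
    idx = list(MAINCHAIN)

    def mainchain(m):
        return m.coords[:, idx, :].reshape(-1, 3)

    ref = mainchain(members[ref_idx])
    for _ in range(2):
        acc = np.zeros_like(ref)
        for m in members:
            moved, _ = geo.kabsch_superpose(mainchain(m), ref)
            acc += moved
        ref = acc / len(members)
    mean = ref.reshape(n, len(idx), 3)
    spread = np.zeros((n, len(idx)))
    for m in members:
        moved, _ = geo.kabsch_superpose(mainchain(m), ref.reshape(-1, 3))
        spread += np.sum((moved.reshape(n, len(idx), 3) - mean) ** 2,
                         axis=2)
    spread = np.sqrt(spread / len(members))
    # idealise: measure torsions on the mean chain, rebuild, superpose
    full = np.zeros((n, 6, 3))
    for k, at in enumerate(idx):
        full[:, at, :] = mean[:, k, :]
    torsions = geo.measure_torsions(full)
    ideal = BackboneStructure(torsions)
    moved, _ = geo.kabsch_superpose(ideal.ca, mean[:, 1, :])
    rot, trans = _fit_rigid(ideal.ca, mean[:, 1, :])
    ideal = ideal.transformed(rot, trans)
    rmsd = float(np.sqrt(np.mean(
        np.sum((ideal.ca - mean[:, 1, :]) ** 2, axis=1))))
    return AveragedStructure(ideal, mean, spread, rmsd)


def _fit_rigid(mobile, target):
    """Rotation and translation of the least-squares rigid fit."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc
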