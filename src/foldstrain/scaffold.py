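"""Geometric initialisation of the designated beta-sheet.

Fragment-assembly Monte Carlo with synthetic per-bin fragments cannot, by
itself, discover the precisely phased hydrogen-bond ladders of a
five-strand sheet at useful rates: database fragment sets carry the
supersecondary geometry that makes that search tractable, synthetic
Gaussians do not.  The builder therefore seeds every trajectory with an
explicit geometric realisation of the blueprint's sheet: strand segments
are sampled from the fragment library, placed strand by strand in the
ideal ladder frame of their designated pairing (calibrated so all
designated hydrogen bonds form at physical energies), perturbed with
rigid-body noise, and connected through their loop-helix motifs by CCD
closure.  The Monte Carlo, relaxation and rebuild stages then sample
thermally around — and away from — this basin, which is where the strain
signal (broken designated bonds, unpackable helices) comes from.

Placement constants were calibrated once on ideal strands
(phi = -119, psi = 113): parallel ladders use a 5.2 A separation along
the amide direction with a -0.3 A axial offset; antiparallel ladders
5.45 A and +0.4 A.
"""

from __future__ import annotations

import numpy as np

from . import geometry as geo
from .backbone import BackboneStructure
from .blueprint import (Blueprint, PARALLEL, sheet_hbond_topology)
from .abego import bin_interval_arrays
from .ccd import ccd_close
from .fragments import FragmentLibrary

PAR_SEP, PAR_AX = 5.2, -0.3
ANTI_SEP, ANTI_AX = 5.45, 0.4
#: rigid-body placement noise: rotation sd (degrees) about the strand
#: axis and the ladder direction, and isotropic translation sd (A)
NOISE_ROT_SD = 5.0
NOISE_TRANS_SD = 0.25
CLOSURE_TOL = 0.6   # scaffold seams are re-zipped by the relaxation stage
CLOSURE_TRIES = 24


class ScaffoldError(RuntimeError):
    pass


def _wrap(t):
    t = (t + 180.0) % 360.0 - 180.0
    t[t == -180.0] = 180.0
    return t


def _strand_frame(coords, rung, use_nh=True):
    """Local ladder frame at a strand rung: unit axis u (N->C) and unit
    amide direction w (projected perpendicular to u)."""
    u = coords[rung + 1, geo.AT_CA] - coords[rung - 1, geo.AT_CA]
    u = u / np.linalg.norm(u)
    if use_nh:
        w = coords[rung, geo.AT_H] - coords[rung, geo.AT_N]
    else:
        w = coords[rung, geo.AT_O] - coords[rung, geo.AT_C]
    w = w - np.dot(w, u) * u
    return u, w / np.linalg.norm(w)


def _rotation_about(axis, angle_rad):
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0.0, -axis[2], axis[1]],
                  [axis[2], 0.0, -axis[0]],
                  [-axis[1], axis[0], 0.0]])
    return (np.eye(3) + np.sin(angle_rad) * k
            + (1.0 - np.cos(angle_rad)) * (k @ k))


def _interface_rungs(bp, topo, pairing_idx, from_elem, to_elem):
    """Aligned (i_on_from, j_on_to) rungs participating in an interface,
    recovered from the enumerated bond list (local 0-based indices)."""
    p = bp.pairings[pairing_idx]
    off = {p.strand_a: bp.element_offset(p.strand_a),
           p.strand_b: bp.element_offset(p.strand_b)}
    len_ = {p.strand_a: bp.elements[p.strand_a].length,
            p.strand_b: bp.elements[p.strand_b].length}
    rungs = set()
    for b in topo.bonds:
        if b.pairing != pairing_idx:
            continue
        # recover the aligned rung from either bond form
        da = b.donor - off[p.strand_a]
        db = b.donor - off[p.strand_b]
        aa = b.acceptor - off[p.strand_a]
        ab = b.acceptor - off[p.strand_b]
        if p.orientation == PARALLEL:
            if 0 <= da < len_[p.strand_a] and 0 <= ab < len_[p.strand_b]:
                rungs.add((da, ab + 1))          # NH_a(i) -> CO_b(j-1)
            elif 0 <= db < len_[p.strand_b] and 0 <= aa < len_[p.strand_a]:
                rungs.add((aa, db - 1))          # NH_b(j+1) -> CO_a(i)
        else:
            if 0 <= da < len_[p.strand_a] and 0 <= ab < len_[p.strand_b]:
                rungs.add((da, ab))
            elif 0 <= db < len_[p.strand_b] and 0 <= aa < len_[p.strand_a]:
                rungs.add((aa, db))
    rungs = sorted(rungs)
    if from_elem == p.strand_a:
        return rungs
    return sorted((j, i) for i, j in rungs)


def _sample_strand_torsions(bp, lib, torsions, rng):
    for ei in bp.strand_elements():
        a, b = bp.element_span(ei)
        for r in range(a, b + 1):
            frags = lib.fragments_at(r, 1)
            torsions[r] = frags[rng.integers(len(frags)), 0]


def _refine_closure(torsions, lo, hi, mobile, coords_init, targets,
                    tol=0.03, bins=None, bin_weight=0.008,
                    anchor_weight=0.002):
    """Polish a CCD closure to near-exact anchor match by least squares
    over the mobile phi/psi, so that rebuilding the chain from torsions
    reproduces the placed downstream geometry without a seam.  Optional
    weak flat-bottom residuals steer the solution toward the blueprint
    ABEGO bins within the closure manifold."""
    from scipy.optimize import least_squares

    anchor = hi + 1
    dims = [(r, tor) for r in range(lo, hi + 1) if mobile[r - lo]
            for tor in (0, 1)]
    scratch = coords_init.copy()
    work = torsions.copy()
    m = len(dims)

    x0 = np.array([torsions[r, tor] for r, tor in dims])

    def residuals(x):
        for d, (r, tor) in enumerate(dims):
            work[r, tor] = x[d]
        geo.build_coords(work, scratch, lo)
        res = np.zeros(9 + m + (m if bins is not None else 0))
        res[0:3] = scratch[anchor, geo.AT_N] - targets[0]
        res[3:6] = scratch[anchor, geo.AT_CA] - targets[1]
        res[6:9] = scratch[anchor, geo.AT_C] - targets[2]
        # stay near the CCD solution so its steric clearance survives
        for d in range(m):
            dd = x[d] - x0[d]
            while dd > 180.0:
                dd -= 360.0
            while dd <= -180.0:
                dd += 360.0
            res[9 + d] = anchor_weight * dd
        if bins is not None:
            for d, (r, tor) in enumerate(dims):
                dev_ = x[d] - bins[r, 2 * tor]
                while dev_ > 180.0:
                    dev_ -= 360.0
                while dev_ <= -180.0:
                    dev_ += 360.0
                ex = abs(dev_) - bins[r, 2 * tor + 1]
                if ex > 0.0:
                    res[9 + m + d] = bin_weight * ex
        return res
    sol = least_squares(residuals, x0, max_nfev=300)
    dev = float(np.sqrt(np.mean(np.sum(
        sol.fun[:9].reshape(3, 3) ** 2, axis=1))))
    if dev > tol:
        return None, dev
    for d, (r, tor) in enumerate(dims):
        work[r, tor] = sol.x[d]
    return work, dev


def motif_mobile_mask(bp: Blueprint, lo: int, hi: int) -> np.ndarray:
    """Loops plus two helix edge residues absorb closure; helix cores
    keep their sampled torsions."""
    ss_des = bp.residue_ss()
    mobile = np.zeros(hi - lo + 1, dtype=bool)
    for r in range(lo, hi + 1):
        if ss_des[r] == "L":
            mobile[r - lo] = True
        elif ss_des[r] == "H":
            h_lo = r
            while h_lo > lo and ss_des[h_lo - 1] == "H":
                h_lo -= 1
            h_hi = r
            while h_hi < hi and ss_des[h_hi + 1] == "H":
                h_hi += 1
            if r - h_lo < 2 or h_hi - r < 2:
                mobile[r - lo] = True
    if not mobile.any():
        mobile[:] = True
    return mobile


def sample_and_close(bp: Blueprint, lib: FragmentLibrary, torsions,
                     coords, lo: int, hi: int, targets, rng,
                     tries: int = CLOSURE_TRIES, tol: float = 0.08,
                     ccd_tol: float = CLOSURE_TOL, resample: bool = True,
                     bin_bias: bool = True, clash_ref=None,
                     clash_mask=None, clash_min: float = 2.0,
                     mobile_override=None, resample_mask=None):
    """Resample a motif from fragments and close it onto fixed anchor
    targets: gap-ranked random initialisations, CCD, then least-squares
    polish to ``tol``.  When ``clash_ref``/``clash_mask`` are given, a
    closed motif whose CA trace comes within ``clash_min`` A of the
    masked context residues is rejected.  Returns closed torsions for
    residues 0..hi+1 (or None) and the achieved deviation."""
    anchor = hi + 1
    mobile = motif_mobile_mask(bp, lo, hi) if mobile_override is None \
        else np.asarray(mobile_override, bool)
    bins = bin_interval_arrays(bp.residue_labels()) if bin_bias else None
    ctx_ca = None
    if clash_ref is not None and clash_mask is not None \
            and clash_mask.any():
        ctx_ca = clash_ref[clash_mask, geo.AT_CA, :]

    def clearance(t_arr):
        if ctx_ca is None:
            return np.inf
        chk = coords[:anchor + 1].copy()
        geo.build_coords(t_arr, chk, lo)
        mca = chk[lo:hi + 1, geo.AT_CA, :]
        return float(np.min(np.linalg.norm(
            mca[:, None, :] - ctx_ca[None, :, :], axis=2)))

    inits = []
    ss_des = bp.residue_ss()
    scratch = coords[:anchor + 1].copy()
    for _ in range(4 * tries):
        work = torsions[:anchor + 1].copy()
        if resample:
            for r in range(lo, hi + 1):
                if resample_mask is not None and not resample_mask[r - lo]:
                    continue
                if not bin_bias and ss_des[r] == "L":
                    # scaffold mode: uniform loop starts reach helix
                    # orientations the narrow loop bins never produce
                    work[r] = (rng.uniform(-180.0, 180.0),
                               rng.uniform(-180.0, 180.0), 180.0)
                else:
                    frags = lib.fragments_at(r, 1)
                    work[r] = frags[rng.integers(len(frags)), 0]

        geo.build_coords(work, scratch, lo)
        gap = float(np.linalg.norm(scratch[anchor, geo.AT_CA]
                                   - targets[1]))
        # rank by reachability AND steric plausibility: compact starts
        # that already thread the context never close cleanly
        score = gap
        if ctx_ca is not None:
            mca = scratch[lo:hi + 1, geo.AT_CA, :]
            dmin = float(np.min(np.linalg.norm(
                mca[:, None, :] - ctx_ca[None, :, :], axis=2)))
            score += 8.0 * max(0.0, 4.5 - dmin)
        inits.append((score, work))
        if not resample:
            break
    inits.sort(key=lambda t: t[0])

    # CCD every promising init (the kernel is cheap), keep the closed
    # candidates that best clear the context, refine those
    best_dev = np.inf
    closed = []
    for gap, work in inits:
        t_cl, c_cl, dev, _ = ccd_close(
            work, (lo, hi), targets, max_iterations=400, tol=ccd_tol,
            mobile_mask=mobile, coords_init=coords[:anchor + 1])
        if dev >= ccd_tol:
            best_dev = min(best_dev, dev)
            continue
        closed.append((clearance(t_cl), dev, t_cl))
    closed.sort(key=lambda t: -t[0])
    for clear0, dev0, t_cl in closed[:tries]:
        if clear0 < clash_min:
            break
        t_ref, dev = _refine_closure(t_cl, lo, hi, mobile,
                                     coords[:anchor + 1], targets,
                                     tol=tol, bins=bins)
        if t_ref is None:
            best_dev = min(best_dev, dev)
            continue
        t_ref[lo:hi + 1] = _wrap(t_ref[lo:hi + 1])
        # allow a little drift from the exact-closure polish
        if clearance(t_ref) < clash_min - 0.5:
            continue
        return t_ref, dev
    return None, best_dev



def _sheet_normal(bp: Blueprint, coords) -> np.ndarray:
    """Unit normal of the least-squares plane through all strand CAs."""
    pts = np.concatenate([
        coords[bp.element_span(e)[0]:bp.element_span(e)[1] + 1, geo.AT_CA]
        for e in bp.strand_elements()])
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[2]


def _align_rotation(a, b):
    """Rotation taking unit vector a onto unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-9:
        if c > 0:
            return np.eye(3)
        # 180 degrees about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _rotation_about(perp / np.linalg.norm(perp), np.pi)
    k = v / np.linalg.norm(v)
    ang = np.arctan2(np.linalg.norm(v), c)
    return _rotation_about(k, ang)


HELIX_DIST = 9.5        # A, helix axis offset from the sheet plane
HELIX_DIST_SD = 0.8
HELIX_TILT_SD = 8.0      # degrees of axis tilt noise


def place_helix_and_close(bp, lib, torsions, coords, lo, hi, rng,
                          face_sign, normal, clash_mask=None,
                          placement_tries=56, is_tail=False,
                          end_target=None, lateral_shift=None,
                          bin_bias=False):
    """Rebuild one loop-helix(-loop) motif geometrically.

    The helix is placed rigidly on the given face of the sheet (axis
    roughly antiparallel to the flanking strand direction, spun
    randomly), then the flanking loops are CCD-closed onto it.  Operates
    on copies; returns ``(torsions, coords)`` for the whole chain or
    ``(None, None)``.

    ``end_target`` (tail motifs): point the helix should end near (the
    chain-terminus packing constraint).
    """
    n = bp.n_residues
    ss_des = bp.residue_ss()
    h_res = [r for r in range(lo, hi + 1) if ss_des[r] == "H"]
    if not h_res:
        # pure-loop motif: fall back to plain closure
        if is_tail:
            return None, None
        targets = np.stack([coords[hi + 1, geo.AT_N],
                            coords[hi + 1, geo.AT_CA],
                            coords[hi + 1, geo.AT_C]])
        t_ref, _ = sample_and_close(bp, lib, torsions, coords, lo, hi,
                                    targets, rng, bin_bias=False,
                                    clash_ref=coords,
                                    clash_mask=clash_mask)
        if t_ref is None:
            return None, None
        out_t = torsions.copy()
        out_t[lo:hi + 1] = t_ref[lo:hi + 1]
        out_c = coords.copy()
        geo.build_coords(out_t[:hi + 2], out_c[:hi + 2], lo)
        return out_t, out_c
    h0, h1 = h_res[0], h_res[-1]
    # local helix segment with the blueprint torsions
    seg_t = torsions.copy()
    for r in range(h0, h1 + 1):
        frags = lib.fragments_at(r, 1)
        seg_t[r] = frags[rng.integers(len(frags)), 0]
    seg_full = geo.build_from_torsion_array(seg_t[h0:h1 + 2]
                                            if h1 + 1 < n
                                            else seg_t[h0:h1 + 1])
    seg = seg_full[:h1 - h0 + 1]
    seg_ca = seg[:, geo.AT_CA]
    axis0 = seg_ca[-1] - seg_ca[0]
    axis0 = axis0 / np.linalg.norm(axis0)
    centroid0 = seg_ca.mean(axis=0)
    # flanking anchors in the placed structure
    p_a = coords[lo - 1, geo.AT_CA]
    if is_tail:
        p_b = end_target if end_target is not None             else coords[0, geo.AT_CA]
    else:
        p_b = coords[hi + 1, geo.AT_CA]
    u = p_b - p_a
    u_norm = np.linalg.norm(u)
    u = u / u_norm if u_norm > 1e-6 else np.array([1.0, 0.0, 0.0])
    ctx_ca = coords[clash_mask, geo.AT_CA] if clash_mask is not None         and clash_mask.any() else None
    for _ in range(placement_tries):
        q = face_sign * normal
        h_off = rng.normal(HELIX_DIST, HELIX_DIST_SD)
        center = 0.5 * (p_a + p_b) + h_off * q             + rng.normal(0.0, NOISE_TRANS_SD, 3)
        # axis along the anchor->anchor direction (the helix crosses
        # back over the sheet), with tilt noise
        axis = u.copy()
        for perp_seed in ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0)):
            perp = np.cross(axis, perp_seed)
            if np.linalg.norm(perp) > 1e-6:
                perp /= np.linalg.norm(perp)
                axis = _rotation_about(
                    perp, np.radians(rng.normal(0, HELIX_TILT_SD))) @ axis
        if is_tail:
            # climb away from the sheet while crossing the helix layer
            axis = axis + rng.uniform(0.0, 0.45) * q
        axis /= np.linalg.norm(axis)
        rot = _align_rotation(axis0, axis)
        rot = _rotation_about(axis, rng.uniform(0, 2 * np.pi)) @ rot
        placed = (rot @ (seg.reshape(-1, 3) - centroid0).T).T + center
        placed = placed.reshape(seg.shape)
        if ctx_ca is not None:
            dmin = float(np.min(np.linalg.norm(
                placed[:, geo.AT_CA][:, None, :] - ctx_ca[None, :, :],
                axis=2)))
            if dmin < 2.6:
                continue
        # reachability of both loops
        gap1 = np.linalg.norm(placed[0, geo.AT_CA] - p_a)
        if gap1 > 3.8 * (h0 - lo + 2):
            continue
        if not is_tail:
            gap2 = np.linalg.norm(coords[hi + 1, geo.AT_CA]
                                  - placed[-1, geo.AT_CA])
            if gap2 > 3.8 * (hi - h1 + 2):
                continue
        work_t = torsions.copy()
        work_t[h0:h1 + 1] = seg_t[h0:h1 + 1]
        work_c = coords.copy()
        work_c[h0:h1 + 1] = placed
        # close the entry loop onto the placed helix: the strand edge
        # residue and the first two helix residues flex with the loop
        seg1_lo = max(lo - 1, 1)
        seg1_hi = min(h0 + 1, h1 - 1)
        targets1 = np.stack([placed[seg1_hi + 1 - h0, geo.AT_N],
                             placed[seg1_hi + 1 - h0, geo.AT_CA],
                             placed[seg1_hi + 1 - h0, geo.AT_C]])
        m1 = np.ones(seg1_hi - seg1_lo + 1, dtype=bool)
        rs1 = np.zeros(seg1_hi - seg1_lo + 1, dtype=bool)
        for r in range(lo, h0 + 1):
            rs1[r - seg1_lo] = True     # resample loop starts only
        t1, _ = sample_and_close(bp, lib, work_t, work_c, seg1_lo,
                                 seg1_hi, targets1, rng,
                                 bin_bias=bin_bias,
                                 clash_ref=work_c, clash_mask=clash_mask,
                                 clash_min=2.0, mobile_override=m1,
                                 resample_mask=rs1)
        if t1 is None:
            continue
        work_t[seg1_lo:seg1_hi + 1] = t1[seg1_lo:seg1_hi + 1]
        stop = h1 + 2 if h1 + 1 < n else n
        geo.build_coords(work_t[:stop], work_c[:stop], seg1_lo)
        if is_tail:
            geo.build_coords(work_t, work_c, seg1_lo)
            return work_t, work_c
        # close the exit loop onto the downstream strand; the last two
        # helix residues flex with it
        seg2_lo = max(h1 - 1, seg1_hi + 1)
        targets2 = np.stack([coords[hi + 1, geo.AT_N],
                             coords[hi + 1, geo.AT_CA],
                             coords[hi + 1, geo.AT_C]])
        m2 = np.ones(hi - seg2_lo + 1, dtype=bool)
        rs2 = np.zeros(hi - seg2_lo + 1, dtype=bool)
        for r in range(h1 + 1, hi + 1):
            rs2[r - seg2_lo] = True
        t2, _ = sample_and_close(bp, lib, work_t, work_c, seg2_lo, hi,
                                 targets2, rng, bin_bias=bin_bias,
                                 clash_ref=work_c, clash_mask=clash_mask,
                                 clash_min=2.0, mobile_override=m2,
                                 resample_mask=rs2)
        if t2 is None:
            continue
        work_t[seg2_lo:hi + 1] = t2[seg2_lo:hi + 1]
        geo.build_coords(work_t[:hi + 2], work_c[:hi + 2], seg2_lo)
        return work_t, work_c
    return None, None


def motif_faces(bp: Blueprint) -> dict:
    """Face sign (+1/-1) per inter-strand motif, keyed by the flanking
    strand element pair, plus 'tail' for the trailing helix.

    Right-handed crossovers put the connecting helix on the face given
    by the crossover direction in the sheet; the trailing helix packs on
    the face of the first crossover helix (the terminal-packing face).
    """
    strands = bp.strand_elements()
    order = bp.sheet_order()
    pos = {e: k for k, e in enumerate(order)}
    faces = {}
    first_face = None
    for s_prev, s_next in zip(strands, strands[1:]):
        face = -1.0 if pos[s_next] > pos[s_prev] else 1.0
        faces[(s_prev, s_next)] = face
        if first_face is None:
            first_face = face
    faces["tail"] = first_face if first_face is not None else 1.0
    return faces


def build_scaffold(bp: Blueprint, lib: FragmentLibrary,
                   rng: np.random.Generator,
                   noise_rot_sd: float = NOISE_ROT_SD,
                   noise_trans_sd: float = NOISE_TRANS_SD):
    """Construct one noisy geometric realisation of the blueprint.

    Returns a BackboneStructure, or raises ScaffoldError when a motif
    cannot be closed onto its strand anchors.
    """
    strands = bp.strand_elements()
    if not strands or bp.elements[0].kind != "E":
        raise ScaffoldError("scaffold construction requires a blueprint "
                            "starting with a strand")
    topo = sheet_hbond_topology(bp)
    n = bp.n_residues
    torsions = lib.initial_torsions()
    _sample_strand_torsions(bp, lib, torsions, rng)
    full = geo.build_from_torsion_array(torsions)
    # local coordinates of each strand segment (from the full build, so
    # interior amide protons are well defined)
    seg = {ei: full[bp.element_span(ei)[0]:bp.element_span(ei)[1] + 1].copy()
           for ei in strands}
    # --- place strands along the sheet
    order = bp.sheet_order()
    pairing_of = {}
    for k, p in enumerate(bp.pairings):
        pairing_of[(p.strand_a, p.strand_b)] = k
        pairing_of[(p.strand_b, p.strand_a)] = k
    placed = {order[0]: seg[order[0]].copy()}
    for ue, ve in zip(order, order[1:]):
        k = pairing_of[(ue, ve)]
        p = bp.pairings[k]
        rungs = _interface_rungs(bp, topo, k, ue, ve)
        if not rungs:
            raise ScaffoldError(f"no designated bonds on interface "
                                f"{ue}-{ve}")
        lu = bp.elements[ue].length
        lv = bp.elements[ve].length
        # central rung with frame-able indices on both strands
        cands = [(abs(i - lu / 2), (i, j)) for i, j in rungs
                 if 1 <= i < lu - 1 and 1 <= j + 1 < lv - 1 + 1
                 and 1 <= j < lv - 1]
        if not cands:
            cands = [(abs(i - lu / 2), (i, j)) for i, j in rungs
                     if 1 <= i < lu - 1 and 1 <= j < lv - 1]
        if not cands:
            raise ScaffoldError(f"interface {ue}-{ve}: no usable rung")
        istar, jstar = min(cands)[1]
        cu = placed[ue]
        ua, wa = _strand_frame(cu, istar, use_nh=True)
        cv = seg[ve]
        if p.orientation == PARALLEL:
            # participating donor on the new strand is jstar + 1
            jref = jstar + 1 if jstar + 1 <= lv - 2 else jstar - 1
            ub, wb = _strand_frame(cv, jref, use_nh=True)
            a1 = np.column_stack([ua, -wa, np.cross(ua, -wa)])
            sep, ax = PAR_SEP, PAR_AX
        else:
            ub, wb = _strand_frame(cv, jstar, use_nh=True)
            a1 = np.column_stack([-ua, -wa, np.cross(-ua, -wa)])
            sep, ax = ANTI_SEP, ANTI_AX
        b1 = np.column_stack([ub, wb, np.cross(ub, wb)])
        rot = a1 @ b1.T
        anchor = cu[istar, geo.AT_CA] + sep * wa + ax * ua
        # rigid-body noise: twist about the strand axis, bend about the
        # ladder direction, translation jitter
        rot = _rotation_about(ua, np.radians(rng.normal(0, noise_rot_sd))) \
            @ _rotation_about(wa, np.radians(rng.normal(0, noise_rot_sd))) \
            @ rot
        anchor = anchor + rng.normal(0, noise_trans_sd, 3)
        flat = cv.reshape(-1, 3)
        moved = (rot @ flat.T).T
        moved = moved + (anchor - moved.reshape(cv.shape)[jstar, geo.AT_CA])
        placed[ve] = moved.reshape(cv.shape)
    # --- assemble the chain
    coords = np.zeros((n, 6, 3))
    for ei in strands:
        a, b = bp.element_span(ei)
        coords[a:b + 1] = placed[ei]
    # place helices on alternating faces of the sheet and close the
    # flanking loops onto them
    placed_mask = np.zeros(n, dtype=bool)
    for ei in strands:
        a, b = bp.element_span(ei)
        placed_mask[a:b + 1] = True
    normal = _sheet_normal(bp, coords)
    # helix faces follow the (right-handed) crossover direction: the
    # helix of a crossover to higher sheet positions sits on one face,
    # to lower positions on the other; the trailing helix joins the
    # first helix's face (this is the terminal-helix packing face)
    pos = {e: k for k, e in enumerate(order)}
    faces = motif_faces(bp)
    # evenly spaced lateral slots per face so same-face helices splay
    # across the sheet instead of colliding at its centre
    cents = {e: coords[bp.element_span(e)[0]:bp.element_span(e)[1] + 1,
                       geo.AT_CA].mean(axis=0) for e in strands}
    sheet_c = np.mean(list(cents.values()), axis=0)
    spread = np.array([cents[e] - sheet_c for e in strands])
    _, _, vt_l = np.linalg.svd(spread)
    w_lat = vt_l[0]
    lvals = [float(np.dot(cents[e] - sheet_c, w_lat)) for e in strands]
    lmin, lmax = min(lvals), max(lvals)
    motif_list = [(sp, sn) for sp, sn in zip(strands, strands[1:])
                  if bp.element_span(sp)[1] + 1
                  <= bp.element_offset(sn) - 1]
    by_face = {}
    nat = {}
    for sp, sn in motif_list:
        mid = 0.5 * (coords[bp.element_span(sp)[1], geo.AT_CA]
                     + coords[bp.element_offset(sn), geo.AT_CA])
        nat[(sp, sn)] = float(np.dot(mid - sheet_c, w_lat))
        by_face.setdefault(faces[(sp, sn)], []).append((sp, sn))
    shifts = {}
    for face, motifs in by_face.items():
        m = len(motifs) + (1 if faces["tail"] == face
                           and bp.element_span(strands[-1])[1] + 1 < n
                           else 0)
        motifs = sorted(motifs, key=lambda k: nat[k])
        for k, key in enumerate(motifs):
            if m >= 3:
                # full-span slots: long helices need ~8.5 A of axis
                # separation, nearly the whole sheet width
                slot = lmin + k * (lmax - lmin) / (m - 1)
            else:
                slot = lmin + (k + 0.5) * (lmax - lmin) / max(m, 1)
            shifts[key] = (slot - nat[key]) * w_lat
    for s_prev, s_next in zip(strands, strands[1:]):
        lo = bp.element_span(s_prev)[1] + 1
        hi = bp.element_offset(s_next) - 1
        if lo > hi:
            continue
        face = faces[(s_prev, s_next)]
        ctx = placed_mask.copy()
        ctx[max(lo - 3, 0):min(hi + 4, n)] = False
        t_new, c_new = place_helix_and_close(
            bp, lib, torsions, coords, lo, hi, rng, face, normal,
            clash_mask=ctx, lateral_shift=shifts.get((s_prev, s_next)))
        if t_new is None:
            raise ScaffoldError(f"could not place/close motif {lo}-{hi}")
        torsions = t_new
        coords = c_new
        placed_mask[lo:hi + 1] = True
    # trailing loop-helix after the last strand: its end must come back
    # toward the chain start (terminal packing constraint)
    tail = bp.element_span(strands[-1])[1] + 1
    if tail < n:
        ctx = placed_mask.copy()
        ctx[max(tail - 3, 0):] = False
        t_new, c_new = place_helix_and_close(
            bp, lib, torsions, coords, tail, n - 1, rng,
            faces["tail"], normal, clash_mask=ctx, is_tail=True,
            end_target=coords[0, geo.AT_CA])
        if t_new is None:
            raise ScaffoldError("could not place the trailing helix")
        torsions = t_new
        coords = c_new
    # the torsions are now seam-free: a full rebuild reproduces the
    # placed sheet (to the closure tolerance)
    coords = geo.build_from_torsion_array(torsions)
    return BackboneStructure(torsions, coords)
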