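"""Backbone ensemble generation: the three-step building protocol.

Every attempt starts from a geometric scaffold of the designated sheet
(see :mod:`foldstrain.scaffold`): synthetic per-bin fragments lack the
supersecondary correlations that make fragment assembly discover phased
hydrogen-bond ladders, so the topology is realised explicitly and the
stochastic stages sample around — and away from — that basin.

Step 1 — part-by-part fragment-assembly Monte Carlo.  The chain is
treated in blueprint parts (a beta-alpha-beta seed, then alpha-beta
units, then the trailing helix); each part runs Metropolis Monte Carlo
at the simulated temperature 2.0 for ``steps_per_residue x current
length`` steps, replacing random 1/3/9-residue frames with
blueprint-compatible fragments.  A part passes when every built pairing
keeps at least one aligned CA pair inside the register window.

Step 2 — constrained relaxation.  An annealed fragment-move Metropolis
pass over the upweighted score plus flat-bottom penalties (designated CA
pairs held in 4.0-5.5 A, designated N..O below 3.0 A, chain termini
restrained when the blueprint ends in a helix, ABEGO bin restraints on
helix/strand torsions).  The structure passes only if the designated
sheet is formed: non-edge strand residues assigned strand, up to
``formed_max_misses`` exceptions.

Step 3 — loop-helix rebuild.  In strict mode each motif is re-placed
geometrically and must satisfy the helical-bin, kink, buriedness and
terminal-distance checks; in the desk-scale "rough" mode the thermally
sampled motifs are kept, kink/buriedness are recorded as diagnostics,
and the terminal-distance gate still applies.  Accepted members carry
provenance including their minimum steric clearances.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import geometry as geo
from .abego import bin_interval_arrays, classify_abego, label_matches
from .backbone import (BackboneStructure, assign_secondary_structure,
                       detect_helix_kink)
from .blueprint import Blueprint, aligned_pairs
from .ccd import ccd_close, closure_feasible
from .fragments import FragmentLibrary, make_synthetic_fragments
from .sasa import residue_sasa
from .scaffold import (ScaffoldError, _sheet_normal, build_scaffold,
                       place_helix_and_close, sample_and_close)
from .scoring import (ScoreWeights, default_params, designated_bond_arrays,
                      designated_pair_arrays, score_terms, ss_masks)

CONSTRAINT_DIST = 5.5     # A, sheet-pairing CA constraint
TERMINAL_DIST = 15.0      # A, first-strand N-term to last-helix C-term
BURIED_AREA = 40.0        # A^2, buried-residue threshold
BURIED_WINDOW = 5
REGISTER_CA_DIST = 6.0    # A, loose in-trajectory register check
BIN_RESTRAINT_K = 0.02    # per-deg^2 flat-bottom ABEGO bin restraint
HELIX_OVERLAP_FLOOR = 0.0  # A, min CA-CA between designated helices;
                           # 0 disables (overlap is endemic to the soft
                           # steric core, not an outlier; it is recorded
                           # per member instead)
CLASH_FLOOR = 0.0         # A, min CA-CA (|i-j|>3) of accepted members;
                          # 0 disables the hard gate (the coarse soft-core
                          # model tolerates residual overlap; the minimum
                          # clearance is recorded in member provenance)
SHEET_FORMED_CUTOFF = -0.3  # kcal/mol; assignment cutoff for the Step-2
                            # sheet-formation filter (the source protocol's
                            # own formation criterion is far more lenient)


@dataclass
class MCConfig:
    """Monte Carlo and protocol configuration.

    The defaults are the full protocol conditions; ``desk_scale`` returns
    a reduced profile for quick interactive runs and routine testing.
    """
    steps_per_residue: int = 300
    temperature: float = 2.0
    seed: int | None = None
    max_restarts: int = 50
    strict_motifs: bool = True
    formed_max_misses: int = 0
    relax_mc_steps_per_residue: int = 100
    motif_attempts: int = 200
    sasa_points: int = 128
    ccd_tol: float = 0.2

    @classmethod
    def desk_scale(cls) -> "MCConfig":
        """Reduced problem-size profile (shorter trajectories, fewer
        retries) for desk-scale ensemble studies."""
        return cls(steps_per_residue=30, relax_mc_steps_per_residue=80,
                   max_restarts=15, motif_attempts=32, sasa_points=64,
                   strict_motifs=False, formed_max_misses=1)


@dataclass
class BuildReport:
    attempts: int = 0
    accepted: int = 0
    stage_failures: Counter = field(default_factory=Counter)
    part_restarts: int = 0
    motif_retries: int = 0

    def fail(self, reason: str):
        self.stage_failures[reason] += 1

    def as_dict(self) -> dict:
        return {"attempts": self.attempts, "accepted": self.accepted,
                "part_restarts": self.part_restarts,
                "motif_retries": self.motif_retries,
                "stage_failures": dict(self.stage_failures)}


class Ensemble:
    """A set of accepted backbone structures from one blueprint."""

    def __init__(self, blueprint: Blueprint, members=None, seed=None,
                 report: BuildReport | None = None):
        self.blueprint = blueprint
        self.members = list(members or [])
        self.seed = seed
        self.report = report or BuildReport()

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def manifest(self) -> dict:
        return {"blueprint": self.blueprint.name, "seed": self.seed,
                "n_members": len(self.members),
                "report": self.report.as_dict(),
                "members": [m.provenance for m in self.members]}


# --------------------------------------------------------------------
# Monte Carlo kernel


@njit(cache=True, fastmath=True)
def _mc_run(torsions, coords, n_built, lo, hi,
            t1, o1, c1, t3, o3, c3, t9, o9, c9,
            pair_i, pair_j, pair_orient, helix_mask, strand_mask,
            bond_d, bond_a, weights, params, steps, temperature, seed,
            record_stride, record):
    np.random.seed(seed)
    terms = score_terms(coords, torsions, n_built, pair_i, pair_j,
                        pair_orient, helix_mask, strand_mask,
                        bond_d, bond_a, params)
    e = 0.0
    for k in range(8):
        e += weights[k] * terms[k]
    e *= params[4]
    n_acc = 0
    span = hi - lo + 1
    rec_k = 0
    for step in range(steps):
        r = np.random.random()
        if span >= 9:
            length = 9 if r < 0.2 else (3 if r < 0.55 else 1)
        elif span >= 3:
            length = 3 if r < 0.4 else 1
        else:
            length = 1
        pos = lo + np.int64(np.random.random() * (span - length + 1))
        if length == 1:
            cnt = c1[pos]
            off = o1[pos]
        elif length == 3:
            cnt = c3[pos]
            off = o3[pos]
        else:
            cnt = c9[pos]
            off = o9[pos]
        if cnt == 0:
            continue
        f = off + np.int64(np.random.random() * cnt)
        old_t = torsions[pos:pos + length].copy()
        back = pos - 1 if pos > 0 else 0
        old_c = coords[back:n_built].copy()
        if length == 1:
            torsions[pos] = t1[f, 0]
        elif length == 3:
            torsions[pos:pos + 3] = t3[f]
        else:
            torsions[pos:pos + 9] = t9[f]
        geo.build_coords(torsions[:n_built], coords[:n_built], pos)
        new_terms = score_terms(coords, torsions, n_built, pair_i, pair_j,
                                pair_orient, helix_mask, strand_mask,
                                bond_d, bond_a, params)
        ne = 0.0
        for k in range(8):
            ne += weights[k] * new_terms[k]
        ne *= params[4]
        de = ne - e
        if de <= 0.0 or np.random.random() < np.exp(-de / temperature):
            e = ne
            n_acc += 1
        else:
            torsions[pos:pos + length] = old_t
            coords[back:n_built] = old_c
        if record_stride > 0 and (step + 1) % record_stride == 0:
            if rec_k < record.shape[0]:
                for rr in range(span):
                    for cc in range(3):
                        record[rec_k, rr, cc] = torsions[lo + rr, cc]
                rec_k += 1
    return e, n_acc


@njit(cache=True, fastmath=True)
def _relax_objective(x, n, coords_scratch, cst_i, cst_j, cst_limit, cst_k,
                     pair_i, pair_j, pair_orient, helix_mask, strand_mask,
                     bond_d, bond_a, weights, params, bins, bin_k,
                     term_limit):
    t = x.reshape(n, 3)
    geo.build_coords(t, coords_scratch, 0)
    terms = score_terms(coords_scratch, t, n, pair_i, pair_j, pair_orient,
                        helix_mask, strand_mask, bond_d, bond_a, params)
    e = 0.0
    for k in range(8):
        e += weights[k] * terms[k]
    for c in range(cst_i.shape[0]):
        dx = coords_scratch[cst_i[c], 2, 0] - coords_scratch[cst_j[c], 2, 0]
        dy = coords_scratch[cst_i[c], 2, 1] - coords_scratch[cst_j[c], 2, 1]
        dz = coords_scratch[cst_i[c], 2, 2] - coords_scratch[cst_j[c], 2, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > cst_limit:
            e += cst_k * (d - cst_limit) ** 2
    # designated-bond N...O flat-bottom constraints: the coarse hydrogen
    # bond well is too shallow at 4 A to zip the ladder on its own
    for c in range(bond_d.shape[0]):
        if bond_d[c] == 0:
            continue
        dx = coords_scratch[bond_d[c], 0, 0] - coords_scratch[bond_a[c], 4, 0]
        dy = coords_scratch[bond_d[c], 0, 1] - coords_scratch[bond_a[c], 4, 1]
        dz = coords_scratch[bond_d[c], 0, 2] - coords_scratch[bond_a[c], 4, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > 3.0:
            e += cst_k * (d - 3.0) ** 2
    # chain-end packing restraint (the terminal-distance constraint of
    # the building protocol; 0 disables)
    if term_limit > 0.0:
        dx = coords_scratch[0, 2, 0] - coords_scratch[n - 1, 2, 0]
        dy = coords_scratch[0, 2, 1] - coords_scratch[n - 1, 2, 1]
        dz = coords_scratch[0, 2, 2] - coords_scratch[n - 1, 2, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > term_limit:
            e += cst_k * (d - term_limit) ** 2
    # flat-bottom restraints keeping each residue in its blueprint
    # ABEGO bin (the coarse analogue of a backbone-torsion term)
    for r in range(n):
        for tor in range(2):
            dev = t[r, tor] - bins[r, 2 * tor]
            while dev > 180.0:
                dev -= 360.0
            while dev <= -180.0:
                dev += 360.0
            ex = abs(dev) - bins[r, 2 * tor + 1]
            if ex > 0.0:
                e += bin_k * ex * ex
    return e


@njit(cache=True, fastmath=True)
def _relax_mc(torsions, coords, n, lo, hi,
              t1, o1, c1, t3, o3, c3, t9, o9, c9,
              cst_i, cst_j, cst_limit, cst_k,
              pair_i, pair_j, pair_orient, helix_mask, strand_mask,
              bond_d, bond_a, weights, params, bins, bin_k, term_limit,
              steps, t_start, t_end, seed):
    """Annealed Metropolis pass over the full objective (score +
    constraints + bin restraints) using fragment-replacement proposals."""
    np.random.seed(seed)
    x = torsions.reshape(-1)
    e = _relax_objective(x, n, coords, cst_i, cst_j, cst_limit, cst_k,
                         pair_i, pair_j, pair_orient, helix_mask,
                         strand_mask, bond_d, bond_a, weights, params,
                         bins, bin_k, term_limit)
    span = hi - lo + 1
    for step in range(steps):
        frac = step / max(steps - 1, 1)
        temp = t_start * (t_end / t_start) ** frac
        r = np.random.random()
        if span >= 3:
            length = 3 if r < 0.3 else 1
        else:
            length = 1
        pos = lo + np.int64(np.random.random() * (span - length + 1))
        if length == 1:
            cnt = c1[pos]
            off = o1[pos]
        else:
            cnt = c3[pos]
            off = o3[pos]
        if cnt == 0:
            continue
        f = off + np.int64(np.random.random() * cnt)
        old_t = torsions[pos:pos + length].copy()
        back = pos - 1 if pos > 0 else 0
        old_c = coords[back:n].copy()
        if length == 1:
            torsions[pos] = t1[f, 0]
        else:
            torsions[pos:pos + 3] = t3[f]
        geo.build_coords(torsions, coords, pos)
        ne = _relax_objective(x, n, coords, cst_i, cst_j, cst_limit,
                              cst_k, pair_i, pair_j, pair_orient,
                              helix_mask, strand_mask, bond_d, bond_a,
                              weights, params, bins, bin_k, term_limit)
        de = ne - e
        if de <= 0.0 or np.random.random() < np.exp(-de / temp):
            e = ne
        else:
            torsions[pos:pos + length] = old_t
            coords[back:n] = old_c
    return e


# --------------------------------------------------------------------
# python-level protocol


def _wrap_degrees(t: np.ndarray) -> np.ndarray:
    t = (t + 180.0) % 360.0 - 180.0
    t[t == -180.0] = 180.0
    return t


def _lib_arrays(lib: FragmentLibrary):
    out = []
    for length in (1, 3, 9):
        out += [lib.torsions[length], lib.offsets[length],
                lib.counts[length]]
    return out


def _prefix_structure(torsions, coords, n_built, provenance=None):
    return BackboneStructure(torsions[:n_built].copy(),
                             coords[:n_built].copy(), provenance)


def _fully_built_elements(bp: Blueprint, n_built: int):
    return [i for i in range(len(bp.elements))
            if bp.element_span(i)[1] < n_built]


def _loose_sheet_ok(bp: Blueprint, torsions, coords, n_built) -> bool:
    """Step-1 acceptance: every built designated helix unkinked and every
    built pairing realised loosely (at least one aligned CA pair close
    and direction-consistent).

    This is deliberately rough — full strand assignment is enforced after
    the Step-2 constrained relaxation, not here, so that parts are not
    locally over-optimised.
    """
    s = _prefix_structure(torsions, coords, n_built)
    built = _fully_built_elements(bp, n_built)
    # progress gate on the sheet only: helices are governed by the
    # strict kink criterion when their motifs are rebuilt in Step 3
    ca = s.ca
    for p in bp.pairings:
        if p.strand_a not in built or p.strand_b not in built:
            continue
        oa = bp.element_offset(p.strand_a)
        ob = bp.element_offset(p.strand_b)
        close = 0
        for i, j in aligned_pairs(bp, p):
            if 3.8 < np.linalg.norm(ca[oa + i] - ca[ob + j]) \
                    < REGISTER_CA_DIST:
                close += 1
        if close < 1:
            return False
    return True


def run_part_trajectory(bp: Blueprint, lib: FragmentLibrary, torsions,
                        coords, part_idx: int, cfg: MCConfig, seed: int,
                        weights: ScoreWeights | None = None,
                        params=None):
    """One Monte Carlo trajectory for one part (in place).

    Returns ``(energy, n_accepted_moves, passed_checks)``.
    """
    weights = weights or ScoreWeights.step1()
    lo, hi = bp.part_span(part_idx)
    n_built = hi + 1
    pi, pj, orient = designated_pair_arrays(bp)
    bd, ba = designated_bond_arrays(bp)
    hm, sm = ss_masks(bp)
    steps = cfg.steps_per_residue * n_built
    dummy = np.zeros((0, hi - lo + 1, 3))
    if params is None:
        params = default_params()
    e, n_acc = _mc_run(torsions, coords, n_built, lo, hi,
                       *_lib_arrays(lib), pi, pj, orient, hm, sm, bd, ba,
                       weights.as_array(), params, steps, cfg.temperature,
                       seed, 0, dummy)
    ok = _loose_sheet_ok(bp, torsions, coords, n_built)
    return e, n_acc, ok


def relax_with_sheet_constraints(s: BackboneStructure, bp: Blueprint,
                                 cfg: MCConfig | None = None,
                                 seed: int = 0,
                                 weights: ScoreWeights | None = None,
                                 constraint_k: float = 8.0,
                                 lib: FragmentLibrary | None = None):
    """Step 2: constrained relaxation toward full sheet pairing.

    An annealed Metropolis pass with fragment-replacement proposals
    minimises the upweighted score plus flat-bottom penalties on the
    designated CA pairs (active above 5.5 A) and on the designated
    hydrogen-bond N...O distances.  Fragment proposals keep every
    residue inside its torsion bin, so - unlike gradient descent on this
    landscape - the pass cannot trade formed ladder geometry for other
    terms.  Returns ``(structure, sheet_formed)``; the sheet is formed
    when every non-edge residue of every strand is assigned strand.  If
    the pass degrades a structure that already met the criterion, the
    input is carried forward.
    """
    cfg = cfg or MCConfig()
    weights = weights or ScoreWeights.step2()
    n = len(s)
    if lib is None:
        raise ValueError("relaxation needs the fragment library")
    pi, pj, orient = designated_pair_arrays(bp)
    bd, ba = designated_bond_arrays(bp)
    hm, sm = ss_masks(bp)
    w = weights.as_array()
    params = default_params()
    from .scoring import RELAX_VDW_SCALE
    params[0] = RELAX_VDW_SCALE
    bins = bin_interval_arrays(bp.residue_labels())
    # restrain only strand/helix torsions; loops must stay free to
    # absorb whatever geometry the closures produced
    ss_des = bp.residue_ss()
    for r in range(n):
        if ss_des[r] == "L":
            bins[r, 1] = 180.0
            bins[r, 3] = 180.0
    torsions = s.torsions.copy()
    coords = s.coords.copy()
    term_limit = 0.0
    if bp.elements and bp.elements[-1].kind == "H":
        term_limit = TERMINAL_DIST - 2.0
    _relax_mc(torsions, coords, n, 0, n - 1, *_lib_arrays(lib),
              pi, pj, CONSTRAINT_DIST, constraint_k,
              pi, pj, orient, hm, sm, bd, ba, w, params,
              bins, BIN_RESTRAINT_K, term_limit,
              cfg.relax_mc_steps_per_residue * n, 1.5, 0.15, seed)
    out = BackboneStructure(torsions, coords, dict(s.provenance))

    def _formed(st):
        ss = assign_secondary_structure(st, cutoff=SHEET_FORMED_CUTOFF)
        misses = 0
        for ei in bp.strand_elements():
            a, b = bp.element_span(ei)
            misses += sum(1 for r in range(a + 1, b) if ss[r] != "E")
        return misses <= cfg.formed_max_misses

    formed = _formed(out)
    if not formed and _formed(s):
        return s.copy(), True
    return out, formed


def _motifs(bp: Blueprint):
    """Element-index spans of the loop-helix(-loop) motifs between
    strands, N->C, plus the trailing loop-helix motif."""
    strands = bp.strand_elements()
    spans = []
    for a, b in zip(strands, strands[1:]):
        if b - a > 1:
            spans.append((a + 1, b - 1))
    if strands and strands[-1] < len(bp.elements) - 1:
        spans.append((strands[-1] + 1, len(bp.elements) - 1))
    return spans


def helix_buriedness(s: BackboneStructure, helix_span, context_residues,
                     probe: float = 2.0, area_threshold: float = BURIED_AREA,
                     window: int = BURIED_WINDOW, n_points: int = 128):
    """Per-residue accessible area of a helix and the windowed pass flag.

    The occluding context is the caller's residue set (strand residues
    plus the residues of the motif under rebuild); the helix passes when
    every ``window`` consecutive helix residues contain at least one
    residue with area below the threshold.
    """
    first, last = helix_span
    helix_residues = list(range(first, last + 1))
    areas = residue_sasa(s, helix_residues, context_residues,
                         probe=probe, n_points=n_points)
    m = len(helix_residues)
    if m < window:
        passed = bool((areas < area_threshold).any())
    else:
        passed = all((areas[k:k + window] < area_threshold).any()
                     for k in range(m - window + 1))
    return areas, passed


def _resample_motif(lib: FragmentLibrary, torsions, lo, hi, rng):
    for r in range(lo, hi + 1):
        frags = lib.fragments_at(r, 1)
        torsions[r] = frags[rng.integers(len(frags)), 0]


def rebuild_loop_helix(s: BackboneStructure, bp: Blueprint, motif_idx: int,
                       lib: FragmentLibrary, cfg: MCConfig, rng,
                       report: BuildReport | None = None):
    """Step 3 for one motif: resample, CCD-close, check.  Returns the
    rebuilt structure or None (reason recorded in the report)."""
    report = report if report is not None else BuildReport()
    spans = _motifs(bp)
    elem_lo, elem_hi = spans[motif_idx]
    lo = bp.element_offset(elem_lo)
    hi = bp.element_span(elem_hi)[1]
    n = len(s)
    is_last = hi == n - 1
    has_anchor = not is_last
    labels = bp.residue_labels()
    ss_designated = bp.residue_ss()
    helix_elems = [e for e in range(elem_lo, elem_hi + 1)
                   if bp.elements[e].kind == "H"]
    helix_span = bp.element_span(helix_elems[0]) if helix_elems else None
    strand_residues = [r for ei in bp.strand_elements()
                       for r in range(*_incl(bp.element_span(ei)))]
    if has_anchor:
        anchor = hi + 1
        gap = float(np.linalg.norm(s.ca[anchor] - s.ca[lo - 1]))
        if not closure_feasible(gap, hi - lo + 1):
            report.fail("motif_closure_infeasible")
            raise ValueError(
                f"motif {motif_idx}: anchors {gap:.1f} A apart cannot be "
                f"bridged by {hi - lo + 1} residues")
    normal = _sheet_normal(bp, s.coords)
    sheet_c = np.mean([s.ca[r] for r in strand_residues], axis=0)
    if helix_span is not None:
        h_cent = s.ca[helix_span[0]:helix_span[1] + 1].mean(axis=0)
        face = 1.0 if float(np.dot(normal, h_cent - sheet_c)) >= 0 \
            else -1.0
    else:
        face = 1.0
    ctx = np.ones(n, dtype=bool)
    ctx[max(lo - 3, 0):min(hi + 4, n)] = False
    # in rough (desk-scale) mode the motifs keep their thermally
    # sampled conformations; resampling happens only in strict mode
    n_outer = max(cfg.motif_attempts // 4, 8) if cfg.strict_motifs else 0
    for _ in range(n_outer):
        report.motif_retries += 1
        t_new, c_new = place_helix_and_close(
            bp, lib, s.torsions, s.coords, lo, hi, rng, face, normal,
            clash_mask=ctx, is_tail=is_last,
            end_target=s.ca[0] if is_last else None)
        if t_new is None:
            report.fail(f"m{motif_idx}_place")
            continue
        cand = BackboneStructure(geo.measure_torsions(c_new), c_new,
                                 dict(s.provenance))
        # designated ABEGO labels over the motif's helix residues (phi
        # of the first and psi of the last chain residue are undefined).
        # Loop bins are reconstructed, not read from data, and closure
        # geometry decides them; they are not a rejection criterion.
        tor = cand.torsions
        ok = True
        if helix_span is not None:
            # closure flexes up to two residues at each helix end; the
            # core must classify into the helical bin
            ok = all(label_matches(classify_abego(*tor[r]), labels[r])
                     for r in range(helix_span[0] + 2, helix_span[1] - 1))
        if not ok:
            report.fail(f"m{motif_idx}_abego")
            continue
        if helix_span is not None:
            if detect_helix_kink(cand, helix_span):
                report.fail(f"m{motif_idx}_kink")
                if cfg.strict_motifs:
                    continue
            context = sorted(set(strand_residues)
                             | set(range(lo, hi + 1)))
            _, buried_ok = helix_buriedness(
                cand, helix_span, context, n_points=cfg.sasa_points)
            if not buried_ok:
                report.fail(f"m{motif_idx}_buried")
                if cfg.strict_motifs:
                    continue
        if is_last:
            d_term = float(np.linalg.norm(cand.ca[-1] - cand.ca[0]))
            if d_term >= TERMINAL_DIST:
                report.fail(f"m{motif_idx}_terminal")
                continue
        return cand
    # resampling found no compliant replacement; the existing motif
    # (geometrically placed at initialisation and thermally sampled
    # since) faces the same acceptance checks
    if helix_span is not None and cfg.strict_motifs:
        if detect_helix_kink(s, helix_span):
            report.fail(f"motif_{motif_idx}_rejected")
            return None
        context = sorted(set(strand_residues) | set(range(lo, hi + 1)))
        _, buried_ok = helix_buriedness(s, helix_span, context,
                                        n_points=cfg.sasa_points)
        if not buried_ok:
            report.fail(f"motif_{motif_idx}_rejected")
            return None
    if is_last and float(np.linalg.norm(s.ca[-1] - s.ca[0])) \
            >= TERMINAL_DIST:
        report.fail(f"motif_{motif_idx}_rejected")
        return None
    report.fail(f"m{motif_idx}_kept")
    return s


def _incl(span):
    return span[0], span[1] + 1


def build_one(bp: Blueprint, lib: FragmentLibrary, cfg: MCConfig,
              rng: np.random.Generator, report: BuildReport,
              provenance=None):
    """Run Steps 1-3 once; returns an accepted structure or None.

    Each attempt starts from a fresh noisy geometric scaffold of the
    designated sheet (see :mod:`foldstrain.scaffold`); the Monte Carlo
    stage then equilibrates each part around that basin at the simulated
    temperature.
    """
    n = bp.n_residues
    seed_structure = None
    for _ in range(12):
        try:
            seed_structure = build_scaffold(bp, lib, rng)
            break
        except ScaffoldError:
            report.fail("scaffold_failed")
    if seed_structure is not None:
        torsions = seed_structure.torsions.copy()
        coords = seed_structure.coords.copy()
    else:
        # small motifs (e.g. two-strand hairpins) may not admit a
        # scaffold; fragment assembly folds them from the extended
        # bin-representative start instead
        torsions = lib.initial_torsions()
        coords = geo.build_from_torsion_array(torsions)
    # Step 1: part by part
    for part_idx in range(len(bp.parts)):
        lo, hi = bp.part_span(part_idx)
        # bring the newly exposed span in sync with the current torsions
        geo.build_coords(torsions[:hi + 1], coords[:hi + 1], lo)
        part_init_t = torsions[lo:hi + 1].copy()
        ok = False
        for _ in range(cfg.max_restarts):
            seed = int(rng.integers(2 ** 31))
            _, _, ok = run_part_trajectory(bp, lib, torsions, coords,
                                           part_idx, cfg, seed)
            if ok:
                break
            report.part_restarts += 1
            torsions[lo:hi + 1] = part_init_t
            geo.build_coords(torsions, coords, lo)
        if not ok:
            report.fail(f"part_{part_idx}_unbuildable")
            return None
    s = BackboneStructure(torsions, coords, provenance)
    # Step 2: constrained relaxation (a fresh anneal may succeed where
    # the first pass left an edge bridge open)
    formed = False
    for _ in range(3):
        s2, formed = relax_with_sheet_constraints(
            s, bp, cfg, seed=int(rng.integers(2 ** 31)), lib=lib)
        if formed:
            s = s2
            break
    if not formed:
        report.fail("sheet_not_formed")
        return None
    # Step 3: motif rebuild, N to C
    for m in range(len(_motifs(bp))):
        s = rebuild_loop_helix(s, bp, m, lib, cfg, rng, report)
        if s is None:
            return None
    # steric diagnostic: minimum nonlocal CA-CA clearance
    ca = s.ca
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) > 3
    min_clearance = float(d[sep].min())
    if CLASH_FLOOR > 0.0 and min_clearance < CLASH_FLOOR:
        report.fail("steric_clash")
        return None
    # record the closest helix-helix approach as well: the soft steric
    # core lets helices overlap, which compresses the inter-helix
    # distance metrics (see the methods note)
    helices = [bp.element_span(e) for e in bp.helix_elements()]
    min_hh = np.inf
    for a in range(len(helices)):
        for b in range(a + 1, len(helices)):
            (a0, a1), (b0, b1) = helices[a], helices[b]
            dh = np.linalg.norm(ca[a0:a1 + 1, None, :]
                                - ca[None, b0:b1 + 1, :], axis=2)
            min_hh = min(min_hh, float(dh.min()))
    if np.isfinite(min_hh) and HELIX_OVERLAP_FLOOR > 0.0 \
            and min_hh < HELIX_OVERLAP_FLOOR:
        report.fail("helix_interpenetration")
        return None
    if provenance is not None:
        if np.isfinite(min_hh):
            s.provenance["min_helix_helix_ca"] = round(min_hh, 2)
        s.provenance["min_ca_clearance"] = round(min_clearance, 2)
    return s


def generate_ensemble(bp: Blueprint, n_target: int, seed: int,
                      cfg: MCConfig | None = None,
                      lib: FragmentLibrary | None = None,
                      max_attempts: int | None = None,
                      time_budget: float | None = None) -> Ensemble:
    """Generate an ensemble of accepted backbones for a blueprint.

    Deterministic under ``seed``; structures carry provenance (blueprint
    name, seed, attempt id).  If the acceptance rate is too low to reach
    ``n_target`` within ``max_attempts`` a partial ensemble is returned
    with a warning.
    """
    cfg = cfg or MCConfig()
    rng = np.random.default_rng(seed)
    if lib is None:
        lib = make_synthetic_fragments(bp, int(rng.integers(2 ** 31)))
    else:
        rng.integers(2 ** 31)  # keep the stream aligned
    if max_attempts is None:
        max_attempts = max(25 * n_target, 50)
    import time as _time

    report = BuildReport()
    members = []
    attempt = 0
    t_start = _time.time()
    while len(members) < n_target and attempt < max_attempts:
        if time_budget is not None and _time.time() - t_start > time_budget:
            break
        attempt += 1
        report.attempts = attempt
        prov = {"blueprint": bp.name, "seed": seed, "attempt": attempt,
                "stage": "final"}
        s = build_one(bp, lib, cfg, rng, report, provenance=prov)
        if s is not None:
            members.append(s)
            report.accepted += 1
    if len(members) < n_target:
        warnings.warn(
            f"{bp.name}: only {len(members)}/{n_target} structures "
            f"accepted within {max_attempts} attempts", stacklevel=2)
    return Ensemble(bp, members, seed=seed, report=report)
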