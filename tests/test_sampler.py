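"""Monte Carlo sampling: Metropolis correctness, determinism, buriedness,
CCD closure and the toy-blueprint pipeline."""

import numpy as np
import pytest
from scipy import stats

from foldstrain import geometry as geo
from foldstrain.abego import classify_abego, label_matches
from foldstrain.backbone import (BackboneStructure, assign_secondary_structure,
                                 build_from_torsions, detect_helix_kink)
from foldstrain.blueprint import parse_blueprint, sheet_hbond_topology
from foldstrain.ccd import ccd_close, closure_feasible
from foldstrain.fragments import make_synthetic_fragments
from foldstrain.sampler import (MCConfig, _mc_run, _lib_arrays,
                                generate_ensemble, helix_buriedness,
                                relax_with_sheet_constraints)
from foldstrain.sasa import residue_sasa, sphere_points
from foldstrain.scaffold import build_scaffold, sample_and_close
from foldstrain.scoring import (ScoreWeights, default_params,
                                designated_bond_arrays,
                                designated_pair_arrays, score_terms,
                                ss_masks)


def _score(bp, torsions, coords, n, weights, params):
    pi, pj, orient = designated_pair_arrays(bp)
    bd, ba = designated_bond_arrays(bp)
    hm, sm = ss_masks(bp)
    terms = score_terms(coords, torsions, n, pi, pj, orient, hm, sm,
                        bd, ba, params)
    return float(weights @ terms) * params[4]


def test_metropolis_matches_boltzmann():
    """On a 2-residue toy with a discretised fragment set, the empirical
    state distribution over 1e5 steps matches exp(-E/T)/Z."""
    bp = parse_blueprint("name two\nL GB\n")
    lib = make_synthetic_fragments(bp, 3, counts={1: 3, 3: 1, 9: 1})
    torsions = lib.initial_torsions()
    coords = geo.build_from_torsion_array(torsions)
    pi, pj, orient = designated_pair_arrays(bp)
    bd, ba = designated_bond_arrays(bp)
    hm, sm = ss_masks(bp)
    w = ScoreWeights().as_array()
    params = default_params()
    temperature = 2.0
    steps = 100_000
    stride = 20
    record = np.zeros((steps // stride, 2, 3))
    _mc_run(torsions, coords, 2, 0, 1, *_lib_arrays(lib),
            pi, pj, orient, hm, sm, bd, ba, w, params, steps,
            temperature, 17, stride, record)
    # identify states: fragment index chosen per residue
    f0 = lib.torsions[1][0:3, 0, :]
    f1 = lib.torsions[1][3:6, 0, :]

    def state_of(t):
        i = int(np.argmin(np.abs(f0[:, 0] - t[0, 0])))
        j = int(np.argmin(np.abs(f1[:, 0] - t[1, 0])))
        return 3 * i + j

    observed = np.zeros(9)
    for k in range(record.shape[0]):
        observed[state_of(record[k])] += 1
    # exact Boltzmann weights from the same energy function
    energies = np.empty(9)
    for i in range(3):
        for j in range(3):
            t = np.stack([f0[i], f1[j]])
            c = geo.build_from_torsion_array(t)
            energies[3 * i + j] = _score(bp, t, c, 2, w, params)
    weights = np.exp(-(energies - energies.min()) / temperature)
    expected = weights / weights.sum() * observed.sum()
    # thin the correlated samples' effective chi^2 by the stride already
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = 1.0 - stats.chi2.cdf(chi2, df=8)
    assert p > 0.01, (observed, expected, p)


def test_seed_determinism_end_to_end(hairpin_bp):
    cfg = MCConfig.desk_scale()
    a = generate_ensemble(hairpin_bp, 3, seed=5, cfg=cfg)
    b = generate_ensemble(hairpin_bp, 3, seed=5, cfg=cfg)
    c = generate_ensemble(hairpin_bp, 3, seed=6, cfg=cfg)
    assert len(a) == len(b) == 3
    for ma, mb in zip(a, b):
        assert np.array_equal(ma.coords, mb.coords)
    assert not all(np.array_equal(ma.coords, mc.coords)
                   for ma, mc in zip(a, c))


def test_toy_hairpin_ensemble_passes_revalidation(hairpin_ensemble,
                                                  hairpin_bp):
    topo = sheet_hbond_topology(hairpin_bp)
    labels = hairpin_bp.residue_labels()
    n = hairpin_bp.n_residues
    for m in hairpin_ensemble:
        # designated ABEGO respected (undefined terminal angles skipped)
        for r in range(1, n - 1):
            assert label_matches(classify_abego(*m.torsions[r]),
                                 labels[r])
        # the sheet is present at the formation-filter cutoff
        ss = assign_secondary_structure(m, cutoff=-0.3)
        assert "E" in ss


def test_empty_ensemble_request(hairpin_bp):
    ens = generate_ensemble(hairpin_bp, 0, seed=1,
                            cfg=MCConfig.desk_scale())
    assert len(ens) == 0
    assert ens.report.attempts == 0


def _scaffold_with_retries(bp, lib, seed, tries=25):
    from foldstrain.scaffold import ScaffoldError
    rng = np.random.default_rng(seed)
    for _ in range(tries):
        try:
            return build_scaffold(bp, lib, rng)
        except ScaffoldError:
            continue
    raise RuntimeError("no scaffold after retries")


def test_relax_preserves_satisfied_constraints(parallel_bp):
    """With all designated pairs already in range, the relaxation keeps
    them there (its flat-bottom penalties stay inactive)."""
    from foldstrain.blueprint import aligned_pairs
    lib = make_synthetic_fragments(parallel_bp, 2)
    s = _scaffold_with_retries(parallel_bp, lib, 0)
    cfg = MCConfig.desk_scale()
    out, _ = relax_with_sheet_constraints(s, parallel_bp, cfg, seed=4,
                                          lib=lib)
    p = parallel_bp.pairings[0]
    oa = parallel_bp.element_offset(p.strand_a)
    ob = parallel_bp.element_offset(p.strand_b)
    dists = [np.linalg.norm(out.ca[oa + i] - out.ca[ob + j])
             for i, j in aligned_pairs(parallel_bp, p)]
    assert np.median(dists) < 6.5


def test_relax_pulls_constrained_pair_back(parallel_bp):
    """A paired CA pair stretched to ~8 A returns below 5.7 A."""
    lib = make_synthetic_fragments(parallel_bp, 2)
    s = _scaffold_with_retries(parallel_bp, lib, 1)
    from foldstrain.blueprint import aligned_pairs
    p = parallel_bp.pairings[0]
    oa = parallel_bp.element_offset(p.strand_a)
    ob = parallel_bp.element_offset(p.strand_b)
    pairs = [(oa + i, ob + j) for i, j in aligned_pairs(parallel_bp, p)]

    def med(st):
        return np.median([np.linalg.norm(st.ca[i] - st.ca[j])
                          for i, j in pairs])

    stretched = None
    for res in (5, 6, 7):
        for kick in (25.0, -25.0, 40.0, -40.0):
            t = s.torsions.copy()
            t[res, 1] += kick
            cand = BackboneStructure(t)
            if 6.0 < med(cand) < 12.0:
                stretched = cand
                break
        if stretched is not None:
            break
    assert stretched is not None
    d0 = med(stretched)
    cfg = MCConfig.desk_scale()
    out, _ = relax_with_sheet_constraints(stretched, parallel_bp, cfg,
                                          seed=4, lib=lib)
    d1 = np.median([np.linalg.norm(out.ca[i] - out.ca[j])
                    for i, j in pairs])
    assert d1 <= 5.7


def test_ccd_closure_success_rate(parallel_bp):
    """Closure of a 6-residue gap whose anchors are ~12 A apart succeeds
    (deviation < 0.2 A) in >= 90% of seeds with gap-ranked starts."""
    base = np.tile([-120.0, 130.0, 180.0], (9, 1))
    rng = np.random.default_rng(2)
    bp = parse_blueprint("name l\nL BGBGBGBBB\n")
    lib = make_synthetic_fragments(bp, 4)
    wins = 0
    trials = 20
    for _ in range(trials):
        # a reachable target: anchor frame from a random compact loop
        t_true = base.copy()
        t_true[1:7, 0] = rng.uniform(-160, -60, 6)
        t_true[1:7, 1] = rng.uniform(60, 170, 6)
        c_true = geo.build_from_torsion_array(t_true)
        gap = np.linalg.norm(c_true[7, geo.AT_CA] - c_true[0, geo.AT_CA])
        targets = np.stack([c_true[7, geo.AT_N], c_true[7, geo.AT_CA],
                            c_true[7, geo.AT_C]])
        assert closure_feasible(gap, 6)
        t_cl, dev = sample_and_close(bp, lib, base.copy(),
                                     geo.build_from_torsion_array(base),
                                     1, 6, targets, rng, tries=10,
                                     tol=0.2, ccd_tol=0.5,
                                     bin_bias=False)
        wins += t_cl is not None
    assert wins >= 0.9 * trials


def test_ccd_infeasible_gap_detected():
    assert not closure_feasible(60.0, 5)  # 5 x 3.8 + slack < 60


def test_buriedness_isolated_helix_fails():
    s = build_from_torsions(np.tile([-57.0, -47.0, 180.0], (10, 1)))
    areas, ok = helix_buriedness(s, (0, 9), context_residues=[])
    assert not ok
    assert np.all(areas > 40.0)


def test_buriedness_caged_helix_passes():
    helix = build_from_torsions(np.tile([-57.0, -47.0, 180.0], (10, 1)))
    n = len(helix)
    # synthetic cage: surround the helix with a dense shell of context
    # residues so that every probe position is occluded
    centre = helix.ca.mean(axis=0)
    shell = []
    for theta in np.linspace(0, np.pi, 10):
        for phi in np.linspace(0, 2 * np.pi, 18, endpoint=False):
            shell.append(centre + 9.0 * np.array([
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi), np.cos(theta)]))
    extra = np.zeros((len(shell), 6, 3))
    for k, p in enumerate(shell):
        extra[k] = p  # all six centres collapsed on the shell point
    coords = np.concatenate([helix.coords, extra])
    torsions = np.full((len(coords), 3), 180.0)
    caged = BackboneStructure(torsions, coords)
    areas, ok = helix_buriedness(caged, (0, 9),
                                 context_residues=range(n, len(coords)))
    assert ok
    assert np.median(areas) < 40.0


def test_sasa_matches_dense_oracle(rng):
    """Coarse-atom accessible areas agree with a dense-sampling
    Shrake-Rupley oracle within 2%."""
    for trial in range(3):
        t = np.column_stack([rng.uniform(-150, -50, 8),
                             rng.uniform(-50, 150, 8),
                             np.full(8, 180.0)])
        s = build_from_torsions(t)
        got = residue_sasa(s, range(8), [], n_points=2000)
        # independent oracle: same algorithm re-derived with different
        # (random-direction) surface sampling
        centers = s.coords.reshape(-1, 3)
        radii = np.tile([geo.RADII[a] for a in geo.ATOM_ORDER], 8)
        probe = 2.0
        oracle = np.zeros(len(centers))
        dirs = rng.normal(size=(8000, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        for a in range(len(centers)):
            ra = radii[a] + probe
            pts = centers[a] + ra * dirs
            free = np.ones(len(pts), dtype=bool)
            for b in range(len(centers)):
                if b == a:
                    continue
                rb = radii[b] + probe
                free &= (np.sum((pts - centers[b]) ** 2, axis=1)
                         >= rb * rb)
            oracle[a] = 4 * np.pi * ra * ra * free.mean()
        oracle_res = oracle.reshape(8, 6).sum(axis=1)
        assert np.allclose(got, oracle_res, rtol=0.02, atol=2.0)
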