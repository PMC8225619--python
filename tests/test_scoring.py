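"""Score terms: zero cases, weight linearity, oracle agreement."""

import numpy as np
import pytest

from foldstrain import geometry as geo
from foldstrain.backbone import build_from_torsions, hbond_energy
from foldstrain.blueprint import parse_blueprint
from foldstrain.scoring import (ScoreWeights, TERM_NAMES, VDW_SCALE,
                                score_structure)


def test_single_residue_scores_zero(hairpin_bp):
    s = build_from_torsions([[180.0, -120.0, 180.0]])
    total, terms = score_structure(s, hairpin_bp, n_built=1)
    assert terms["vdw"] == 0.0
    assert terms["rg"] == 0.0
    assert terms["ss_pair"] == 0.0
    assert terms["hbond_sr_bb"] == 0.0


def test_weight_linearity(hairpin_bp, rng):
    t = np.column_stack([rng.uniform(-150, -60, 10),
                         rng.uniform(-60, 150, 10),
                         np.full(10, 175.0)])
    s = build_from_torsions(t)
    base = ScoreWeights()
    total1, terms = score_structure(s, hairpin_bp, base)
    doubled = ScoreWeights(rg=2.0)
    total2, _ = score_structure(s, hairpin_bp, doubled)
    assert total2 - total1 == pytest.approx(terms["rg"], rel=1e-12)


def test_vdw_matches_hand_formula(rng):
    """vdw equals an independent evaluation of the scaled soft-sphere
    formula over the CA/CB sphere pairs."""
    bp = parse_blueprint("name t\nL GGGGGGGG\n")
    t = np.column_stack([rng.uniform(20, 100, 8),
                         rng.uniform(-90, 90, 8),
                         np.full(8, 180.0)])
    s = build_from_torsions(t)
    _, terms = score_structure(s, bp)
    radii = {geo.AT_CA: geo.RADII["CA"], geo.AT_CB: geo.RADII["CB"]}
    expected = 0.0
    for i in range(8):
        for j in range(i + 2, 8):
            for ai, ri in radii.items():
                for aj, rj in radii.items():
                    d = np.linalg.norm(s.coords[i, ai] - s.coords[j, aj])
                    if d < ri + rj:
                        expected += VDW_SCALE * ((ri + rj - d)
                                                 / (ri + rj)) ** 2
    assert terms["vdw"] == pytest.approx(expected, rel=1e-9)


def test_rg_is_ca_radius_of_gyration(hairpin_bp, rng):
    t = np.column_stack([rng.uniform(-150, -60, 10),
                         rng.uniform(-60, 150, 10),
                         np.full(10, 175.0)])
    s = build_from_torsions(t)
    _, terms = score_structure(s, hairpin_bp)
    ca = s.ca
    expected = np.sqrt(np.mean(np.sum((ca - ca.mean(0)) ** 2, axis=1)))
    assert terms["rg"] == pytest.approx(expected, rel=1e-9)


def test_hbond_terms_sum_per_donor_bests(rng):
    bp = parse_blueprint("name t\nH 12\n")
    s = build_from_torsions(np.tile([-57.0, -47.0, 180.0], (12, 1)))
    _, terms = score_structure(s, bp)
    expected_sr = 0.0
    for i in range(1, 12):
        best = 0.0
        for j in range(12):
            if abs(i - j) >= 2:
                best = min(best, hbond_energy(s, i, j))
        if best < -0.5:
            expected_sr += max(best, -4.0)
    assert terms["hbond_sr_bb"] == pytest.approx(expected_sr, abs=1e-9)
    assert terms["hbond_lr_bb"] == 0.0


def test_omega_term_penalises_cis():
    bp = parse_blueprint("name t\nL GGG\n")
    s = build_from_torsions([[80.0, 0.0, 180.0], [80.0, 0.0, 170.0],
                             [80.0, 0.0, 180.0]])
    _, terms = score_structure(s, bp)
    assert terms["omega"] == pytest.approx(1.0)  # ((170-180)/10)^2


def test_term_names_cover_breakdown(hairpin_bp):
    s = build_from_torsions(np.tile([-120.0, 130.0, 180.0], (10, 1)))
    _, terms = score_structure(s, hairpin_bp)
    assert tuple(terms) == TERM_NAMES
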