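"""Strain metrics: closed forms, synthetic-geometry cases, invariances,
ensemble averaging."""

import numpy as np
import pytest

from foldstrain import geometry as geo
from foldstrain.backbone import BackboneStructure, build_from_torsions
from foldstrain.blueprint import (Blueprint, SSElement, StrandPairing,
                                  parse_blueprint, sheet_hbond_topology)
from foldstrain.sampler import Ensemble
from foldstrain.strain import (average_structure, ensemble_metrics,
                               formability, hbond_probabilities,
                               packability, sheet_bend_angle,
                               terminal_helix_distance)


def test_formability_closed_forms():
    assert formability([1.0, 1.0, 1.0]) == 0.0
    assert formability([0.5, 0.5]) == pytest.approx(2 * np.log(0.5))
    with pytest.raises(ValueError):
        formability([0.0, 1.0])


def test_hbond_probability_counts_and_floor(hairpin_ensemble, hairpin_bp):
    topo = sheet_hbond_topology(hairpin_bp)
    probs = hbond_probabilities(hairpin_ensemble, topo)
    n = len(hairpin_ensemble)
    assert np.all(probs >= 1.0 / (2 * n))
    assert np.all(probs <= 1.0)
    # formability composes over the per-bond probabilities
    f = formability(probs)
    assert f == pytest.approx(float(np.sum(np.log(probs))))
    assert f <= 0.0


def test_excluded_bond_skipped(hairpin_ensemble, hairpin_bp):
    topo = sheet_hbond_topology(hairpin_bp)
    topo.bonds[0].excluded = True
    probs = hbond_probabilities(hairpin_ensemble, topo)
    assert np.isnan(probs[0])
    assert not np.isnan(probs[1:]).any()
    topo.bonds[0].excluded = False


def _two_helix_structure(separation):
    """Two ideal 12-residue helices with parallel axes ``separation`` A
    apart, joined by a dummy loop."""
    bp = parse_blueprint("name hh\nH 12\nL GG\nH 12\n")
    t = np.tile([-57.0, -47.0, 180.0], (12, 1))
    helix = geo.build_from_torsion_array(t)
    coords = np.zeros((26, 6, 3))
    coords[0:12] = helix
    coords[12:14] = helix[-1] + np.array([30.0, 30.0, 0.0])
    # ideal helix built along a known axis; copy and translate
    # perpendicular to that axis
    _, d = _axis_of(helix)
    perp = np.cross(d, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 0.5:
        perp = np.cross(d, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    coords[14:26] = helix + separation * perp
    s = BackboneStructure(np.full((26, 3), 180.0), coords)
    return s, bp


def _axis_of(helix_coords):
    from foldstrain.backbone import fit_helix_axis
    s = BackboneStructure(np.full((len(helix_coords), 3), 180.0),
                          helix_coords.copy())
    return fit_helix_axis(s, (0, len(helix_coords) - 1))


def test_terminal_helix_distance_analytic():
    s, bp = _two_helix_structure(10.0)
    assert terminal_helix_distance(s, bp) == pytest.approx(10.0, abs=0.1)


def test_terminal_helix_distance_invariances():
    s, bp = _two_helix_structure(9.0)
    d0 = terminal_helix_distance(s, bp)
    theta = 0.9
    rot = np.array([[np.cos(theta), 0, np.sin(theta)],
                    [0, 1, 0],
                    [-np.sin(theta), 0, np.cos(theta)]])
    moved = s.transformed(rot, np.array([4.0, 5.0, -6.0]))
    assert terminal_helix_distance(moved, bp) == pytest.approx(d0,
                                                               abs=1e-6)


def test_helix_distance_to_itself_is_zero():
    bp = parse_blueprint("name hh\nH 12\nL GG\nH 12\n")
    t = np.tile([-57.0, -47.0, 180.0], (12, 1))
    helix = geo.build_from_torsion_array(t)
    coords = np.zeros((26, 6, 3))
    coords[0:12] = helix
    coords[12:14] = helix[-1] + 30.0
    coords[14:26] = helix          # identical copy
    s = BackboneStructure(np.full((26, 3), 180.0), coords)
    assert terminal_helix_distance(s, bp) < 1e-6


class _FakeEnsemble(list):
    blueprint = None


def test_packability_closed_forms_and_monotonicity(hairpin_bp):
    bp = parse_blueprint("name hh\nH 12\nL GG\nH 12\n")
    close, _ = _two_helix_structure(8.0)
    far, _ = _two_helix_structure(14.0)
    all_close = [close] * 4
    assert packability(all_close, bp) == 0.0
    half = [close, close, far, far]
    assert packability(half, bp) == pytest.approx(np.log(0.5))
    none = [far] * 4
    assert packability(none, bp) == pytest.approx(np.log(0.5 / 4))
    # monotone in the threshold
    assert packability(half, bp, threshold=10.0) <= \
        packability(half, bp, threshold=12.0)


def _grid_sheet_bp_and_coords(fold_deg=0.0):
    """Synthetic 3-strand sheet: strand CAs on a planar grid, with the
    third strand's half-plane folded by ``fold_deg`` about the middle
    strand axis."""
    bp = Blueprint("s3", [SSElement("E", 5), SSElement("L", 1, abego="G"),
                          SSElement("E", 5), SSElement("L", 1, abego="G"),
                          SSElement("E", 5)],
                   [StrandPairing(0, 2, 0), StrandPairing(2, 4, 0)])
    coords = np.zeros((17, 6, 3))
    spans = [bp.element_span(e) for e in bp.strand_elements()]
    theta = np.radians(fold_deg)
    rows = [np.zeros(3),
            np.array([0.0, 4.8, 0.0]),
            np.array([0.0, 4.8 + 4.8 * np.cos(theta),
                      4.8 * np.sin(theta)])]
    for (a, b), offset in zip(spans, rows):
        for k in range(5):
            coords[a + k, geo.AT_CA] = offset + np.array([3.3 * k, 0, 0])
    return bp, BackboneStructure(np.full((17, 3), 180.0), coords)


def test_bend_angle_flat_sheet():
    bp, s = _grid_sheet_bp_and_coords(0.0)
    assert sheet_bend_angle(s, bp) == pytest.approx(0.0, abs=0.5)


def test_bend_angle_constructed_fold():
    bp, s = _grid_sheet_bp_and_coords(30.0)
    assert sheet_bend_angle(s, bp) == pytest.approx(30.0, abs=1.0)


def test_bend_angle_rigid_invariance():
    bp, s = _grid_sheet_bp_and_coords(25.0)
    a0 = sheet_bend_angle(s, bp)
    theta = 1.3
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    assert sheet_bend_angle(s.transformed(rot, [1., 2., 3.]), bp) == \
        pytest.approx(a0, abs=1e-6)


def test_bend_angle_needs_three_strands(hairpin_bp):
    s = build_from_torsions(np.tile([-120.0, 130.0, 180.0], (10, 1)))
    with pytest.raises(ValueError):
        sheet_bend_angle(s, hairpin_bp)


def test_average_of_identical_copies(rng):
    t = np.column_stack([rng.uniform(-150, -60, 12),
                         rng.uniform(-60, 150, 12),
                         np.full(12, 180.0)])
    m = build_from_torsions(t)
    avg = average_structure([m.copy() for _ in range(5)], seed=1)
    dev = np.abs(avg.mean_coords[:, 1, :] - m.ca).max()
    assert dev < 1e-6
    assert np.all(avg.spread < 1e-6)


def test_average_recovers_rigidly_scattered_copies(rng):
    t = np.column_stack([rng.uniform(-150, -60, 12),
                         rng.uniform(-60, 150, 12),
                         np.full(12, 180.0)])
    m = build_from_torsions(t)
    members = []
    for _ in range(6):
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        members.append(m.transformed(rot, rng.uniform(-20, 20, 3)))
    avg = average_structure(members, seed=2)
    moved, rmsd = geo.kabsch_superpose(avg.mean_coords[:, 1, :], m.ca)
    assert rmsd < 1e-3


def test_idealised_average_has_ideal_bonds(hairpin_ensemble):
    avg = average_structure(hairpin_ensemble, seed=3)
    c = avg.structure.coords
    n = len(avg.structure)
    for i in range(n):
        assert np.linalg.norm(c[i, geo.AT_CA] - c[i, geo.AT_N]) == \
            pytest.approx(geo.BOND_N_CA, abs=1e-3)
        if i:
            assert np.linalg.norm(c[i, geo.AT_N] - c[i - 1, geo.AT_C]) \
                == pytest.approx(geo.BOND_C_N, abs=1e-3)


def test_average_rejects_mismatched_lengths(hairpin_ensemble):
    short = build_from_torsions(np.tile([-57.0, -47.0, 180.0], (4, 1)))
    with pytest.raises(ValueError):
        average_structure(list(hairpin_ensemble) + [short], seed=0)


def test_ensemble_metrics_summary(hairpin_ensemble, hairpin_bp):
    # hairpins have two strands -> no bend angle; use metrics pieces
    topo = sheet_hbond_topology(hairpin_bp)
    probs = hbond_probabilities(hairpin_ensemble, topo)
    assert formability(probs) <= 0.0
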