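"""Geometry round-trips, hydrogen-bond detection, secondary structure,
helix axes and kink detection."""

import numpy as np
import pytest

from foldstrain import geometry as geo
from foldstrain.backbone import (BackboneStructure, assign_secondary_structure,
                                 build_from_torsions, compute_hbonds,
                                 detect_helix_kink, fit_helix_axis,
                                 hbond_energy)

KS = 0.084 * 332.0


def random_chain(rng, n=15):
    t = np.column_stack([rng.uniform(-179, 180, n),
                         rng.uniform(-179, 180, n),
                         rng.uniform(150, 180, n)])
    return build_from_torsions(t), t


def test_torsion_coordinate_roundtrip(rng):
    worst = 0.0
    for _ in range(200):
        s, t = random_chain(rng)
        m = s.measured_torsions()
        err = np.abs(m - t)
        err[0, 0] = err[-1, 1] = err[-1, 2] = 0.0  # undefined at termini
        worst = max(worst, float(err.max()))
    assert worst < 1e-6


def test_single_residue_chain():
    s = build_from_torsions([[180.0, 180.0, 180.0]])
    assert len(s) == 1
    assert compute_hbonds(s) == []


def test_built_geometry_matches_ideal_table(rng):
    s, _ = random_chain(rng, 10)
    c = s.coords
    for i in range(10):
        assert np.linalg.norm(c[i, geo.AT_CA] - c[i, geo.AT_N]) == \
            pytest.approx(geo.BOND_N_CA, abs=1e-6)
        assert np.linalg.norm(c[i, geo.AT_C] - c[i, geo.AT_CA]) == \
            pytest.approx(geo.BOND_CA_C, abs=1e-6)
        if i:
            assert np.linalg.norm(c[i, geo.AT_N] - c[i - 1, geo.AT_C]) == \
                pytest.approx(geo.BOND_C_N, abs=1e-6)


def test_kabsch_sander_hand_evaluation():
    """A constructed geometry with r_ON=2.9, r_CH=3.9, r_OH=1.9 and
    r_CN=3.9 A scores exactly the hand-evaluated energy."""
    coords = np.zeros((2, 6, 3))
    # acceptor residue 0 far placeholder positions; donor residue 1
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.01, 0.0, 0.0])
    # O satisfying |N-O| = 2.9, |H-O| = 1.9
    ox = (2.9 ** 2 - 1.9 ** 2 + 1.01 ** 2) / (2 * 1.01)
    o = np.array([ox, np.sqrt(2.9 ** 2 - ox ** 2), 0.0])
    # C satisfying |N-C| = 3.9, |H-C| = 3.9
    cx = 1.01 / 2
    c = np.array([cx, np.sqrt(3.9 ** 2 - cx ** 2), 0.0])
    coords[1, geo.AT_N] = n
    coords[1, geo.AT_H] = h
    coords[0, geo.AT_O] = o
    coords[0, geo.AT_C] = c
    coords[0, geo.AT_CA] = o + 0.1
    coords[1, geo.AT_CA] = n + 0.1
    s = BackboneStructure(np.full((2, 3), 180.0), coords)
    expected = KS * (1 / 2.9 + 1 / 3.9 - 1 / 1.9 - 1 / 3.9)
    # hbond_energy rejects |i-j| < 2; evaluate via the same geometry on a
    # padded chain
    coords4 = np.zeros((4, 6, 3))
    coords4[3] = coords[1]
    coords4[0] = coords[0]
    coords4[1, :, :] = 50.0
    coords4[2, :, :] = 60.0
    s4 = BackboneStructure(np.full((4, 3), 180.0), coords4)
    assert hbond_energy(s4, 3, 0) == pytest.approx(expected, abs=1e-9)


def test_distant_residues_have_no_bonds():
    coords = np.zeros((2, 6, 3))
    coords[1] += 30.0
    s = BackboneStructure(np.full((2, 3), 180.0), coords)
    assert compute_hbonds(s) == []


def test_ideal_helix_bonds_and_assignment():
    s = build_from_torsions(np.tile([-57.0, -47.0, 180.0], (12, 1)))
    bonds = {(b.donor, b.acceptor) for b in compute_hbonds(s)}
    for i in range(8):
        assert (i + 4, i) in bonds
    ss = assign_secondary_structure(s)
    assert set(ss[2:12]) == {"H"}


def test_extended_chain_is_loop_without_partner():
    s = build_from_torsions(np.tile([-120.0, 130.0, 180.0], (10, 1)))
    assert assign_secondary_structure(s) == "L" * 10


def test_hbonds_equal_all_pairs_oracle(rng):
    """compute_hbonds (with its CA prefilter) equals a brute-force
    all-pairs per-donor-best evaluation on compact random chains."""
    for _ in range(10):
        n = int(rng.integers(8, 30))
        t = np.column_stack([rng.uniform(-150, -40, n),
                             rng.uniform(-60, 160, n),
                             np.full(n, 180.0)])
        s = build_from_torsions(t)
        got = {(b.donor, b.acceptor): b.energy for b in compute_hbonds(s)}
        expect = {}
        for i in range(1, n):
            best = (None, -0.5)
            for j in range(n):
                if abs(i - j) < 2:
                    continue
                e = hbond_energy(s, i, j)
                if e < best[1]:
                    best = (j, e)
            if best[0] is not None:
                expect[(i, best[0])] = best[1]
        assert set(got) == set(expect)
        for k in got:
            assert got[k] == pytest.approx(expect[k], abs=1e-9)


def test_assignment_rigid_motion_invariant(rng):
    s = build_from_torsions(np.tile([-57.0, -47.0, 180.0], (12, 1)))
    theta = 1.1
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1.0]])
    moved = s.transformed(rot, np.array([5.0, -3.0, 12.0]))
    assert assign_secondary_structure(moved) == \
        assign_secondary_structure(s)


def _helix_ca_structure(n, radius=2.3, rise=1.5, phase=0.0):
    """Structure whose CA trace lies exactly on a helix around z."""
    coords = np.zeros((n, 6, 3))
    k = np.arange(n)
    ang = phase + k * np.radians(99.6)
    coords[:, geo.AT_CA, 0] = radius * np.cos(ang)
    coords[:, geo.AT_CA, 1] = radius * np.sin(ang)
    coords[:, geo.AT_CA, 2] = rise * k
    return BackboneStructure(np.full((n, 3), 180.0), coords)


@pytest.mark.parametrize("n", [6, 10, 14, 20])
def test_helix_axis_recovers_generating_axis(n):
    s = _helix_ca_structure(n)
    point, direction = fit_helix_axis(s, (0, n - 1))
    assert abs(abs(direction[2]) - 1.0) < 1e-3
    assert direction[2] > 0  # oriented N->C
    # axis passes within 0.05 A of the z axis
    assert np.linalg.norm(point[:2]) < 0.05


def test_helix_axis_equivariance(rng):
    s = _helix_ca_structure(12)
    theta = 0.7
    rot = np.array([[1, 0, 0],
                    [0, np.cos(theta), -np.sin(theta)],
                    [0, np.sin(theta), np.cos(theta)]])
    trans = np.array([3.0, -2.0, 8.0])
    moved = s.transformed(rot, trans)
    p1, d1 = fit_helix_axis(s, (0, 11))
    p2, d2 = fit_helix_axis(moved, (0, 11))
    assert np.allclose(rot @ d1, d2, atol=1e-9)
    assert np.allclose(rot @ p1 + trans, p2, atol=1e-9)


def test_helix_axis_span_too_short():
    s = _helix_ca_structure(6)
    with pytest.raises(ValueError):
        fit_helix_axis(s, (0, 2))


def test_kink_detection():
    ideal = build_from_torsions(np.tile([-57.0, -47.0, 180.0], (14, 1)))
    assert not detect_helix_kink(ideal, (0, 13))
    t = np.tile([-57.0, -47.0, 180.0], (14, 1))
    t[7] = [-120.0, 130.0, 180.0]  # breaks the helical bond pattern
    assert detect_helix_kink(build_from_torsions(t), (0, 13))
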