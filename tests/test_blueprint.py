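"""Blueprint parsing, validation and sheet hydrogen-bond topology."""

import pytest

from foldstrain.blueprint import (ANTIPARALLEL, PARALLEL, Blueprint,
                                  BlueprintError, SSElement, StrandPairing,
                                  aligned_pairs, builtin_blueprint_names,
                                  builtin_blueprints, get_blueprint,
                                  parse_blueprint, sheet_hbond_topology,
                                  validate_blueprint, write_blueprint)


def test_parse_minimal_hairpin():
    bp = parse_blueprint("name h\nE 4\nL GG\nE 4\nP 1 3 3 anti\n")
    assert len(bp.elements) == 3
    assert bp.n_residues == 10
    assert bp.pairings[0].orientation == ANTIPARALLEL


def test_roundtrip_identity_on_all_builtins():
    for name in builtin_blueprint_names():
        bp = get_blueprint(name)
        assert parse_blueprint(write_blueprint(bp)) == bp


def test_self_pairing_rejected():
    with pytest.raises(BlueprintError, match="StrandPairing"):
        parse_blueprint("name bad\nE 4\nL GG\nE 4\nP 3 3 0 anti\n")


def test_pairing_to_helix_rejected():
    with pytest.raises(BlueprintError, match="non-strand"):
        parse_blueprint("name bad\nE 4\nL GG\nH 6\nP 1 3 0 par\n")


def test_parts_must_cover_elements():
    bp = Blueprint("p", [SSElement("E", 4), SSElement("L", 2, abego="GG"),
                         SSElement("E", 4)],
                   [StrandPairing(0, 2, 3, ANTIPARALLEL)],
                   parts=[(0, 1)])
    report = validate_blueprint(bp)
    assert any("parts do not cover" in r for r in report)


def test_non_alternating_pleats_flagged():
    bp = Blueprint("p", [SSElement("E", 4, pleats="++--")], [])
    report = validate_blueprint(bp)
    assert any("pleat" in r for r in report)


def test_builtin_inventory_and_validity():
    bps = builtin_blueprints()
    r2 = bps["R2x3_BP1"]
    assert len(r2.strand_elements()) == 5
    assert len(r2.helix_elements()) == 5
    r3 = bps["R3x3_BP1"]
    assert len(r3.strand_elements()) == 6
    assert len(r3.helix_elements()) == 6
    for bp in bps.values():
        assert validate_blueprint(bp) == []
    assert get_blueprint("R2×3_BP1").name == "R2x3_BP1"
    with pytest.raises(KeyError):
        get_blueprint("nope")


def test_single_strand_has_empty_topology():
    bp = parse_blueprint("name s\nE 5\n")
    assert sheet_hbond_topology(bp).bonds == []


def test_parallel_ladder_matches_hand_enumeration():
    """Two parallel 3-residue strands at register 0: the participating
    rung at local index 0 contributes NH(b1)->CO(a0); the rung at local
    index 2 contributes NH(a2)->CO(b1)."""
    bp = parse_blueprint("name p\nE 3\nL GB\nE 3\nP 1 3 0 par\n")
    bonds = [(b.donor, b.acceptor) for b in sheet_hbond_topology(bp).bonds]
    assert bonds == [(6, 0), (2, 6)]


def _brute_force_ladder(bp):
    """Independent oracle: walk every aligned rung of the (single)
    pairing at the first-strand parity and place ladder bonds."""
    p = bp.pairings[0]
    oa = bp.element_offset(p.strand_a)
    ob = bp.element_offset(p.strand_b)
    lb = bp.elements[p.strand_b].length
    bonds = []
    for i, j in aligned_pairs(bp, p):
        if i % 2 != 0:
            continue
        if p.orientation == PARALLEL:
            if j - 1 >= 0 and oa + i > 0:
                bonds.append((oa + i, ob + j - 1))
            if j + 1 < lb and ob + j + 1 > 0:
                bonds.append((ob + j + 1, oa + i))
        else:
            if oa + i > 0:
                bonds.append((oa + i, ob + j))
            if ob + j > 0:
                bonds.append((ob + j, oa + i))
    seen = set()
    out = []
    for d, a in bonds:
        if d not in seen:
            seen.add(d)
            out.append((d, a))
    return out


@pytest.mark.parametrize("la", [3, 4, 5, 6])
@pytest.mark.parametrize("lb", [3, 4, 6])
@pytest.mark.parametrize("shift", [-3, -1, 0, 1, 2, 3])
@pytest.mark.parametrize("orient", ["par", "anti"])
def test_topology_equals_brute_force(la, lb, shift, orient):
    if orient == "anti":
        shift = shift + lb - 1  # re-centre the sum convention
    text = (f"name t\nE {la}\nL GG\nE {lb}\n"
            f"P 1 3 {shift} {orient}\n")
    try:
        bp = parse_blueprint(text)
    except BlueprintError:
        return  # no aligned residues at this shift; nothing to compare
    got = [(b.donor, b.acceptor) for b in sheet_hbond_topology(bp).bonds]
    assert got == _brute_force_ladder(bp)


def test_register_shift_translates_partners():
    base = parse_blueprint("name t\nE 6\nL GG\nE 6\nP 1 3 0 par\n")
    shifted = parse_blueprint("name t\nE 6\nL GG\nE 6\nP 1 3 2 par\n")
    bonds0 = {b.donor: b.acceptor
              for b in sheet_hbond_topology(base).bonds}
    bonds2 = {b.donor: b.acceptor
              for b in sheet_hbond_topology(shifted).bonds}
    # donors on the first strand keep their index; partners move by +2
    for d, a in bonds0.items():
        if d < 6 and d in bonds2:
            assert bonds2[d] == a + 2


def test_contradictory_pairings_rejected():
    text = ("name t\nE 4\nL GG\nE 4\nP 1 3 3 anti\nP 3 1 2 anti\n")
    with pytest.raises(BlueprintError, match="contradicts"):
        parse_blueprint(text)


def test_no_residue_donates_twice():
    for name in builtin_blueprint_names():
        topo = sheet_hbond_topology(get_blueprint(name))
        donors = [b.donor for b in topo.bonds]
        assert len(donors) == len(set(donors))
        assert 0 not in donors  # first residue has no amide proton
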