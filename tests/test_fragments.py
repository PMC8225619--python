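"""Synthetic fragment generation and the fragment-table loader."""

import numpy as np
import pytest

from foldstrain.abego import classify_abego, label_matches
from foldstrain.fragments import (FRAGMENT_LENGTHS, load_fragment_file,
                                  make_synthetic_fragments)


def test_fragments_satisfy_compatibility_tags(parallel_bp):
    lib = make_synthetic_fragments(parallel_bp, 5)
    labels = parallel_bp.residue_labels()
    for length in FRAGMENT_LENGTHS:
        for pos in range(len(lib.counts[length])):
            for frag in lib.fragments_at(pos, length):
                for r in range(length):
                    lab = classify_abego(*frag[r])
                    assert label_matches(lab, labels[pos + r]), \
                        (length, pos, r, lab, labels[pos + r])


def test_loop_fragments_follow_pattern(hairpin_bp):
    # loop 'GG' at positions 4-5 (0-based): 1-mers there classify as G
    lib = make_synthetic_fragments(hairpin_bp, 5)
    for pos in (4, 5):
        for frag in lib.fragments_at(pos, 1):
            assert classify_abego(*frag[0]) == "G"


def test_seed_determinism(hairpin_bp):
    a = make_synthetic_fragments(hairpin_bp, 9)
    b = make_synthetic_fragments(hairpin_bp, 9)
    c = make_synthetic_fragments(hairpin_bp, 10)
    for length in FRAGMENT_LENGTHS:
        assert np.array_equal(a.torsions[length], b.torsions[length])
    assert not np.array_equal(a.torsions[1], c.torsions[1])


def test_initial_torsions_are_bin_representatives(hairpin_bp):
    lib = make_synthetic_fragments(hairpin_bp, 5)
    t = lib.initial_torsions()
    labels = hairpin_bp.residue_labels()
    for r in range(hairpin_bp.n_residues):
        assert label_matches(classify_abego(*t[r]), labels[r])


def test_fragment_file_roundtrip(tmp_path, hairpin_bp):
    lib = make_synthetic_fragments(hairpin_bp, 5)
    path = tmp_path / "frags.txt"
    with open(path, "w") as fh:
        for length in FRAGMENT_LENGTHS:
            for pos in range(len(lib.counts[length])):
                for frag in lib.fragments_at(pos, length):
                    vals = " ".join(f"{v:.4f}" for v in frag.reshape(-1))
                    fh.write(f"{pos + 1} {length} {vals}\n")
    loaded = load_fragment_file(path, hairpin_bp)
    for length in FRAGMENT_LENGTHS:
        assert np.allclose(loaded.torsions[length],
                           lib.torsions[length], atol=1e-3)


def test_fragment_file_rejects_incompatible_torsions(tmp_path, hairpin_bp):
    path = tmp_path / "bad.txt"
    # position 1 is a strand (B); alpha torsions are incompatible
    path.write_text("1 1 -60.0 -45.0 180.0\n")
    with pytest.raises(ValueError, match="classif"):
        load_fragment_file(path, hairpin_bp)
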