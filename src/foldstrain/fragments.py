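"""Torsion-fragment libraries for fragment-assembly Monte Carlo.

Moves replace the (phi, psi, omega) of a 1-, 3- or 9-residue frame with a
fragment compatible with the secondary structure and extended ABEGO label
the blueprint assigns at each covered position.  The shipped generator is
synthetic: it draws torsions from per-bin truncated Gaussians (see
:data:`foldstrain.abego.BIN_TORSION_PARAMS`), which removes any dependency
on an external structure database.  A loader for user-supplied fragment
tables is provided for fidelity studies against database-derived sets.
"""

from __future__ import annotations

import numpy as np

from .abego import BIN_TORSION_PARAMS, classify_abego, label_matches
from .blueprint import Blueprint

FRAGMENT_LENGTHS = (1, 3, 9)
#: fragments generated per position for each frame length
DEFAULT_COUNTS = {1: 24, 3: 16, 9: 8}


class FragmentLibrary:
    """Per-position fragment sets for each frame length.

    Attributes
    ----------
    n_res : int
    torsions : dict
        length -> (total_frags, length, 3) float64 array.
    offsets, counts : dict
        length -> (n_positions,) int64 arrays; fragments for position p of
        that length occupy rows offsets[p] : offsets[p] + counts[p].
    labels : str
        The per-residue blueprint ABEGO labels the fragments satisfy.
    """

    def __init__(self, n_res: int, labels: str):
        self.n_res = n_res
        self.labels = labels
        self.torsions = {}
        self.offsets = {}
        self.counts = {}

    def add_length(self, length, torsions, offsets, counts):
        self.torsions[length] = np.ascontiguousarray(torsions, float)
        self.offsets[length] = np.ascontiguousarray(offsets, np.int64)
        self.counts[length] = np.ascontiguousarray(counts, np.int64)

    def fragments_at(self, position: int, length: int) -> np.ndarray:
        """All fragments of ``length`` anchored at 0-based ``position``."""
        off = self.offsets[length][position]
        cnt = self.counts[length][position]
        return self.torsions[length][off:off + cnt]

    def initial_torsions(self) -> np.ndarray:
        """Bin-representative (phi, psi, omega) per residue — the
        deterministic starting chain for Monte Carlo."""
        out = np.empty((self.n_res, 3))
        for i, lab in enumerate(self.labels):
            phi, psi, _, _ = BIN_TORSION_PARAMS[lab]
            out[i] = (phi, psi, 0.0 if lab == "O" else 180.0)
        return out


#: bins sampled with phi/psi anticorrelation (beta-like residues keep
#: phi + psi roughly constant, which keeps strands flat enough to ladder)
_DIAGONAL_BINS = frozenset("BCDYZ")


def _sample_bin(lab: str, rng: np.random.Generator) -> tuple:
    """Draw one (phi, psi, omega) inside the given extended bin."""
    phi_m, psi_m, phi_sd, psi_sd = BIN_TORSION_PARAMS[lab]
    for _ in range(64):
        phi = rng.normal(phi_m, phi_sd)
        if lab in _DIAGONAL_BINS:
            # move along the anti-diagonal: phi + psi ~ constant
            psi = (phi_m + psi_m) - phi + rng.normal(0.0, 4.0)
        else:
            psi = rng.normal(psi_m, psi_sd)
        if psi > 180.0:
            psi -= 360.0
        elif psi <= -180.0:
            psi += 360.0
        if lab == "O":
            omega = float(np.clip(rng.normal(0.0, 5.0), -85.0, 85.0))
        else:
            omega = 180.0 - abs(rng.normal(0.0, 2.5))
        if label_matches(classify_abego(phi, psi, omega), lab):
            return phi, psi, omega
    return phi_m, psi_m, 0.0 if lab == "O" else 180.0


def make_synthetic_fragments(bp: Blueprint, seed: int,
                             counts: dict | None = None) -> FragmentLibrary:
    """Build a synthetic fragment library for a blueprint.

    Deterministic under ``seed``; every fragment satisfies its
    compatibility tag (verified by re-classification during sampling).
    """
    merged = dict(DEFAULT_COUNTS)
    merged.update(counts or {})
    counts = merged
    labels = bp.residue_labels()
    n = bp.n_residues
    rng = np.random.default_rng(seed)
    lib = FragmentLibrary(n, labels)
    for length in FRAGMENT_LENGTHS:
        n_pos = max(n - length + 1, 0)
        k = counts[length]
        tors = np.empty((n_pos * k, length, 3))
        offs = np.arange(n_pos, dtype=np.int64) * k
        cnts = np.full(n_pos, k, dtype=np.int64)
        for p in range(n_pos):
            for f in range(k):
                for r in range(length):
                    tors[p * k + f, r] = _sample_bin(labels[p + r], rng)
        lib.add_length(length, tors, offs, cnts)
    return lib


def load_fragment_file(path, bp: Blueprint) -> FragmentLibrary:
    """Load a whitespace fragment table: ``pos len phi psi omega ...``
    (one fragment per line, ``len`` torsion triples, 1-based positions)."""
    labels = bp.residue_labels()
    n = bp.n_residues
    per = {length: [[] for _ in range(max(n - length + 1, 0))]
           for length in FRAGMENT_LENGTHS}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            pos, length = int(tok[0]) - 1, int(tok[1])
            if length not in FRAGMENT_LENGTHS:
                raise ValueError(f"line {lineno}: unsupported fragment "
                                 f"length {length}")
            vals = np.array(tok[2:], dtype=float)
            if vals.size != 3 * length:
                raise ValueError(f"line {lineno}: expected {3 * length} "
                                 f"torsions, got {vals.size}")
            frag = vals.reshape(length, 3)
            for r in range(length):
                lab = classify_abego(*frag[r])
                if not label_matches(lab, labels[pos + r]):
                    raise ValueError(
                        f"line {lineno}: residue {pos + r + 1} torsions "
                        f"classify as {lab}, blueprint requires "
                        f"{labels[pos + r]}")
            per[length][pos].append(frag)
    lib = FragmentLibrary(n, labels)
    for length in FRAGMENT_LENGTHS:
        rows = per[length]
        cnts = np.array([len(r) for r in rows], dtype=np.int64)
        offs = np.concatenate([[0], np.cumsum(cnts)[:-1]]) if len(cnts) \
            else np.zeros(0, np.int64)
        total = int(cnts.sum())
        tors = np.zeros((total, length, 3))
        k = 0
        for r in rows:
            for frag in r:
                tors[k] = frag
                k += 1
        lib.add_length(length, tors, offs.astype(np.int64), cnts)
    return lib
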