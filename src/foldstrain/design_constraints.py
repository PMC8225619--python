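"""Sequence-design constraint export.

Sequence design itself is out of scope; this module exports the
per-position rules that reduce strand-swap ambiguity and aggregation
risk as a resfile-like text file for downstream design tools:

* the first and last residue of every strand are restricted to polar
  amino acids (reduces consecutive hydrophobics at strand ends);
* buried positions of internal strands receive hydrophobic sets drawn
  from AVILMF, assigned so that no two internal strands carry the same
  position-pattern signature when avoidable (greedy in strand order);
* positions permitting aromatics carry a chi2 note restricting the
  rotamer to the 70-110 degree range common in native structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .blueprint import Blueprint

POLAR = "DEKRNQSTH"
HYDROPHOBIC = "AVILMF"
AROMATIC = set("FYHW")
CHI2_NOTE = "chi2:70-110"
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PositionConstraint:
    index: int                 # 1-based residue index
    allowed: str               # one-letter codes, sorted
    tag: str                   # polar-terminus | hydrophobic-pattern |
                               # unconstrained
    chi2_note: str = ""

    def __post_init__(self):
        self.allowed = "".join(sorted(set(self.allowed)))
        if not self.allowed:
            raise ValueError(f"position {self.index}: empty allowed set")
        if self.chi2_note and not (set(self.allowed) & AROMATIC):
            raise ValueError(f"position {self.index}: chi2 note on a "
                             f"position that permits no aromatics")


def make_constraints(bp: Blueprint, hard: bool = True) -> list:
    """Ordered per-residue constraints for a blueprint.

    ``hard=False`` marks the polar/hydrophobic restrictions as
    preferences (the full alphabet stays allowed; the tag records the
    favoured set) instead of hard restrictions.
    """
    n = bp.n_residues
    allowed = [ALL_AA] * n
    tags = ["unconstrained"] * n
    strands = bp.strand_elements()
    # sheet-edge strands keep their faces solvent-accessible; only
    # internal strands get buried-pattern assignments
    order = bp.sheet_order() if len(strands) > 1 else strands
    internal = set(order[1:-1]) if len(order) > 2 else set()
    for rank, ei in enumerate(e for e in strands if e in internal):
        a, b = bp.element_span(ei)
        e = bp.elements[ei]
        for local in range(e.length):
            r = a + local
            if local in (0, e.length - 1):
                continue
            # buried face: pleats pointing into the page face the core
            if e.pleats[local] == "-":
                letter = HYDROPHOBIC[(rank + local) % len(HYDROPHOBIC)]
                allowed[r] = letter if hard else ALL_AA
                tags[r] = f"hydrophobic-pattern:{letter}"
    for ei in strands:
        a, b = bp.element_span(ei)
        for r in (a, b):
            allowed[r] = POLAR if hard else ALL_AA
            tags[r] = "polar-terminus"
    out = []
    for r in range(n):
        note = CHI2_NOTE if set(allowed[r]) & AROMATIC else ""
        out.append(PositionConstraint(r + 1, allowed[r], tags[r], note))
    return out


def pattern_signatures(constraints, bp: Blueprint) -> dict:
    """Per-internal-strand tuple of hydrophobic-pattern letters, used to
    verify pairwise distinctness."""
    sig = {}
    for ei in bp.strand_elements():
        a, b = bp.element_span(ei)
        pat = tuple(c.tag.split(":", 1)[1]
                    for c in constraints[a:b + 1]
                    if c.tag.startswith("hydrophobic-pattern"))
        if pat:
            sig[ei] = pat
    return sig


def write_constraints(constraints, path) -> None:
    """Resfile-like export: ``index ALLOWED <set> # tag [chi2]``."""
    with open(path, "w") as fh:
        for c in constraints:
            note = f" {c.chi2_note}" if c.chi2_note else ""
            fh.write(f"{c.index} ALLOWED {c.allowed} # {c.tag}{note}\n")
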