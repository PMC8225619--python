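"""Blueprints: residue-level specifications of a target alpha/beta fold.

A blueprint lists the secondary-structure elements of a chain in N->C
order (helix/strand/loop with lengths, strand pleat patterns and per-loop
extended-ABEGO patterns), the strand pairings of the beta-sheet with
signed register shifts, and the part decomposition used for part-by-part
backbone building.

Text dialect (UTF-8, LF, ``#`` comments)::

    name <identifier>
    H <length>                    # helix
    E <length> <pleats>           # strand; pleats e.g. "+-+-+-"
    L <abego>                     # loop; e.g. "GB"
    P <elem_a> <elem_b> <shift> <par|anti>   # strand pairing (1-based)
    PART <first_elem> <last_elem>            # optional explicit parts

Register-shift convention (0-based local strand indices): for a parallel
pairing residue ``i`` of strand_a pairs with ``j = i + shift`` of
strand_b; for an antiparallel pairing ``i + j = shift``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .abego import EXTENDED_LABELS

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"


class BlueprintError(ValueError):
    """Raised for dialect syntax errors and invariant violations."""


@dataclass
class SSElement:
    kind: str              # 'H' | 'E' | 'L'
    length: int
    abego: str = ""        # per-residue labels; defaults by kind
    pleats: str = ""       # strands only; '+' out of page, '-' into page

    def __post_init__(self):
        if self.kind not in ("H", "E", "L"):
            raise BlueprintError(f"unknown element kind {self.kind!r}")
        if self.length < 1:
            raise BlueprintError("element length must be >= 1")
        if not self.abego:
            self.abego = {"H": "A", "E": "B"}.get(self.kind, "") * self.length
        if self.kind == "E" and not self.pleats:
            self.pleats = "".join("+-"[i % 2] for i in range(self.length))


@dataclass
class StrandPairing:
    strand_a: int          # element index (0-based)
    strand_b: int
    register_shift: int
    orientation: str = PARALLEL

    def __post_init__(self):
        if self.orientation not in (PARALLEL, ANTIPARALLEL):
            raise BlueprintError(
                f"StrandPairing orientation {self.orientation!r} invalid")


@dataclass
class SheetBond:
    """One designated intra-sheet backbone hydrogen bond."""
    label: int             # 1-based ladder numbering, sheet order
    donor: int             # global residue index, 0-based
    acceptor: int
    pairing: int           # index into Blueprint.pairings
    excluded: bool = False


@dataclass
class SheetHBondTopology:
    bonds: list

    def __len__(self):
        return len(self.bonds)

    def included(self):
        return [b for b in self.bonds if not b.excluded]


class Blueprint:
    """A validated fold blueprint."""

    def __init__(self, name, elements, pairings=(), parts=None,
                 terminal_helices=None, provenance: str = ""):
        self.name = name
        self.elements = list(elements)
        self.pairings = list(pairings)
        self.provenance = provenance
        if parts is None:
            parts = default_parts(self.elements)
        self.parts = [tuple(p) for p in parts]
        if terminal_helices is None:
            hel = [i for i, e in enumerate(self.elements) if e.kind == "H"]
            terminal_helices = (hel[0], hel[-1]) if hel else None
        self.terminal_helices = terminal_helices

    # --- residue bookkeeping -------------------------------------------
    @property
    def n_residues(self) -> int:
        return sum(e.length for e in self.elements)

    def element_offset(self, idx: int) -> int:
        """Global 0-based index of the first residue of element ``idx``."""
        return sum(e.length for e in self.elements[:idx])

    def element_span(self, idx: int):
        off = self.element_offset(idx)
        return off, off + self.elements[idx].length - 1

    def part_span(self, part_idx: int):
        first, last = self.parts[part_idx]
        return self.element_offset(first), self.element_span(last)[1]

    def strand_elements(self):
        return [i for i, e in enumerate(self.elements) if e.kind == "E"]

    def helix_elements(self):
        return [i for i, e in enumerate(self.elements) if e.kind == "H"]

    def residue_labels(self) -> str:
        """Per-residue blueprint ABEGO labels, concatenated N->C."""
        return "".join(e.abego for e in self.elements)

    def residue_ss(self) -> str:
        """Per-residue designated secondary structure (H/E/L)."""
        return "".join(e.kind * e.length for e in self.elements)

    def sheet_order(self) -> list:
        """Strand element indices in spatial sheet order.

        Derived from the pairing graph, which must form a single path.
        """
        strands = self.strand_elements()
        if len(strands) <= 1:
            return strands
        adj = {s: [] for s in strands}
        for p in self.pairings:
            adj[p.strand_a].append(p.strand_b)
            adj[p.strand_b].append(p.strand_a)
        ends = [s for s in strands if len(adj[s]) == 1]
        if len(ends) != 2 or any(len(v) > 2 for v in adj.values()):
            raise BlueprintError(
                f"{self.name}: pairings do not form a single linear sheet")
        order = [min(ends)]
        prev = None
        while True:
            nxts = [s for s in adj[order[-1]] if s != prev]
            if not nxts:
                break
            prev = order[-1]
            order.append(nxts[0])
        if len(order) != len(strands):
            raise BlueprintError(f"{self.name}: sheet is not connected")
        return order

    def terminal_helix_spans(self):
        """Global residue spans of the N- and C-terminal helices."""
        if self.terminal_helices is None:
            raise BlueprintError(f"{self.name}: no helices")
        a, b = self.terminal_helices
        return self.element_span(a), self.element_span(b)

    def __eq__(self, other):
        return (isinstance(other, Blueprint)
                and self.name == other.name
                and self.elements == other.elements
                and self.pairings == other.pairings
                and list(self.parts) == list(other.parts)
                and self.terminal_helices == other.terminal_helices)

    def __repr__(self):
        return (f"Blueprint({self.name!r}, {len(self.elements)} elements, "
                f"{self.n_residues} residues)")


def default_parts(elements) -> list:
    """Default part decomposition: a beta-alpha-beta seed, then one
    alpha-beta unit per further strand, then the trailing loop-helix."""
    strands = [i for i, e in enumerate(elements) if e.kind == "E"]
    if len(strands) < 2:
        return [(0, len(elements) - 1)]
    parts = [(0, strands[1])]
    for s in strands[2:]:
        parts.append((parts[-1][1] + 1, s))
    if parts[-1][1] < len(elements) - 1:
        parts.append((parts[-1][1] + 1, len(elements) - 1))
    return parts


# --- validation --------------------------------------------------------

def validate_blueprint(bp: Blueprint) -> list:
    """Return a list of invariant-violation messages (empty iff valid)."""
    report = []
    n_elem = len(bp.elements)
    for i, e in enumerate(bp.elements):
        if len(e.abego) != e.length:
            report.append(f"element {i + 1}: abego length {len(e.abego)} "
                          f"!= element length {e.length}")
        bad = [c for c in e.abego if c not in EXTENDED_LABELS]
        if bad:
            report.append(f"element {i + 1}: unknown ABEGO labels {bad}")
        if e.kind == "E":
            if len(e.pleats) != e.length:
                report.append(f"element {i + 1}: pleat pattern length "
                              f"mismatch")
            elif any(e.pleats[k] == e.pleats[k + 1]
                     for k in range(e.length - 1)):
                report.append(f"element {i + 1}: pleat pattern does not "
                              f"alternate")
    seen = {}
    for k, p in enumerate(bp.pairings):
        for s in (p.strand_a, p.strand_b):
            if not (0 <= s < n_elem):
                report.append(f"pairing {k + 1}: element index {s + 1} "
                              f"out of range")
            elif bp.elements[s].kind != "E":
                report.append(f"pairing {k + 1}: StrandPairing references "
                              f"non-strand element {s + 1}")
        if p.strand_a == p.strand_b:
            report.append(f"pairing {k + 1}: StrandPairing pairs strand "
                          f"{p.strand_a + 1} with itself")
        key = frozenset((p.strand_a, p.strand_b))
        if key in seen:
            q = seen[key]
            if (q.register_shift, q.orientation) != (p.register_shift,
                                                     p.orientation):
                report.append(f"pairing {k + 1}: contradicts an earlier "
                              f"pairing of the same strands")
        seen[key] = p
        if all(0 <= s < n_elem and bp.elements[s].kind == "E"
               for s in (p.strand_a, p.strand_b)):
            if not aligned_pairs(bp, p):
                report.append(f"pairing {k + 1}: register shift "
                              f"{p.register_shift} leaves no paired "
                              f"residues in range")
    covered = []
    for first, last in bp.parts:
        if not (0 <= first <= last < n_elem):
            report.append("parts reference elements out of range")
        covered.extend(range(first, last + 1))
    if covered != list(range(n_elem)):
        report.append("parts do not cover elements exactly once in N->C "
                      "order")
    if len(bp.strand_elements()) >= 2 and not report:
        try:
            bp.sheet_order()
        except BlueprintError as exc:
            report.append(str(exc))
    return report


def aligned_pairs(bp: Blueprint, p: StrandPairing) -> list:
    """All (local_i_on_a, local_j_on_b) residue alignments of a pairing."""
    la = bp.elements[p.strand_a].length
    lb = bp.elements[p.strand_b].length
    out = []
    for i in range(la):
        j = i + p.register_shift if p.orientation == PARALLEL \
            else p.register_shift - i
        if 0 <= j < lb:
            out.append((i, j))
    return out


# --- sheet hydrogen-bond topology --------------------------------------

def sheet_hbond_topology(bp: Blueprint) -> SheetHBondTopology:
    """Enumerate the designated intra-sheet backbone hydrogen bonds.

    In a beta-sheet each residue's NH and C=O point to one side of the
    strand, alternating along it, so only every other aligned residue
    pair ladders an interface.  The participating parity is propagated
    along the sheet: each interior strand faces its two neighbours with
    opposite parities.  Parallel interfaces contribute, per participating
    alignment (i, j), the bonds NH(a_i) -> CO(b_{j-1}) and NH(b_{j+1}) ->
    CO(a_i); antiparallel interfaces contribute the mutual pair
    NH(a_i) -> CO(b_j) and NH(b_j) -> CO(a_i).
    """
    errors = validate_blueprint(bp)
    if errors:
        raise BlueprintError("; ".join(errors))
    order = bp.sheet_order()
    if len(order) < 2:
        return SheetHBondTopology([])
    pairing_of = {}
    for k, p in enumerate(bp.pairings):
        pairing_of[(p.strand_a, p.strand_b)] = (k, False)
        pairing_of[(p.strand_b, p.strand_a)] = (k, True)
    bonds = []
    parity = 0  # participating local-index parity on the current strand
    for u, v in zip(order, order[1:]):
        k, flipped = pairing_of[(u, v)]
        p = bp.pairings[k]
        off_u, off_v = bp.element_offset(u), bp.element_offset(v)
        lv = bp.elements[v].length
        next_parity = 0
        for i, j in _oriented_alignments(bp, p, flipped):
            if i % 2 != parity:
                continue
            gi = off_u + i
            if p.orientation == PARALLEL:
                if j - 1 >= 0 and gi > 0:
                    bonds.append((gi, off_v + j - 1, k))
                if j + 1 < lv and off_v + j + 1 > 0:
                    bonds.append((off_v + j + 1, gi, k))
                next_parity = (j + 1) % 2
            else:
                if gi > 0:
                    bonds.append((gi, off_v + j, k))
                if off_v + j > 0:
                    bonds.append((off_v + j, gi, k))
                next_parity = j % 2
        # the next strand faces its other neighbour with opposite parity
        parity = 1 - next_parity
    # order by donor position, then drop double donations (keep first)
    seen_donors = set()
    out = []
    for donor, acceptor, k in bonds:
        if donor in seen_donors:
            continue
        seen_donors.add(donor)
        out.append(SheetBond(len(out) + 1, donor, acceptor, k))
    return SheetHBondTopology(out)


def _oriented_alignments(bp, p, flipped):
    """Alignments as (i_on_from_strand, j_on_to_strand)."""
    pairs = aligned_pairs(bp, p)
    if flipped:
        pairs = [(j, i) for i, j in pairs]
    return pairs


# --- dialect parsing and writing ---------------------------------------

def parse_blueprint(text: str) -> Blueprint:
    """Parse the blueprint dialect; returns a validated Blueprint."""
    name = None
    elements = []
    raw_pairings = []
    raw_parts = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if tok[0] == "name":
                name = tok[1]
            elif tok[0] == "H":
                elements.append(SSElement("H", int(tok[1])))
            elif tok[0] == "E":
                pleats = tok[2] if len(tok) > 2 else ""
                elements.append(SSElement("E", int(tok[1]), pleats=pleats))
            elif tok[0] == "L":
                elements.append(SSElement("L", len(tok[1]), abego=tok[1]))
            elif tok[0] == "P":
                raw_pairings.append((int(tok[1]) - 1, int(tok[2]) - 1,
                                     int(tok[3]), tok[4]))
            elif tok[0] == "PART":
                raw_parts.append((int(tok[1]) - 1, int(tok[2]) - 1))
            else:
                raise BlueprintError(
                    f"line {lineno}: unknown directive {tok[0]!r}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, BlueprintError):
                raise
            raise BlueprintError(f"line {lineno}: cannot parse {raw!r}") \
                from exc
    if name is None:
        raise BlueprintError("missing 'name' header line")
    pairings = []
    for a, b, shift, orient in raw_pairings:
        orient_full = {"par": PARALLEL, "anti": ANTIPARALLEL}.get(orient)
        if orient_full is None:
            raise BlueprintError(f"pairing orientation {orient!r} must be "
                                 f"'par' or 'anti'")
        pairings.append(StrandPairing(a, b, shift, orient_full))
    bp = Blueprint(name, elements, pairings,
                   parts=raw_parts or None)
    errors = validate_blueprint(bp)
    if errors:
        raise BlueprintError(f"{name}: " + "; ".join(errors))
    return bp


def write_blueprint(bp: Blueprint) -> str:
    """Serialise a Blueprint to the dialect; parse(write(bp)) == bp."""
    lines = [f"name {bp.name}"]
    for e in bp.elements:
        if e.kind == "H":
            lines.append(f"H {e.length}")
        elif e.kind == "E":
            lines.append(f"E {e.length} {e.pleats}")
        else:
            lines.append(f"L {e.abego}")
    for p in bp.pairings:
        orient = "par" if p.orientation == PARALLEL else "anti"
        lines.append(f"P {p.strand_a + 1} {p.strand_b + 1} "
                     f"{p.register_shift} {orient}")
    for first, last in bp.parts:
        lines.append(f"PART {first + 1} {last + 1}")
    return "\n".join(lines) + "\n"


# --- built-in blueprints ------------------------------------------------
# Approximate transcriptions of the published blueprint diagrams for the
# P-loop and Rossmann design series.  The diagrams are residue-level
# cartoons; element lengths and register shifts here are plausible
# reconstructions consistent with the accompanying text (design-model
# strands longer, NMR-derived strands shorter; the Rossmann sheet order
# 2-1-3-4-5 converts to the P-loop order 2-3-1-4-5 by swapping the two
# internal strands).  All sheets are parallel.


def _r2x3(name, s1, s2, s3, s4, s5, shift13, ploop_order=False,
          helix=12):
    """Five-stranded, five-helix alpha/beta blueprint.

    Chain order b1 a1 b2 a2 b3 a3 b4 a4 b5 a5; sheet order 2-1-3-4-5
    (Rossmann) or 2-3-1-4-5 (P-loop / strand-swapped).
    Element indices: b1=1 b2=5 b3=9 b4=13 b5=17 (1-based).
    """
    lines = [f"name {name}"]
    strands = [s1, s2, s3, s4, s5]
    for i, sl in enumerate(strands):
        lines.append(f"E {sl}")
        lines.append("L BBB")
        lines.append(f"H {helix}")
        if i < 4:
            lines.append("L BBB")
    if ploop_order:
        # sheet 2-3-1-4-5: interfaces b2-b3, b3-b1, b1-b4, b4-b5
        lines += [f"P 5 9 0 par", f"P 9 1 {shift13} par",
                  f"P 1 13 0 par", f"P 13 17 0 par"]
    else:
        # sheet 2-1-3-4-5: interfaces b2-b1, b1-b3, b3-b4, b4-b5
        lines += [f"P 5 1 0 par", f"P 1 9 {shift13} par",
                  f"P 9 13 0 par", f"P 13 17 0 par"]
    return "\n".join(lines) + "\n"


def _r3x3(name, strands, shift14, helix=12):
    """Six-stranded, six-helix Rossmann blueprint; sheet order 3-2-1-4-5-6.
    Element indices: b1=1 b2=5 b3=9 b4=13 b5=17 b6=21."""
    lines = [f"name {name}"]
    for i, sl in enumerate(strands):
        lines.append(f"E {sl}")
        lines.append("L BBB")
        lines.append(f"H {helix}")
        if i < 5:
            lines.append("L BBB")
    lines += ["P 9 5 0 par", "P 5 1 0 par", f"P 1 13 {shift14} par",
              "P 13 17 0 par", "P 17 21 0 par"]
    return "\n".join(lines) + "\n"


_BUILTIN_TEXT = {
    # design-model blueprints (five-stranded series)
    "Pl2x3_BP": _r2x3("Pl2x3_BP", 5, 6, 6, 6, 5, 0, ploop_order=True),
    "R2x3_BP1": _r2x3("R2x3_BP1", 6, 6, 6, 6, 5, 0),
    # register-shift variants of the b1-b3 interface.  The published
    # variants are defined by their effect (BP3 curves the sheet more,
    # BP2 less); in this package's shift convention the curvature-
    # increasing direction is negative, so BP3 carries -2 and BP2 +2.
    "R2x3_BP2": _r2x3("R2x3_BP2", 6, 6, 6, 6, 5, 2),
    "R2x3_BP3": _r2x3("R2x3_BP3", 6, 6, 6, 6, 5, -2),
    # BP3 with shortened strands to relieve sheet frustration
    "R2x3_BP4": _r2x3("R2x3_BP4", 5, 5, 5, 5, 4, -2),
    # strand-swapped (P-loop order) blueprints read off the NMR structures
    "R2x3_BP1_A5_NMR": _r2x3("R2x3_BP1_A5_NMR", 5, 5, 5, 5, 4, 0,
                             ploop_order=True),
    "R2x3_BP1_B9_NMR": _r2x3("R2x3_BP1_B9_NMR", 4, 5, 5, 5, 4, 0,
                             ploop_order=True),
    # six-stranded Rossmann series
    "R3x3_BP1": _r3x3("R3x3_BP1", [6, 6, 6, 6, 6, 5], 0),
    "R3x3_BP2": _r3x3("R3x3_BP2", [6, 6, 6, 5, 6, 5], 1),
    "R3x3_BP3": _r3x3("R3x3_BP3", [5, 5, 5, 4, 5, 4], 1),
}

_PROVENANCE = ("approximate transcription of the published blueprint "
               "diagram for this design series (element lengths and "
               "registers reconstructed from the figure panels)")


def builtin_blueprint_names() -> list:
    return sorted(_BUILTIN_TEXT)


def builtin_blueprints() -> dict:
    """All built-in blueprints, keyed by canonical name."""
    return {name: get_blueprint(name) for name in _BUILTIN_TEXT}


def get_blueprint(name: str) -> Blueprint:
    """Look up a built-in blueprint ('x' and the multiplication sign are
    interchangeable in names)."""
    key = name.replace("×", "x")
    if key not in _BUILTIN_TEXT:
        raise KeyError(f"unknown built-in blueprint {name!r}; available: "
                       f"{', '.join(builtin_blueprint_names())}")
    bp = parse_blueprint(_BUILTIN_TEXT[key])
    bp.provenance = _PROVENANCE
    return bp
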