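"""Extended ABEGO classification of backbone torsion angles.

The classic ABEGO alphabet coarsely bins the (phi, psi, omega) torus into
five regions: A (alpha), B (beta), G (positive-phi alpha), E (positive-phi
extended) and O (cis omega).  For loop design the broad B region is further
subdivided into four quadrants labelled C, D, Y and Z, so that a loop
pattern can pin each residue to a more canonical part of the beta basin.

Boundaries used here (all angles in degrees, the interval convention is
half-open (lo, hi]):

* O:   |omega| < 90 (cis peptide), regardless of phi/psi
* A:   phi < 0 and psi in (-75, 50]
* B:   phi < 0 and psi outside (-75, 50]
* G:   phi >= 0 and psi in (-100, 100]
* E:   phi >= 0 and psi outside (-100, 100]

The B quadrants split at phi = -100 and at psi = 145 (psi wraps through
+-180 back to -75):

* C:   phi in [-100, 0) and psi in (50, 145]
* D:   phi < -100     and psi in (50, 145]
* Y:   phi in [-100, 0) and psi in (145, 180] or (-180, -75]
* Z:   phi < -100     and psi in (145, 180] or (-180, -75]

The subdivision boundaries are provisional design choices (the exact
published quadrants are not restated here); they are module constants and
can be overridden for sensitivity studies.
"""

from __future__ import annotations

import numpy as np

#: All nine extended labels.
EXTENDED_LABELS = ("A", "B", "G", "E", "O", "C", "D", "Y", "Z")
#: Classic five-letter labels.
CLASSIC_LABELS = ("A", "B", "G", "E", "O")
#: Subregions of the classic B bin.
B_SUBREGIONS = ("C", "D", "Y", "Z")

# Overridable subdivision boundaries of the B region (degrees).
B_SPLIT_PHI = -100.0
B_SPLIT_PSI = 145.0

# Boundary between A and B along psi, and between G and E.
A_PSI_LO, A_PSI_HI = -75.0, 50.0
G_PSI_LO, G_PSI_HI = -100.0, 100.0

# Integer codes used by the numba kernels; order matches EXTENDED_LABELS.
LABEL_CODES = {lab: i for i, lab in enumerate(EXTENDED_LABELS)}
CODE_LABELS = {i: lab for lab, i in LABEL_CODES.items()}


def classify_abego(phi: float, psi: float, omega: float = 180.0,
                   extended: bool = True) -> str:
    """Classify one torsion triple into an (extended) ABEGO bin.

    Parameters
    ----------
    phi, psi, omega : float
        Backbone torsions in degrees, in (-180, 180].
    extended : bool
        If True, residues in the B region report their C/D/Y/Z quadrant;
        if False they report plain ``B``.

    Returns
    -------
    str
        Exactly one label; the bins partition the full torus.
    """
    if abs(omega) < 90.0:
        return "O"
    if phi < 0.0:
        if A_PSI_LO < psi <= A_PSI_HI:
            return "A"
        if not extended:
            return "B"
        wide = phi < B_SPLIT_PHI  # more extended phi half
        # psi side: (50, 145] vs the wrap-around arc (145, 180] u (-180, -75]
        mid = A_PSI_HI < psi <= B_SPLIT_PSI
        if mid:
            return "D" if wide else "C"
        return "Z" if wide else "Y"
    if G_PSI_LO < psi <= G_PSI_HI:
        return "G"
    return "E"


def classify_abego_array(phi, psi, omega, extended: bool = True) -> np.ndarray:
    """Vectorised :func:`classify_abego`; returns an array of label strings."""
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    omega = np.asarray(omega, dtype=float)
    out = np.empty(phi.shape, dtype="U1")
    it = np.nditer(phi, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        out[idx] = classify_abego(phi[idx], psi[idx], omega[idx], extended)
    return out


def label_matches(observed: str, required: str) -> bool:
    """True if an observed extended label satisfies a blueprint label.

    A required plain ``B`` accepts any of its C/D/Y/Z subregions; a
    required subregion accepts only itself.
    """
    if observed == required:
        return True
    if required == "B" and observed in B_SUBREGIONS:
        return True
    return False


# Circular (phi, psi) intervals per bin as (center, halfwidth) pairs in
# degrees, used for bin restraints during relaxation: a torsion is inside
# the bin when |wrap(angle - center)| <= halfwidth.
BIN_INTERVALS = {
    "A": ((-90.0, 90.0), (-12.5, 62.5)),
    "B": ((-90.0, 90.0), (167.5, 117.5)),
    "C": ((-50.0, 50.0), (97.5, 47.5)),
    "D": ((-140.0, 40.0), (97.5, 47.5)),
    "Y": ((-50.0, 50.0), (-145.0, 70.0)),
    "Z": ((-140.0, 40.0), (-145.0, 70.0)),
    "G": ((90.0, 90.0), (0.0, 100.0)),
    "E": ((90.0, 90.0), (180.0, 80.0)),
    "O": ((0.0, 180.0), (0.0, 180.0)),
}


def bin_interval_arrays(labels: str):
    """Per-residue (phi_center, phi_halfwidth, psi_center, psi_halfwidth)
    arrays for a label string."""
    out = np.empty((len(labels), 4))
    for i, lab in enumerate(labels):
        (pc, ph), (sc, sh) = BIN_INTERVALS[lab]
        out[i] = (pc, ph, sc, sh)
    return out


# Representative torsions and sampling widths per bin, used by the
# synthetic fragment generator: label -> (phi_mean, psi_mean, phi_sd, psi_sd).
BIN_TORSION_PARAMS = {
    "A": (-63.0, -42.0, 5.0, 5.0),
    "B": (-120.0, 132.0, 16.0, 16.0),
    "C": (-75.0, 120.0, 14.0, 14.0),
    "D": (-130.0, 120.0, 16.0, 14.0),
    "Y": (-75.0, 162.0, 14.0, 10.0),
    "Z": (-135.0, 160.0, 18.0, 12.0),
    "G": (75.0, 20.0, 12.0, 25.0),
    "E": (75.0, 160.0, 12.0, 14.0),
    "O": (-75.0, 160.0, 15.0, 15.0),  # omega handled separately (cis)
}
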