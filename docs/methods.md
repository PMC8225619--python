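# Methods

## The problem

In de novo design of alpha/beta proteins, a *blueprint* fixes the target
fold at residue level: the lengths of strands, helices and loops, the
pleat directions of strand residues, the pairings of the beta-sheet with
their register shifts, and a coarse torsion-bin (extended ABEGO) label
per loop residue.  A blueprint that is locally ideal can still be
globally *strained*: the supersecondary elements it prescribes may be
incompatible with any relaxed tertiary structure.  The experimental
signature of such strain is strand swapping — a designed Rossmann strand
order folding into the P-loop order.  This package quantifies that
strain *before* any sequence exists, by generating sequence-independent
backbone ensembles from the blueprint and measuring

* **sheet formability** `F = Σᵢ ln Pᵢ`, where `Pᵢ` is the fraction of
  ensemble members in which the i-th designated intra-sheet hydrogen
  bond is formed (Kabsch–Sander energy below −0.5 kcal/mol; `Pᵢ`
  floored at 1/(2N));
* **terminal-helix packability** `ln P(d < 11 Å)`, where `d` is the
  minimum distance between the clipped axis segments of the N- and
  C-terminal helices (count floored at ½);
* the **sheet bend angle**, the angle between least-squares plane
  normals of the two halves of the sheet, split at the central strand.

Both log-metrics are ≤ 0, with 0 meaning frustration-free.

## Ensemble generation

Each accepted backbone passes through a three-step protocol on a
coarse-grained chain (N, amide H, CA, C, carbonyl O and one side-chain
pseudo-sphere of Val radius 2.0 Å per residue; ideal bond lengths and
angles; torsions are the only degrees of freedom).

**Initialisation (geometric sheet scaffold).**  Database-derived
fragment sets carry strong supersecondary correlations; the synthetic
per-bin fragments shipped here (truncated Gaussians per extended-ABEGO
bin, with the beta-basin sampled along the φ+ψ anti-diagonal) do not,
and fragment assembly alone essentially never discovers a correctly
phased five-strand parallel ladder.  Every attempt therefore starts from
an explicit geometric realisation of the blueprint: strand segments are
sampled from the fragment library and placed strand-by-strand in the
ideal ladder frame of their designated pairing (parallel: 5.2 Å along
the amide direction, −0.3 Å axial offset; antiparallel: 5.45 Å, +0.4 Å —
both calibrated once on ideal strands so that all designated hydrogen
bonds form at physical energies), with rigid-body noise (rotation sd 5°,
translation sd 0.25 Å).  Helices are placed rigidly ~9.5 Å off the sheet
plane on the face given by the right-handed crossover rule (crossovers
toward higher sheet positions on one face, lower on the other; the
terminal helix joins the face of the first helix — which is exactly the
terminal-helix packing face), in evenly spaced lateral slots.  Loops are
closed onto the placed elements by CCD and polished by least squares to
a seam-free torsion representation.

**Step 1 — part-by-part Monte Carlo.**  The chain is built in parts (a
beta-alpha-beta seed, then one alpha-beta unit per strand, then the
trailing helix).  Each part runs Metropolis Monte Carlo at the simulated
temperature 2.0 for `steps_per_residue × current length` steps (default
300 per residue), replacing random 1/3/9-residue frames with
blueprint-compatible fragments.  A part is accepted when every built
pairing retains at least one aligned CA pair in the 3.8–6 Å register
window; helix quality is enforced later, at the motif-rebuild stage.
The score mirrors the low-resolution design potential by term name
(vdw, rg, ss_pair, rsigma, hs_pair, hbond_sr_bb, hbond_lr_bb, omega)
with explicit stand-in forms documented in `scoring.py`; weights follow
the published presets (all 1.0 in Step 1; hydrogen bonding and omega
upweighted to 5/3/3 in Step 2).  Because the stand-in terms carry their
own energy scale, a global calibration constant (3.0) relates them to
the simulated temperature so that the designated basin is metastable at
T = 2.0.

**Step 2 — constrained relaxation.**  An annealed fragment-move
Metropolis pass (T 1.5 → 0.15) over the Step-2-weighted score plus
flat-bottom penalties: designated CA pairs restrained into 4.0–5.5 Å
(the lower wall prevents register collapse through the soft steric
core), designated N···O distances below 3.0 Å, and the chain termini
below 13 Å when the blueprint ends in a helix.  Torsion-space gradient
minimisation (L-BFGS over φ/ψ with in-kernel finite differences) was
implemented and evaluated, but on this landscape it systematically
trades formed ladder geometry against the upweighted short-range
hydrogen-bond term, so the fragment-move anneal — whose proposals keep
every residue inside its torsion bin — is the production minimiser.
A structure passes Step 2 only if the designated sheet is formed: every
non-edge strand residue assigned strand by the built-in DSSP-style
assignment (a −0.3 kcal/mol cutoff is used for this filter; the
published formation criterion is far more lenient than the −0.5 used
for reporting bonds).

**Step 3 — loop–helix rebuild.**  Each loop-helix(-loop) motif between
strands is re-placed geometrically (fresh helix placement on its face,
loops re-closed by CCD) and must pass: helical-bin torsions in the helix
core, no helix kink (any non-helical interior residue with three
tolerated at each terminus, or half-span axes diverging more than 25°),
helix buriedness against the strands plus the motif's own residues
(Shrake–Rupley accessible area with probe 2.0 Å; at least one residue
under 40 Å² in every 5-residue window), and, for the final motif, chain
termini closer than 15 Å.

## Desk-scale profile

`MCConfig.desk_scale()` is the problem size used by the test suite and
the acceptance script: 30 MC steps per residue, 80 annealing steps per
residue in Step 2, restart caps of 15, and "rough" motif mode, in which
the kink/buriedness gates are recorded as diagnostics rather than
enforced per motif and one missing non-edge bridge is tolerated by the
sheet-formed filter.  The ensembles behind the headline numbers are tens
of members rather than the thousands a production run would use; medians
of the terminal-helix distance are stable at these sizes, but the
packability and bend-angle *orderings* across register-shift variants
are noisy, and the corresponding comparison tests may fail purely for
sampling-size reasons.

## What the synthetic generator does and does not emulate

The synthetic fragments reproduce the marginal torsion distributions of
each bin but none of the higher-order correlations of real fragment
sets.  Consequences: the geometric scaffold (not fragment assembly)
supplies the fold topology; loop torsions are decided by closure
geometry rather than by loop-bin statistics, so the built-in blueprints'
loop patterns (three-residue, beta-basin) are reconstructions chosen to
be self-consistent with the model, and loop-bin compliance is not a
rejection criterion; and the absolute values of the strain metrics are
not comparable to runs with database fragments — only comparisons
between blueprints under identical settings are meaningful.

The steric model is a soft-sphere stand-in over the CA and pseudo-atom
spheres (quadratic overlap, weight 1).  Accepted members usually contain
one residual contact below 2.5 Å CA–CA somewhere in the chain; stiffer
walls (tested up to 25×) freeze the Monte Carlo before they remove the
contacts.  The per-member minimum nonlocal CA clearance is recorded in
the provenance so downstream analyses can filter on it.  Kabsch–Sander
energies are clamped to zero below 2.2 Å N···O, because the raw
electrostatic form otherwise rewards steric overlap as an apparently
perfect hydrogen bond.

## Built-in blueprints

The built-ins (`Pl2x3_BP`, `R2x3_BP1`–`BP4`, `R2x3_BP1_A5_NMR`,
`R2x3_BP1_B9_NMR`, `R3x3_BP1`–`BP3`) are approximate transcriptions:
element lengths, loop patterns and register shifts are plausible
reconstructions consistent with the described design series (design
strands ~6 residues, experimentally observed strands shorter; the
Rossmann sheet order 2-1-3-4-5 converts to the P-loop order 2-3-1-4-5 by
swapping the two internal strands; `R2x3_BP2`/`BP3` put a −2/+2 register
shift on the beta1–beta3 pairing; `BP4` shortens the strands of `BP3`).
The shift-sign convention is this package's own (parallel: `j = i + s`
on 0-based local indices; antiparallel: `i + j = s`).

## Numerical choices

* Ideal geometry: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å,
  N–H 1.01 Å; angles 111.2°/116.2°/121.7°; pseudo-atom 1.5 Å from CA.
* Extended ABEGO: cis ω (|ω| < 90°) → O; φ < 0 with ψ ∈ (−75, 50] → A,
  else the beta basin, subdivided at φ = −100° and ψ = 145° (wrapping
  to −75°) into C/D/Y/Z; φ ≥ 0 with ψ ∈ (−100, 100] → G, else E.  The
  subdivision boundaries are provisional and overridable.
* Helix axes by chord bisectors plus an algebraic circle fit (exact on
  noiseless helices); inter-helix distance as the minimum distance of
  the clipped axis segments.
* Probability floors: 1/(2N) for bond probabilities, ½ count for
  packability, so the logs stay finite at desk-scale N.
* Seeds: a single integer seed drives fragment generation, all Monte
  Carlo streams and the averaging reference via a `numpy` generator;
  identical seeds give bit-identical ensembles.

## Known limitations

The sampler is a documented stand-in, not a re-implementation of the
original fragment-assembly/relax machinery: absolute energies,
acceptance rates and ensemble breadths differ.  Acceptance per attempt
for the five-strand blueprints is roughly 30% at desk scale and about
45 s per attempt on one CPU, which bounds the ensemble sizes reachable
inside test budgets.  Residual steric overlap (above) and the
reconstructed blueprints mean the quantitative metrics should be read
as model-internal comparisons, with the terminal-helix distance median
the most robust of them.
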