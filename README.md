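# foldstrain

Blueprint-based backbone ensembles and global strain metrics for de novo
alpha/beta protein folds.

## The problem

A de novo alpha/beta design starts from a *blueprint*: an ordered list
of secondary-structure elements with lengths, strand pleats, loop
torsion-bin (extended ABEGO) patterns, and strand pairings with register
shifts.  Even a locally ideal blueprint can hide *global* backbone
strain — an incompatibility between the prescribed supersecondary
elements and any relaxed tertiary structure.  Experimentally this shows
up as strand swapping: a designed Rossmann strand order folding into the
P-loop order.  `foldstrain` diagnoses such strain before any sequence is
designed, by generating sequence-independent backbone ensembles from the
blueprint and measuring how reliably the designated sheet forms and how
well the terminal helices pack:

* **formability**  F = Σᵢ ln Pᵢ, with Pᵢ the ensemble formation
  probability of the i-th designated intra-sheet hydrogen bond;
* **packability**  ln P(d < 11 Å), with d the distance between the
  N- and C-terminal helix axes;
* the **sheet bend angle** between the two halves of the beta-sheet.

All three are computed over ensembles produced by a three-step protocol
(geometric sheet initialisation, part-by-part fragment-assembly Monte
Carlo at temperature 2.0, constrained relaxation toward full sheet
pairing, loop–helix rebuild with CCD closure), on a coarse-grained chain
(five main-chain centres plus one side-chain pseudo-sphere per residue).
See `docs/methods.md` for the model, all stand-in choices and their
limitations.

## Worked example

```python
from foldstrain import (get_blueprint, MCConfig, generate_ensemble,
                        ensemble_metrics)

bp = get_blueprint("R2x3_BP1")           # five-strand Rossmann blueprint
ens = generate_ensemble(bp, 12, seed=1, cfg=MCConfig.desk_scale(),
                        time_budget=600)
m = ensemble_metrics(ens)
print(f"N={m.n}  formability={m.formability:.2f}  "
      f"packability={m.packability:.2f}  "
      f"median terminal-helix distance={m.median_distance:.1f} A")
```

prints (seed 1, desk scale; about ten minutes on one CPU):

```
N=9  formability=-16.16  packability=-0.59  median terminal-helix distance=7.3 A
```

A formability of 0 would mean every designated hydrogen bond forms in
every member; the negative value quantifies sheet frustration, and the
per-bond probabilities (`m.bond_probabilities`) resolve it bond by bond
along the ladder.  Packability is the log ensemble probability that the
terminal helices come within the ~11 Å side-chain packing range.  At
these small desk-scale ensemble sizes the distance median fluctuates by
several Ångström between runs, and the model's soft steric core
compresses inter-helix distances relative to a full-atom treatment (see
`docs/methods.md`), so the metrics are best read as comparisons between
blueprints under identical settings.  Register-shift variants
(`R2x3_BP2`/`BP3`) and the shortened-strand `R2x3_BP4` probe how
shifting the beta1–beta3 register curves the sheet and how shorter
strands relieve bond frustration.

The same workflow is scriptable:

```
foldstrain build    -b R2x3_BP1 --n 10 --seed 1 -o runs/bp1
foldstrain metrics  -e runs/bp1 -b R2x3_BP1 -o runs/bp1_metrics
foldstrain compare  -b R2x3_BP1 -b R2x3_BP4 --n 10 --seed 1
foldstrain constraints -b R2x3_BP1 -o bp1.res
```

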