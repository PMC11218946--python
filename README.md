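# rnatangle

Topological audit of predicted 3D RNA structures.

Structure-prediction algorithms — machine-learning ones in particular —
sometimes emit RNA conformations that are topologically impossible or at
least unseen in experimentally solved RNA: backbones tied into knots, loops
threaded by other parts of the chain (lassos), and pairs of closed elements
linked like chain links (interlaces). Standard accuracy measures (RMSD,
TM-score, INF, clash score) do not see these defects. `rnatangle` gives
modelers and assessors an automated screen: it reads a predicted model (PDB
or mmCIF), decides whether each chain's backbone is knotted and which knot it
forms, classifies every entanglement of structure elements into nine
subclasses, measures lasso depth, and aggregates cohorts of predictions into
stratified summary tables.

## The methods at the core

**Backbone knots.** The sugar-phosphate backbone (atoms P, O5′, C5′, C4′,
C3′, O3′) is an open curve, so knottedness is only defined relative to a
closure. The chain is first simplified with KMT reduction (a vertex is
deleted whenever its removal triangle is crossed by no other segment), then
closed 200 times: both endpoints are pushed radially onto a sphere of radius
10× the chain extent and joined through a random point of that sphere. Each
closure is classified by its Alexander polynomial Δ(t), computed from the
determinant of the Alexander matrix of a generic projection and normalized to
the symmetric representative — Δ(3₁) = t² − t + 1, Δ(4₁) = t² − 3t + 1, and
so on through the seven-crossing knots, where Δ identifies the knot type
uniquely. A chain is called *knotted* when fewer than 50% of its closures are
unknots; the single straight-segment (direct) closure is kept as a
cross-check, and chains whose diagrams stay above a crossing budget after
reduction fall into the *TTC* (too tangled to check) category.

**Entanglements of structure elements.** Canonical base pairs (Watson–Crick
A-U/G-C and wobble G-U) partition a chain into loops (L), dinucleotide steps
(D), and single strands (S). Each closed element (L or D) is spanned by a
triangulated surface; another element entangles it when its curve punctures
that surface. Non-zero Gauss linking number of two closed elements ⇒
interlace (L&L, D&L, D&D); punctures without linking ⇒ lasso X(Y). For
lassos around loops the threading depth is counted in nucleotides (minimum
distance from the crossing to a strand end, or the span between two
crossings); depth ≤ 5 nt is *shallow*, > 5 nt *deep*. Interlaces, D(\*)
lassos, and deep L(\*) lassos are flagged as modeling artifacts.

## Worked example

```python
from rnatangle.entangle import detect_all
from rnatangle.structure_io import annotate_base_pairs
from rnatangle.synthetic import make_hairpin_lasso

model, dotbracket, truth = make_hairpin_lasso(loop_size=6, depth=6)
ss = annotate_base_pairs(model, "dotbracket", dotbracket)
(ent,) = detect_all(model, ss)
print(ent.subclass, ent.depth, ent.depth_class, ent.artifact)
```

prints

```
L(S) 6 deep True
```

— a single loop–strand lasso whose threading leaves 6 nucleotides beyond the
crossing on the free-end side: one past the 5-nt shallow threshold, so it is
flagged as an artifact. The scripts in `examples/` walk through the other
capabilities (knot assessment with the closure histogram, Hopf-linked loops,
and a stratified cohort scan); each prints the numbers it computes and a line
on what they mean.

A shell interface mirrors the library:

```bash
rnatangle synth hairpin_lasso --depth 7 --out lasso.pdb
rnatangle entangle lasso.pdb
rnatangle knots model.pdb --closures 200 --seed 42
rnatangle scan --input models/ --out report/ --seed 1
```

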