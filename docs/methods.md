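# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `rnatangle`. Units are angstroms (Å) for coordinates and
nucleotides (nt) for depths unless stated otherwise.

## Backbone knot assessment

### Chain model

A chain's curve is the ordered polyline through the backbone atoms P, O5′,
C5′, C4′, C3′, O3′ of each residue (six points per residue; a missing
phosphate on the 5′-terminal residue is tolerated, any other missing backbone
atom causes the residue to be skipped with a warning). Chains with fewer than
three usable residues are not assessed. Atom names are normalized (`*` and
`′` → `'`, so legacy `O5*` is accepted), and CASP submission headers
(`PFRMAT`, `TARGET`, …) are stripped before parsing.

Chains containing atoms at (near-)duplicate coordinates — two atoms of
distinct residues within 0.01 Å by default — are excluded from knot
analysis entirely and reported with status `invalid-coordinates`, because
coincident vertices make the diagram of the curve ill-defined.

### KMT reduction

Before closing, the open chain is simplified by the KMT procedure: an
interior vertex *v* is deleted whenever the triangle *(prev, v, next)* is
intersected by no other segment of the chain, iterated to a fixed point with
endpoints held fixed. The segment–triangle test is conservative: segments
running within tolerance of the triangle plane count as blocking, so a vertex
is only removed when its removal triangle is provably clear (tolerance
1e-9, absolute). Closed curves are reduced cyclically. Reduction preserves
the knot type of closed curves and, for open chains, the type of any closure
whose arc stays outside the chain's hull.

### Stochastic two-point closure

Knottedness of an open curve depends on how it is closed. Each closure pushes
both endpoints radially from the chain centroid onto a sphere of radius 10×
the maximal centroid distance, then joins the two sphere points through one
uniformly random point of the sphere by two great-circle arcs, each
approximated by chords of ≤ 20° so that every closure vertex stays on the
sphere and every closure segment stays far outside the chain. The default of
200 closures per chain gives a knot-type distribution; the chain is *knotted*
iff strictly fewer than 50% of closures are unknots, and the *dominant* label
is the most frequent non-trivial one. One *direct closure* (single straight
segment between the endpoints) is always computed: a chain that is
probabilistically knotted but trivially closed is flagged `ambiguous` rather
than silently discarded, and the pipeline option `discard_ambiguous`
reproduces the stricter convention of dropping such chains from the knotted
count.

Randomness is fully reproducible: closure *i* of a run with master seed *s*
draws from `default_rng([s, i])`, so histograms are bit-for-bit stable.

### Alexander polynomial

Each closed curve is projected along a random direction; directions giving
tangencies, vertex hits, coincident crossing depths, or overlapping
near-parallel segments are redrawn (up to 100 times). From the generic
diagram the Alexander matrix is assembled (one row per crossing, one column
per arc; entries 1−t on the over-arc and {−1, t} on the incoming/outgoing
under-arcs, swapped with crossing sign), one row and one column are deleted,
and the determinant over Z[t] is taken with fraction-free Bareiss elimination
(sympy). The result is normalized by units ±t^k to the symmetric
representative with positive constant term. Classification is by table lookup
over the prime knots through seven crossings; within that range the
polynomial is a complete invariant of the table, so each entry carries one
label (the lookup would join colliding labels with `|` if the table were ever
extended). Unrecognized polynomials are labelled `unknown`.

The table itself was validated against closed forms rather than copied
blindly: Δ of the (2,q) torus knots is the alternating sum
t^(q−1) − t^(q−2) + … + 1, and Δ of the twist knot with k half-twists is
a·t² − m·t + a with a = ⌈k/2⌉ and m = 2a∓1 — the test suite asserts both
families against the geometric pipeline.

### Too tangled to check (TTC)

Some densely packed chains cannot be classified reliably. Operationally: a
closure counts as `too_complex` when its diagram still exceeds the crossing
budget (default 50) after reduction, or when no generic projection is found;
a chain is TTC when more than 20% of its closures are `too_complex`. For
closed curves longer than 600 vertices the per-closure KMT pass is skipped
(the shared open-chain reduction has already run, and chains of that residual
size are far beyond the budget anyway); the projected crossing count is then
compared to the budget directly. The exact crossing budget is a convention —
any threshold well above the seven-crossing classification range behaves
identically on our fixtures.

## Entanglements of structure elements

### Elements

Canonical pairs (Watson–Crick A-U, G-C; wobble G-U) define three element
kinds per chain:

* **Loop** — one closed cycle per closing pair plus its directly enclosed
  pairs, alternating backbone arcs with hydrogen-bond edges (hairpin,
  internal, and multibranch cycles alike; helix-interior cycles of two
  stacked pairs are steps, not loops). Pseudoknotted pairs participate
  within their own crossing-free layer, so a hairpin closed by a
  pseudoknotted pair yields a loop exactly like a nested one.
* **Dinucleotide step** — the closed quadrilateral of two consecutive
  stacked pairs (i, j), (i+1, j−1).
* **Single strand** — each maximal unpaired run extended by its flanking
  paired anchors, as an open polyline. A run whose two anchors pair with
  *each other* (a hairpin interior) is wholly contained in its loop element
  and is not emitted separately; this avoids double-counting a loop and its
  own interior when the loop participates in an interlace.

Hydrogen-bond edges run between per-residue proxy points: the mean of the
residue's canonical donor/acceptor atoms when present, else C1′ — robust to
predicted models that carry no base atoms.

### Surfaces, punctures, linking

Each closed element is spanned by a triangle fan from its boundary centroid,
refined by 3 rounds of midpoint subdivision with Laplacian relaxation of
interior vertices (boundary fixed, so the surface boundary always coincides
with the element curve; the construction is deterministic). Punctures are
segment–triangle intersections (vectorized Möller–Trumbore, absolute
tolerance 1e-6 Å) with crossing signs from the surface orientation; hits
closer than 0.1 Å along the piercing curve, or geometrically coincident on
shared triangle edges, are merged. Linking numbers are computed as half the
sum of signed inter-curve crossings in a generic projection; the test suite
cross-checks this against an exact evaluation of the Gauss linking integral
over segment pairs. The entanglement label must not depend on the arbitrary
choice of spanning surface; the suite verifies that 1 vs 3 subdivision
rounds give identical calls on all fixtures.

### Taxonomy and artifact flags

For a closed element X and another element Y sharing no residue with it:
lk(X, Y) ≠ 0 (both closed) ⇒ interlace `X&Y` (kinds sorted, D before L);
punctures with lk = 0 ⇒ lasso `X(Y)`; a strand puncturing twice is reported
as L(S) with two intersection points. Elements sharing a residue are never
tested against each other (a loop and its closing stem would otherwise
self-intersect trivially). Interlaces are reported once per unordered pair.
All interlaces and all D(\*) lassos are artifacts; L(\*) lassos are artifacts
only when deep.

### Lasso depth

Depth is counted on the piercing element. Single puncture through a loop by
a strand: for each chain direction, the number of unpaired strand residues
strictly beyond the crossing-adjacent residue on that side, through the
terminal residue; depth is the minimum of the two counts (anchors are
excluded, so a strand spanning residues 36–69 with its anchor at 36 and a
crossing between residues 62 and 63 has depth min(25, 6) = 6). Two
punctures: the number of residues lying between the two crossing points,
i.e. from the residue after the first crossing segment through the residue
before the second, inclusive. Zero or more than two punctures: no depth.
Shallow means depth ≤ 5 nt, deep means > 5 nt, with the boundary exercised
explicitly in the tests (5 → shallow, 6 → deep).

The single-puncture rule admits two off-by-one readings (count from the
crossing segment, or from its adjacent residue). This implementation counts
strictly beyond the crossing-adjacent residue, the convention consistent
with the depth-6 example above; the generator and detector share no code on
this path, so the round-trip tests would catch a drift in either.

### Base-pair annotation

Models rarely ship secondary structure, so two sources are supported.
*Dot-bracket*: layered strings over `()[]{}<>` (4 pseudoknot layers),
validated for balance and length. *Geometric detection*: candidate pairs with
C1′–C1′ distance in [10.0, 11.0] Å whose full canonical donor–acceptor
pattern (e.g. N1–N3, N2–O2, O6–N4 for G-C) lies within [2.4, 3.5] Å;
best-scoring partner kept per residue (score: mean deviation from 2.9 Å).
These ranges are standard canonical-pair geometry; they are deliberately
strict, since a missed marginal pair costs one element while a spurious pair
invents a closed cycle. Detection is intra-chain only.

## Synthetic fixtures

The generators produce the archetypes the detectors must recognize, with
truth labels fixed by construction:

* **Knot curves** — parametric torus knots T(2,3)/T(2,5)/T(2,7) and
  polygonal twist-knot templates (4₁, 5₂, 6₁, 7₂) realized as plat closures
  of 4-strand braid words, each validated against the closed-form Alexander
  polynomials above. `open_fraction` removes a terminal arc, leaving the
  knot core intact (the opened-trefoil fixture drops 5%).
* **Hairpin lasso** — a planar stem-loop whose apical loop (circle of ~6 Å
  per-residue spacing) is threaded once, perpendicularly through its center,
  by the 3′ tail; the crossing falls between two consecutive residues with
  exactly *d* unpaired residues beyond it on the free-end side, so the depth
  convention returns *d* exactly, for d = 1…10.
* **Hopf loops** — two hairpins in one chain whose loop circles are
  interlocked orthogonally (each passes through the other's center),
  linking number ±1; the unlinked control translates the second hairpin
  away.
* **Dinucleotide pierce** — a tail pushed through the quadrilateral of a
  mid-stem step (D(S)); piercing a middle step avoids sharing residues with
  the tail's anchor.
* **Dense walk** — a ~3 Å-step random walk confined to a small box
  (default 1,200 steps in 15 Å) with reflecting walls; its diagrams stay in
  the thousands of crossings after reduction, driving the TTC pathway.
  Reflecting rather than clamping at the walls matters: clamped points stack
  on the box faces and create genuine self-intersections.

Fixture residues carry six idealized backbone atoms spread along ~6 Å
per-residue virtual bonds plus a C1′ proxy — realistic in scale and
connectivity, but not in nucleotide-level geometry: no base atoms (except
the dedicated helix fixture used to test geometric pair detection), no
sugar pucker, no A-form twist in the stems. Consequently the tests
demonstrate correct *topology* calls (knot labels, subclasses, depths,
linking) under controlled geometry; they do not exercise tolerance to the
noisy, near-clashing coordinates of real predictions, nor the base-pair
annotation ambiguities that dominate real-model disagreements.

## Pipeline conventions

Model identifiers are parsed as `R<target>TS<group>_<index>`. Two packaged
CSVs map the 12 CASP15 RNA targets to natural/synthetic + difficulty and
prediction groups to traditional/ML + server/human; the groups table ships
with the documented example groups and is meant to be extended by the user —
unknown models fall into an `unknown` stratum rather than failing. Cohort
tables count models once per row but lassos/interlaces per instance; the
Venn decomposition (only elements / only knots / both) satisfies the
identity that its three parts sum to the number of entangled models, which
is asserted on every cohort in the tests. Per-model JSON, the flat
entanglement CSV, the summary table, and the run manifest (seed, thresholds,
version) contain no timestamps, so reruns with the same seed are
byte-identical.

## Problem sizes

Defaults were chosen so a full audit stays interactive on one CPU: 200
closures per chain, crossing budget 50, 3 subdivision rounds, 1,200-step
dense walks; the packaged test suite and the acceptance script run the
complete pipeline at these sizes in a few minutes. Empirically the dominant
costs are the O(n²)-per-pass KMT reduction on long chains and the symbolic
determinant for diagrams near the crossing budget.

## Known limitations

* Knot labels are limited to prime knots through seven crossings; composite
  or larger knots report `unknown` (still counted as knotted when the
  closure vote says so).
* Geometric base-pair detection covers canonical pairs only (no
  Leontis–Westhof non-canonical families) and only within a chain; elements,
  and hence entanglements, are intra-chain constructs here even though the
  detector pools elements across chains.
* Surfaces are spanned on every loop cycle, including multibranch loops; on
  wildly non-planar junction cycles the fan-plus-relaxation surface is one
  of many spanning choices, and a puncture count on such a cycle is only as
  canonical as the surface (interlace calls, which use linking numbers, are
  unaffected).
* The closure-sphere sampling law is one faithful reading of "project the
  endpoints onto a large sphere and connect them"; other published closure
  variants (uniform direction pairs, one-point closure) can shift closure
  histograms by a few percent on shallow knots.
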