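# Methods

## The synthesis model

`ranksynth` treats a phylogeny purely as a set of rooted clusters.  A cluster
`C` of a source with leaf set `L` asserts the rooted triples `ab|c` for every
pair `a,b ∈ C` and every `c ∈ L\C`; branch lengths, support values and
internal labels carry no weight.  The engine never enumerates these triples:
a cluster is carried as the pair `(C, L\C)`, and inside the BUILD recursion a
constraint glues `C ∩ X` into one component of the current leaf set `X`
exactly when some member of `L\C` is still in `X`.  This is arithmetically
identical to running BUILD on the enumerated triple set (both forms induce
the same constraint-graph components at every recursion level) but scales
with the number of clusters rather than with `|C|²·|L\C|`.  The explicit
triple API (`RootedTriple`, `ConstraintSet`, `cluster_triples`,
`is_consistent`, `build_tree`) shares the same core, and the test suite
checks the core against exhaustive enumeration of all rooted trees on small
leaf sets.

Synthesis is greedy ranked atomic acceptance.  Sources are visited in rank
order with the taxonomy forcibly last; within a source, clusters are offered
largest-first (ties by lexicographically smallest leaf — for a single tree
the order is immaterial because its clusters are laminar and mutually
consistent).  A cluster is accepted iff the accepted constraint set plus all
of its triples is still BUILD-consistent; partial acceptance of a cluster's
triples is never attempted, because the cluster is the unit of "grouping" a
study asserts.  The output is the minimally resolved BUILD tree: children of
each node are the constraint-graph components, so nothing is resolved that
no accepted source implies, and species mentioned by no accepted cluster
attach at the root.  This engine is an independent re-implementation of
rank-precedence synthesis semantics, not of any particular pipeline's
subproblem decomposition; on a real corpus its tree is expected to agree in
its guarantees (rank-1 supremacy, taxonomy-last gap filling, basal
accumulation under broken taxa) rather than node-for-node with any
previously published synthesis.

Determinism everywhere is by construction: trees keep children sorted by
their lexicographically smallest descendant leaf, so equal topologies have
equal newick strings and repeated runs are byte-identical.

### Complexity and scale

Each candidate cluster triggers one full consistency check over the
universe, so synthesis costs roughly (number of offered clusters) ×
(BUILD over accepted constraints).  The implementation is comfortable to a
few hundred leaves and a few dozen sources on one core — the scale of the
examples and the test suite; corpora an order of magnitude larger are out of
the design envelope.

## Name resolution

Tip labels resolve against the taxonomy in a fixed cascade: exact accepted
name → exact synonym (resolved to its accepted target) → whitespace/case
normalized → fuzzy → genus-only → unmatched.  Fuzzy matching (edlib edit
distances, default budget 2) is two-tiered: candidates whose genus word
equals the query's are tried first, and only if none falls within the budget
do candidates whose genus word is itself within the budget compete.  The
tiering lets genus-word misspellings ("Ballanus balanus") resolve while a
same-genus candidate always beats an equally close congener-lookalike from
another genus.  A non-unique minimum distance within the deciding tier means
no match — the resolver never guesses.  Labels of the form `<Genus> sp.` or
`<Genus> sp. X` with an accepted genus become *pseudo-species* parented at
that genus, with ids deterministic in (genus, normalized label) so
re-validation is idempotent; such unidentified tips are first-class members
of the species universe, mirroring practice in synthesis projects that keep
genus-level tips as potential undescribed species.  The matching budget is a
declared default, not a value any published corpus states.

## Study ranking

Three criteria, applied as a stable sort: ascending scope ordinal (genus=1
… subclass=8); within a (scope, focal taxon) group, descending marker count
— a morphological character set counts as one marker unit; then descending
genus count, then descending species count; everything else keeps input
order.  Marker counts are deliberately *not* compared across different focal
taxa of equal scope: published rankings interleave focal taxa in ways no
marker criterion explains, and the criterion's own rationale (better
reconstructions of *the same* ancestor) only applies within a focal taxon.
The taxonomy source id is appended last unconditionally.

## Annotation semantics

For a synthesis node with leaf set `C` and a source with leaves `L`, let
`C' = C ∩ L`.  Empty, singleton, or whole-`L` restrictions are neutral.
`C'` equal to a source cluster is support; `C'` properly overlapping some
source cluster (both minus the other and the intersection non-empty) is
conflict; anything else — in particular a `C'` that would resolve inside a
source polytomy — is neutral.  Support and conflict so defined coincide with
triple-level satisfiability: conflict iff the source's triples plus the
triples of `C'`-as-a-cluster are jointly inconsistent (property-tested
against enumeration).  Annotation is computed against the finished tree,
independent of the acceptance ledger, so a low-ranked source can support
nodes it did not itself contribute.  The summary partitions *informed* nodes
(at least one support or conflict) into more-support / more-conflict /
equal.  Exports are a tab-separated branch-label file (`support/conflict`
per node, keyed by a 12-hex-digit SHA-1 of the sorted leaf ids) in the
drag-and-drop style of interactive tree viewers, plus a JSON-lines dump.

## Reports

*Resolution.*  `pct_unresolved = 100·(1 − bifurcating / expected)`.  The
expected count for a fully resolved tree is an explicit parameter defaulting
to `n_tips − 1` (the internal-node count of a rooted binary tree); it is a
parameter because published resolution figures sometimes rest on an expected
count that cannot be derived from the tip total.  Percentages display-round
half-away-from-zero to one decimal, matching how such figures are printed.

*Coverage.*  Per accepted taxon of a chosen rank: species total and counts
with phylogenetic, geographic, and both kinds of information, computed
through `species_under` (leaf taxa = species/subspecies without accepted
children, plus registered pseudo-species).  Printed proportions are always
recomputed quotients, never copied.

*Monophyly.*  For each taxon of a rank with ≥2 *eligible* members on the
tree: the members' MRCA is located and intruders are eligible non-member
leaves under it; zero intruders means monophyletic.  Eligibility defaults in
the pipeline to species appearing in at least one mapped source tree,
because taxonomy-placed leaves sit where the taxonomy put them and would
trivially vote for their own hierarchy.  Taxa with fewer than two eligible
members are reported "not assessable".  Para- versus polyphyly is not
distinguished — the distinction needs outgroup/character context the input
trees do not carry.

## Geographic coverage

Occurrence CSVs are Darwin-Core-like (scientificName, decimalLatitude,
decimalLongitude; case-insensitive headers).  Rows with unparseable or
out-of-bounds coordinates are dropped and counted; duplicates are retained,
as in raw aggregator exports.  Names resolve through the same cascade as
tips except that genus-only labels stay unresolved (an occurrence cannot be
tied to one particular unidentified tip).  A species "has geographic
information" iff ≥1 resolved record.  The "well-recorded but unsequenced"
table takes species with strictly more than `min_records` (default 30)
records and no phylogenetic data, sorted by descending count then name.
Density grids are equal-angle: cell indices `floor((lat+90)/cell)`,
`floor((lon+180)/cell)`, half-open except the closed top/right boundary;
counts are conserved for any cell size.

## The synthetic world

The generator is the package's stand-in for a real corpus of curated study
trees, a reference taxonomy, and an occurrence export; every test and the
acceptance script run against it.

* **Taxonomy** — a complete subclass→order→family→genus→species hierarchy
  with pseudo-Latin names; shape defaults (4 orders, 1–4 families each, 2–5
  genera per family, 1–6 species per genus, ≈120–160 species) keep runs in
  seconds while leaving room for monotypic and polytypic taxa.  A fraction
  of species (default 15%) gets one synonym; a fraction (default 5%) gets a
  misspelling of 1–2 edits, verified by brute force to have its true name as
  unique nearest accepted name so that resolution *must* recover it.
* **True tree** — the taxonomy tree with every polytomy resolved by random
  sequential joining, then each multi-species genus independently broken
  with probability `p_break` (default 0.3, echoing the observation that a
  large share of named taxa fail monophyly) by relocating one member outside
  the genus clade.  Relocation targets are never strictly inside another
  unbroken genus clade, so planted breakage is recoverable and the observed
  broken fraction is binomial in `p_break`.
* **Study corpus** — each study draws a scope (30% genus, 30% family, 25%
  order, 15% subclass — a narrow-heavy mix like published corpora), picks a
  focal taxon of that rank, samples 70% of its species (min 4), restricts
  the true tree, and applies rooted NNI moves (default 1) as topological
  noise; metadata records the realized species/genus counts and a drawn
  marker count.  A small fraction of tips can be relabeled `Genus sp. N` to
  emulate unidentified material.
* **Occurrences** — per-species record counts are negative-binomial (mean 8,
  shape 0.6: strongly overdispersed, as aggregator exports are, where a few
  species carry hundreds of records); coordinates are bivariate normal
  (σ = 12°) around a per-species uniform centroid, clipped to bounds; 2% of
  rows carry invalid latitudes and 10% use a synonym name.

What the generator does **not** emulate: real nomenclatural pathologies
(homonyms across kingdoms, authority strings), correlated sampling between
studies, coastline-shaped occurrence geography, and gene-tree/species-tree
discordance as a noise model (NNI count is a purely topological knob).
Passing tests therefore demonstrate the engine's contracts — precedence,
consistency, conservation, recovery — not field-realistic accuracy of any
particular corpus.

## Numerical and degenerate-input choices

Ties everywhere break lexicographically (cluster offering order, canonical
child order, fuzzy candidates by id).  Ambiguous exact name matches resolve
to the smallest taxon id.  The empty constraint set yields a star tree; an
empty universe is an error.  Sources whose leaves fall outside the declared
universe are rejected up front.  A mapped source tree must retain ≥2 leaves.
Occurrence coordinate bounds are closed (`lat = ±90`, `lon = ±180` are
valid).  All generator randomness flows from a single integer seed through
seeded numpy generators; identical configuration implies identical output
bytes.

## Known limitations

* Greedy atomic acceptance is order-dependent by design; it implements rank
  precedence, not any global optimality criterion, and a rejected cluster is
  never revisited even if later rejections would have made it admissible.
* Support/conflict uses exact-restriction identity; a source displayed
  within a synthesis polytomy counts as neutral, which undercounts "support"
  relative to path-based definitions used by some synthesis pipelines.
* The engine is not built for corpora beyond a few hundred leaves; no
  subproblem decomposition or triple subsampling is attempted.
* Geographic handling stops at bounds checking — no land/sea masking, no
  coordinate cleaning, no equal-area projection for the density grid.
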