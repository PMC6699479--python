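# ranksynth

Ranked supertree synthesis over a taxonomic backbone, for groups — like the
thecostracan barnacles that motivated the method — where published
phylogenies rarely share taxa or characters, yet a comprehensive taxonomy
exists.  `ranksynth` combines a set of rooted, branch-length-free source
trees with a reference taxonomy into a single *synthesis tree*: every
recognized species appears exactly once, species with phylogenetic data sit
where the best-ranked study places them, and everything else is placed by
taxonomy alone.  The package also quantifies what the synthesis does and
does not know: branch-level support/conflict counts against the source
trees, resolution statistics, per-rank coverage tables, monophyly
assessments of named taxa, and geographic occurrence coverage ("which
well-recorded species have never been sequenced?").

## The model

Inputs are ranked: studies with a narrower taxonomic scope outrank broader
ones; among studies aiming at the same focal taxon, more molecular markers
win; remaining ties go to more genera, then more species; the taxonomy is
always ranked last.  Each internal node (cluster `C`) of a source tree with
leaf set `L` is read as the set of rooted triples

```
ab|c   for all a,b ∈ C,  c ∈ L \ C
```

i.e. *a and b share a more recent common ancestor than either does with c*.
Synthesis is greedy ranked acceptance: walking sources in rank order and each
source's clusters largest-first, a cluster is accepted iff its triples are
jointly consistent — in the BUILD sense of Aho et al. (1981) — with
everything accepted so far, and rejected otherwise (acceptance is atomic per
cluster).  The final tree is the minimally resolved BUILD tree of the
accepted constraints, so a polytomy appears wherever no accepted source says
anything: in this framework a polytomy *is* the absence of information.
Consequences, all property-tested: the first-ranked tree has every grouping
displayed; jointly consistent corpora are reproduced in full; species named
by no study attach under their lowest accepted taxonomic cluster; members of
taxa broken by the phylogenies accumulate basally at the next higher rank.

Branch annotation follows the displayed/incompatible dichotomy: a source
*supports* a synthesis node if the node's leaf set, restricted to the
source's leaves, equals one of the source's own clusters; it *conflicts* if
the restriction properly overlaps some source cluster; otherwise it is
neutral.

## Worked example

Everything runs from synthetic data with known truth — no downloads:

```sh
ranksynth simulate --seed 7 --out demo
ranksynth run --config demo.yaml        # paths to demo/* and an out_dir
```

or equivalently in Python:

```python
from ranksynth.simulate import SimConfig, write_fixture
from ranksynth.pipeline import PipelineConfig, run_pipeline

truth = write_fixture(SimConfig(seed=7), "demo")
out = run_pipeline(PipelineConfig(
    taxonomy="demo/taxonomy.tsv", trees_dir="demo/studies",
    studies="demo/studies.tsv", occurrences="demo/occurrences.csv",
    out_dir="demo_out"))
```

With seed 7 the generator plants 116 described species (4 orders, genus
breakage probability 0.3 → 6 broken genera), 10 overlapping study trees —
whose tips carry planted synonyms, misspellings and `Genus sp. N` labels —
and 770 occurrence rows.  The run manifest then reports:

```
map_tips:   356 tip labels resolved, 0 pruned
synthesize: 334 clusters accepted, 41 rejected, 125 tips
annotate:   109 informed nodes — 99 more support, 3 more conflict, 7 equal
report:     97 of 124 expected nodes bifurcating → 21.8% unresolved
geo:        770 records, 11 rejected (bad coordinates), 95 species with data
```

and `reports/resolution.csv` contains

```
n_tips,n_internal,n_bifurcating,expected_resolved,pct_unresolved
125,110,97,124,21.8
```

Reading: all 116 species survive into the tree plus 9 genus-only tips
registered while mapping (leaf conservation is an engine invariant); 41
offered clusters lost conflicts to higher-ranked sources — mostly taxonomy
clusters of deliberately broken genera; the monophyly report
(`reports/monophyly_genus.csv`) flags 7 of 25 assessable genera as
non-monophyletic, recovering the 6 planted breaks plus one genus split by
study-tree noise.

## Layout

| module | role |
| --- | --- |
| `ranksynth.taxonomy` | taxonomy table I/O, validation, synonym/fuzzy/genus-only name resolution |
| `ranksynth.trees` | newick I/O, canonical form, clusters, restriction, MRCA, tip mapping |
| `ranksynth.ranking` | study ranking criteria, taxonomy ranked last |
| `ranksynth.synthesis` | rooted triples, BUILD consistency/construction, ranked greedy synthesis |
| `ranksynth.annotation` | branch support/conflict counts and annotation-file export |
| `ranksynth.reports` | resolution, coverage and monophyly reports |
| `ranksynth.geo` | occurrence ingestion, cross-tabulation, density grids |
| `ranksynth.simulate` | synthetic taxonomies, true trees, study corpora, occurrence tables |
| `ranksynth.pipeline` / `ranksynth.cli` | end-to-end orchestration and the `ranksynth` command |

See `docs/methods.md` for the underlying model, parameter defaults, and
known limitations.
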