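"""Synthetic corpora with known truth for exercising every pipeline stage.

The generator emulates the study conditions of a taxonomy-plus-ranked-trees
synthesis: a multi-rank reference taxonomy (subclass → order → family →
genus → species) seeded with synonyms and misspellings; a binary "true"
species tree obtained by randomly resolving the taxonomy tree, in which a
controllable fraction of genera is deliberately broken (one member relocated
outside its genus clade); a corpus of overlapping study trees of varying
scope, each a perturbed restriction of the true tree; and a GBIF-style
occurrence table with strongly overdispersed per-species record counts and
spatially clustered coordinates.  Everything is deterministic under a fixed
seed, and each generator returns the planted truth alongside the data so
tests can check parameter recovery instead of eyeballing.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ranking import StudyMetadata, rank_studies, write_ranked_ids
from .taxonomy import TaxonRecord, Taxonomy, write_taxonomy_tsv
from .trees import Tree, TreeNode, restrict, write_newick

__all__ = [
    "SimConfig",
    "gen_taxonomy",
    "gen_true_tree",
    "gen_study_corpus",
    "gen_occurrences",
    "corrupt_labels",
    "write_fixture",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic world; defaults are the study conditions used
    throughout the test-suite and the worked examples."""

    seed: int = 0
    # taxonomy shape (ranges are inclusive)
    n_orders: int = 4
    families_per_order: tuple[int, int] = (1, 4)
    genera_per_family: tuple[int, int] = (2, 5)
    species_per_genus: tuple[int, int] = (1, 6)
    synonym_rate: float = 0.15
    typo_rate: float = 0.05
    # true tree
    p_break: float = 0.3
    # study corpus
    n_studies: int = 10
    scope_weights: tuple[tuple[str, float], ...] = (
        ("genus", 0.30),
        ("family", 0.30),
        ("order", 0.25),
        ("subclass", 0.15),
    )
    sampling_fraction: float = 0.7
    n_perturbations: int = 1
    genus_only_rate: float = 0.03
    # occurrences (negative-binomial record counts, clustered coordinates)
    mean_records: float = 8.0
    dispersion: float = 0.6  # NB shape k; smaller = more overdispersed
    coord_spread_deg: float = 12.0
    invalid_coord_rate: float = 0.02
    synonym_name_rate: float = 0.10

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


_SYLLABLES = [
    "ba", "bel", "ca", "chi", "cor", "dar", "el", "fa", "gal", "hel",
    "ib", "kal", "lep", "mi", "nor", "op", "pel", "qua", "ros", "sca",
    "tal", "ul", "ver", "wil", "xan", "yor", "zel",
]


def _make_name(rng: np.random.Generator, n_syll: int, used: set[str]) -> str:
    for _ in range(1000):
        name = "".join(
            _SYLLABLES[rng.integers(0, len(_SYLLABLES))] for _ in range(n_syll)
        )
        if name not in used:
            used.add(name)
            return name
    raise RuntimeError("name space exhausted")


def _levenshtein(a: str, b: str) -> int:
    # small independent DP; the production path uses edlib
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _typo(word: str, n_edits: int, rng: np.random.Generator) -> str:
    letters = string.ascii_lowercase
    s = list(word)
    for _ in range(n_edits):
        op = rng.integers(0, 3)
        pos = int(rng.integers(0, max(len(s), 1)))
        if op == 0 and len(s) > 3:  # delete
            del s[pos]
        elif op == 1:  # insert
            s.insert(pos, letters[rng.integers(0, 26)])
        else:  # substitute
            if s:
                s[pos] = letters[rng.integers(0, 26)]
    return "".join(s)


def gen_taxonomy(
    cfg: SimConfig,
) -> tuple[Taxonomy, list[tuple[str, str]], list[tuple[str, str, int]]]:
    """Build the reference taxonomy.

    Returns (taxonomy, synonym table, misspelling table); the synonym table
    lists (synonym name, accepted species id), the misspelling table lists
    (corrupted label, true species id, edit distance ≤ 2) where each
    corrupted label is verified to have its true name as the unique nearest
    accepted name (so fuzzy resolution must recover it).
    """
    rng = cfg.rng(salt=1)
    used_names: set[str] = set()
    records: list[TaxonRecord] = []
    counter = [0]

    def new_id(prefix: str) -> str:
        counter[0] += 1
        return f"{prefix}{counter[0]:04d}"

    root_id = new_id("t")
    root_name = _make_name(rng, 4, used_names).capitalize()
    records.append(TaxonRecord(root_id, root_name, "subclass", None))
    species_names: dict[str, str] = {}  # id -> name
    genus_of: dict[str, str] = {}

    def draw(lohi: tuple[int, int]) -> int:
        lo, hi = lohi
        return int(rng.integers(lo, hi + 1))

    for _ in range(cfg.n_orders):
        oid = new_id("t")
        records.append(
            TaxonRecord(oid, _make_name(rng, 3, used_names).capitalize() + "ida",
                        "order", root_id)
        )
        for _ in range(draw(cfg.families_per_order)):
            fid = new_id("t")
            records.append(
                TaxonRecord(fid, _make_name(rng, 3, used_names).capitalize() + "idae",
                            "family", oid)
            )
            for _ in range(draw(cfg.genera_per_family)):
                gid = new_id("t")
                gname = _make_name(rng, 3, used_names).capitalize()
                records.append(TaxonRecord(gid, gname, "genus", fid))
                for _ in range(draw(cfg.species_per_genus)):
                    sid = new_id("t")
                    epithet = _make_name(rng, 3, used_names)
                    sname = f"{gname} {epithet}"
                    records.append(TaxonRecord(sid, sname, "species", gid))
                    species_names[sid] = sname
                    genus_of[sid] = gname

    # synonyms: a fraction of species get one synonym with a different epithet
    synonyms: list[tuple[str, str]] = []
    for sid, sname in species_names.items():
        if rng.random() < cfg.synonym_rate:
            alt = f"{genus_of[sid]} {_make_name(rng, 3, used_names)}"
            records.append(
                TaxonRecord(new_id("s"), alt, "species", None, "synonym", sid)
            )
            synonyms.append((alt, sid))

    taxonomy = Taxonomy(records)

    # misspellings: epithet-level typos with a verified unique minimizer
    accepted_norm = [n.casefold() for n in species_names.values()]
    typos: list[tuple[str, str, int]] = []
    for sid, sname in species_names.items():
        if rng.random() >= cfg.typo_rate:
            continue
        genus, epithet = sname.split(" ", 1)
        for _ in range(20):
            n_edits = int(rng.integers(1, 3))
            cand = f"{genus} {_typo(epithet, n_edits, rng)}"
            if cand == sname or cand in used_names:
                continue
            dists = [_levenshtein(cand.casefold(), n) for n in accepted_norm]
            d = _levenshtein(cand.casefold(), sname.casefold())
            if 0 < d <= 2 and dists.count(min(dists)) == 1 and min(dists) == d:
                typos.append((cand, sid, d))
                break
    return taxonomy, synonyms, typos


# -- true tree -------------------------------------------------------------


def _resolve_polytomies(tree: Tree, rng: np.random.Generator) -> Tree:
    """Binary resolution by random sequential joining at each polytomy."""
    t = tree.copy()
    for node in list(t.root.iter_postorder()):
        while len(node.children) > 2:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            joint = TreeNode()
            joint.add_child(a)
            joint.add_child(b)
            joint.parent = node
            node.children = [
                c for k, c in enumerate(node.children) if k not in (i, j)
            ] + [joint]
    return Tree(t.root)


def gen_true_tree(
    taxonomy: Taxonomy, p_break: float, seed: int | Sequence[int]
) -> tuple[Tree, list[str]]:
    """Binary true tree over all species; each multi-species genus is broken
    with probability ``p_break`` by relocating one member outside its clade.

    Relocation targets are never strictly inside another unbroken genus
    clade, so the broken fraction matches ``p_break`` binomially.  Returns
    (tree, ids of broken genera).
    """
    rng = np.random.default_rng(seed)
    tree = _resolve_polytomies(taxonomy.to_tree(), rng)
    genus_members = {
        gid: taxonomy.species_under(gid)
        for gid in taxonomy.accepted_ids(rank="genus")
    }
    multi = [g for g, m in sorted(genus_members.items()) if len(m) >= 2]
    broken: list[str] = []
    for gid in multi:
        if rng.random() >= p_break:
            continue
        members = genus_members[gid]
        # leaf sets per node, recomputed per relocation (tree is small)
        leafset: dict[int, frozenset[str]] = {}
        for n in tree.root.iter_postorder():
            if n.is_leaf:
                leafset[id(n)] = frozenset((n.label,))
            else:
                leafset[id(n)] = frozenset().union(
                    *(leafset[id(c)] for c in n.children)
                )
        from .trees import mrca as _mrca

        clade_root = _mrca(tree, members)
        inside = {id(m) for m in clade_root.iter_preorder()}
        unbroken = [
            g for g in multi if g != gid and g not in broken
        ]
        forbidden_interiors: set[int] = set()
        for g in unbroken:
            gm = genus_members[g]
            if gm <= tree.leaf_set and len(gm) >= 2:
                gr = _mrca(tree, gm)
                if leafset[id(gr)] == gm:  # still a clade
                    for m in gr.iter_preorder():
                        if m is not gr:
                            forbidden_interiors.add(id(m))
        mover_label = sorted(members)[int(rng.integers(0, len(members)))]
        targets = [
            n
            for n in tree.root.iter_preorder()
            if n is not tree.root
            and id(n) not in inside
            and id(n) not in forbidden_interiors
        ]
        if not targets:
            continue
        target = targets[int(rng.integers(0, len(targets)))]
        mover = tree.leaf_node(mover_label)
        # detach mover, suppress its unary parent
        parent = mover.parent
        parent.children.remove(mover)
        if len(parent.children) == 1 and parent.parent is not None:
            only = parent.children[0]
            gp = parent.parent
            gp.children[gp.children.index(parent)] = only
            only.parent = gp
        elif len(parent.children) == 1:
            # parent is root: promote the single child
            tree_root_child = parent.children[0]
            parent.children = tree_root_child.children
            parent.label = tree_root_child.label
            for c in parent.children:
                c.parent = parent
        # target is outside the genus clade, so detachment cannot orphan it
        new_leaf = TreeNode(label=mover_label)
        tgt_parent = target.parent
        joint = TreeNode()
        joint.parent = tgt_parent
        tgt_parent.children[tgt_parent.children.index(target)] = joint
        joint.add_child(target)
        joint.add_child(new_leaf)
        tree = Tree(tree.root)
        broken.append(gid)
    return tree, broken


# -- study corpus ----------------------------------------------------------


def _rooted_nni(tree: Tree, rng: np.random.Generator) -> Tree:
    """One rooted nearest-neighbour-interchange: swap a child of an internal
    node with one of that node's siblings."""
    t = tree.copy()
    candidates = [
        n
        for n in t.root.iter_preorder()
        if not n.is_leaf and n.parent is not None and len(n.parent.children) >= 2
    ]
    if not candidates:
        return t
    v = candidates[int(rng.integers(0, len(candidates)))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    s = siblings[int(rng.integers(0, len(siblings)))]
    c = v.children[int(rng.integers(0, len(v.children)))]
    u.children[u.children.index(s)] = c
    v.children[v.children.index(c)] = s
    c.parent, s.parent = u, v
    return Tree(t.root)


def gen_study_corpus(
    true_tree: Tree,
    taxonomy: Taxonomy,
    cfg: SimConfig,
) -> list[tuple[Tree, StudyMetadata]]:
    """Study trees as perturbed restrictions of the true tree.

    Each study picks a focal taxon at a drawn scope rank, samples its species
    at the sampling fraction (min 4), restricts the true tree, and applies
    ``n_perturbations`` rooted NNI moves.  Leaf labels stay taxon ids;
    name-space corruption is applied separately by :func:`corrupt_labels`.
    """
    rng = cfg.rng(salt=2)
    scopes, weights = zip(*cfg.scope_weights)
    weights = np.asarray(weights) / sum(weights)
    out: list[tuple[Tree, StudyMetadata]] = []
    genus_of = {
        sid: taxonomy.record(sid).parent_id
        for sid in true_tree.leaf_set
    }
    attempt = 0
    while len(out) < cfg.n_studies and attempt < cfg.n_studies * 50:
        attempt += 1
        scope = scopes[int(rng.choice(len(scopes), p=weights))]
        candidates = [
            tid
            for tid in taxonomy.accepted_ids(rank=scope)
            if len(taxonomy.species_under(tid) & true_tree.leaf_set) >= 4
        ]
        if not candidates:
            continue
        focal = candidates[int(rng.integers(0, len(candidates)))]
        pool = sorted(taxonomy.species_under(focal) & true_tree.leaf_set)
        n_sample = max(4, int(round(cfg.sampling_fraction * len(pool))))
        n_sample = min(n_sample, len(pool))
        picked = rng.choice(len(pool), size=n_sample, replace=False)
        sample = sorted(pool[i] for i in picked)
        study = restrict(true_tree, sample)
        for _ in range(cfg.n_perturbations):
            study = _rooted_nni(study, rng)
        sid = f"study{len(out) + 1:02d}"
        meta = StudyMetadata(
            study_id=sid,
            focal_taxon_id=focal,
            scope_rank=scope,
            marker_count=int(rng.integers(1, 8)),
            n_species=study.n_leaves,
            n_genera=len({genus_of[l] for l in study.leaf_set}),
        )
        out.append((study, meta))
    if len(out) < cfg.n_studies:
        raise RuntimeError("could not place the requested number of studies")
    return out


def corrupt_labels(
    labels: Sequence[str],
    taxonomy: Taxonomy,
    synonyms: Sequence[tuple[str, str]],
    typos: Sequence[tuple[str, str, int]],
    rng: np.random.Generator,
    synonym_rate: float = 0.15,
    typo_rate: float = 0.1,
    genus_only_rate: float = 0.0,
) -> tuple[list[str], dict[str, str]]:
    """Map taxon-id labels to (possibly corrupted) name labels.

    Returns (new labels, truth map new label → the taxon id it must resolve
    to).  Planted synonyms and verified misspellings substitute at the given
    rates; with ``genus_only_rate`` a label degrades to "<Genus> sp. N"
    (emulating unidentified material), whose truth entry is the deterministic
    pseudo-species id the resolver will register.  Everything else gets the
    accepted name.
    """
    syn_by_id: dict[str, list[str]] = {}
    for name, sid in synonyms:
        syn_by_id.setdefault(sid, []).append(name)
    typo_by_id: dict[str, list[str]] = {}
    for name, sid, _ in typos:
        typo_by_id.setdefault(sid, []).append(name)
    out: list[str] = []
    truth: dict[str, str] = {}
    sp_counter: dict[str, int] = {}
    for tid in labels:
        name = taxonomy.name_of(tid)
        r = rng.random()
        if r < genus_only_rate:
            genus_id = taxonomy.record(tid).parent_id
            sp_counter[genus_id] = sp_counter.get(genus_id, 0) + 1
            name = f"{taxonomy.name_of(genus_id)} sp. {sp_counter[genus_id]}"
            out.append(name)
            truth[name] = f"{genus_id}!{name.casefold()}"
            continue
        if r < genus_only_rate + synonym_rate and tid in syn_by_id:
            name = syn_by_id[tid][0]
        elif r < genus_only_rate + synonym_rate + typo_rate and tid in typo_by_id:
            name = typo_by_id[tid][0]
        out.append(name)
        truth[name] = tid
    return out, truth


# -- occurrences -----------------------------------------------------------


def gen_occurrences(
    taxonomy: Taxonomy,
    cfg: SimConfig,
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """GBIF-style occurrence table.

    Per-species record counts are negative-binomial (mean ``mean_records``,
    shape ``dispersion``); coordinates are bivariate normal around a
    per-species uniform-random centroid, clipped to bounds; a configured
    fraction of rows carries an out-of-bounds latitude and a fraction uses a
    synonym name.  Returns (table, planted per-species valid-record counts,
    number of invalid rows planted).
    """
    rng = cfg.rng(salt=3)
    species = sorted(
        sid
        for sid in taxonomy.species_under(taxonomy.root_id)
        if not taxonomy.record(sid).pseudo
    )
    syn_by_id: dict[str, list[str]] = {}
    for rec in taxonomy.records():
        if rec.status == "synonym":
            syn_by_id.setdefault(rec.synonym_of, []).append(rec.name)
    k = cfg.dispersion
    p = k / (k + cfg.mean_records)
    rows = []
    planted: dict[str, int] = {}
    n_invalid = 0
    for sid in species:
        n = int(rng.negative_binomial(k, p))
        if n == 0:
            continue
        lat0 = float(rng.uniform(-75, 75))
        lon0 = float(rng.uniform(-180, 180))
        valid = 0
        for _ in range(n):
            name = taxonomy.name_of(sid)
            if sid in syn_by_id and rng.random() < cfg.synonym_name_rate:
                name = syn_by_id[sid][0]
            lat = float(np.clip(rng.normal(lat0, cfg.coord_spread_deg), -90, 90))
            lon = float(np.clip(rng.normal(lon0, cfg.coord_spread_deg), -180, 180))
            if rng.random() < cfg.invalid_coord_rate:
                lat = 95.0 + float(rng.uniform(0, 5))
                n_invalid += 1
            else:
                valid += 1
            rows.append(
                {
                    "scientificName": name,
                    "decimalLatitude": round(lat, 4),
                    "decimalLongitude": round(lon, 4),
                }
            )
        if valid:
            planted[sid] = valid
    df = pd.DataFrame(
        rows, columns=["scientificName", "decimalLatitude", "decimalLongitude"]
    )
    return df, planted, n_invalid


# -- fixture directory -----------------------------------------------------


def write_fixture(cfg: SimConfig, out_dir: str | Path) -> dict[str, object]:
    """Emit a complete input fixture: taxonomy.tsv, studies/*.nwk,
    studies.tsv, ranked_ids.txt, occurrences.csv, and truth/ files."""
    out = Path(out_dir)
    (out / "studies").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    taxonomy, synonyms, typos = gen_taxonomy(cfg)
    true_tree, broken = gen_true_tree(taxonomy, cfg.p_break, (cfg.seed, 4))
    corpus = gen_study_corpus(true_tree, taxonomy, cfg)
    occurrences, planted, n_invalid = gen_occurrences(taxonomy, cfg)
    rng = cfg.rng(salt=5)

    write_taxonomy_tsv(taxonomy, out / "taxonomy.tsv")
    metas = []
    for study, meta in corpus:
        labels, _ = corrupt_labels(
            study.leaf_labels(),
            taxonomy,
            synonyms,
            typos,
            rng,
            synonym_rate=cfg.synonym_rate,
            typo_rate=cfg.typo_rate,
            genus_only_rate=cfg.genus_only_rate,
        )
        named = study.relabel(dict(zip(study.leaf_labels(), labels)))
        (out / "studies" / f"{meta.study_id}.nwk").write_text(
            write_newick(named) + "\n", encoding="utf-8"
        )
        metas.append(meta)
    with open(out / "studies.tsv", "w", encoding="utf-8") as fh:
        fh.write("study_id\tfocal_taxon\tscope\tmarkers\tn_species\tn_genera\n")
        for m in metas:
            markers = ";".join(f"m{i+1}" for i in range(m.marker_count))
            fh.write(
                f"{m.study_id}\t{m.focal_taxon_id}\t{m.scope_rank}\t{markers}\t"
                f"{m.n_species}\t{m.n_genera}\n"
            )
    write_ranked_ids(rank_studies(metas), out / "ranked_ids.txt")
    occurrences.to_csv(out / "occurrences.csv", index=False)
    (out / "truth" / "true_tree.nwk").write_text(
        write_newick(true_tree) + "\n", encoding="utf-8"
    )
    (out / "truth" / "broken_genera.txt").write_text(
        "\n".join(broken) + ("\n" if broken else ""), encoding="utf-8"
    )
    pd.DataFrame(
        sorted(planted.items()), columns=["taxon_id", "n_valid_records"]
    ).to_csv(out / "truth" / "planted_occurrence_counts.csv", index=False)
    with open(out / "truth" / "planted_names.tsv", "w", encoding="utf-8") as fh:
        fh.write("label\ttrue_id\tkind\n")
        for name, sid in synonyms:
            fh.write(f"{name}\t{sid}\tsynonym\n")
        for name, sid, d in typos:
            fh.write(f"{name}\t{sid}\ttypo{d}\n")
    return {
        "taxonomy": taxonomy,
        "true_tree": true_tree,
        "broken_genera": broken,
        "corpus": corpus,
        "synonyms": synonyms,
        "typos": typos,
        "planted_occurrences": planted,
        "n_invalid_rows": n_invalid,
    }
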