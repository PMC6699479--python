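"""Shared fixtures: a tiny hand-built taxonomy, a simulated world, and
brute-force oracles (exhaustive rooted-tree enumeration, DP edit distance)."""

from __future__ import annotations

import functools
import itertools
import random

import pytest
from hypothesis import settings

from ranksynth.simulate import SimConfig, gen_taxonomy, gen_true_tree
from ranksynth.taxonomy import Taxonomy, TaxonRecord

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


# -- hand-built taxonomy ---------------------------------------------------
#
# subclass Thecostraca
#   order Sessilida
#     family Balanidae
#       genus Balanus: B. balanus, B. crenatus
#       genus Amphibalanus: A. improvisus
#     family Chthamalidae
#       genus Chthamalus: C. stellatus, C. montagui
#   order Iblida
#     family Iblidae
#       genus Ibla: I. cumingi, I. quadrivalvis
# synonyms: "Lepas balanus" -> Balanus balanus


@pytest.fixture()
def small_taxonomy() -> Taxonomy:
    R = TaxonRecord
    return Taxonomy(
        [
            R("c1", "Thecostraca", "subclass", None),
            R("o1", "Sessilida", "order", "c1"),
            R("o2", "Iblida", "order", "c1"),
            R("f1", "Balanidae", "family", "o1"),
            R("f2", "Chthamalidae", "family", "o1"),
            R("f3", "Iblidae", "family", "o2"),
            R("g1", "Balanus", "genus", "f1"),
            R("g2", "Amphibalanus", "genus", "f1"),
            R("g3", "Chthamalus", "genus", "f2"),
            R("g4", "Ibla", "genus", "f3"),
            R("s1", "Balanus balanus", "species", "g1"),
            R("s2", "Balanus crenatus", "species", "g1"),
            R("s3", "Amphibalanus improvisus", "species", "g2"),
            R("s4", "Chthamalus stellatus", "species", "g3"),
            R("s5", "Chthamalus montagui", "species", "g3"),
            R("s6", "Ibla cumingi", "species", "g4"),
            R("s7", "Ibla quadrivalvis", "species", "g4"),
            R("y1", "Lepas balanus", "species", None, "synonym", "s1"),
        ]
    )


@pytest.fixture(scope="session")
def sim_world():
    """One deterministic simulated world shared across tests."""
    cfg = SimConfig(seed=11)
    taxonomy, synonyms, typos = gen_taxonomy(cfg)
    true_tree, broken = gen_true_tree(taxonomy, cfg.p_break, (cfg.seed, 4))
    return {
        "cfg": cfg,
        "taxonomy": taxonomy,
        "synonyms": synonyms,
        "typos": typos,
        "true_tree": true_tree,
        "broken": broken,
    }


# -- brute-force oracles ---------------------------------------------------


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook DP edit distance, independent of the edlib-backed path."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@functools.lru_cache(maxsize=None)
def all_rooted_binary_trees(labels: tuple[str, ...]) -> tuple[frozenset, ...]:
    """Every rooted binary tree on ``labels``, each as its frozenset of
    clusters (all node leaf sets, root and leaves included)."""
    labels = tuple(sorted(labels))
    if len(labels) == 1:
        leaf = frozenset([frozenset(labels)])
        return (leaf,)
    out = []
    rest = labels[1:]
    anchor = labels[0]
    for r in range(0, len(rest)):
        for combo in itertools.combinations(rest, r):
            left = tuple(sorted((anchor,) + combo))
            right = tuple(sorted(set(rest) - set(combo)))
            if not right:
                continue
            for lt in all_rooted_binary_trees(left):
                for rt in all_rooted_binary_trees(right):
                    out.append(lt | rt | {frozenset(labels)})
    return tuple(out)


def displays(tree_clusters: frozenset, a: str, b: str, c: str) -> bool:
    """Does a tree (as cluster set) display the rooted triple ab|c?"""
    return any(a in C and b in C and c not in C for C in tree_clusters)


def consistent_by_enumeration(universe: tuple[str, ...], triples) -> bool:
    """Ground truth: some rooted (binary suffices) tree displays them all."""
    for clusters in all_rooted_binary_trees(tuple(sorted(universe))):
        if all(displays(clusters, t.a, t.b, t.c) for t in triples):
            return True
    return False


@pytest.fixture(scope="session")
def enumeration_oracle():
    return consistent_by_enumeration
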