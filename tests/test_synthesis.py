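"""Rooted-triple constraints, BUILD consistency/construction, and ranked
greedy synthesis."""

import itertools
import random

import pytest
from hypothesis import given, strategies as st

from ranksynth.simulate import SimConfig, gen_study_corpus, gen_taxonomy, gen_true_tree
from ranksynth.synthesis import (
    ConstraintSet,
    InconsistentConstraints,
    RootedTriple,
    build_tree,
    cluster_triples,
    is_consistent,
    source_from_taxonomy,
    source_from_tree,
    synthesize,
)
from ranksynth.trees import mrca, nontrivial_clusters, parse_newick, restrict, write_newick

from conftest import all_rooted_binary_trees, consistent_by_enumeration, displays


def CS(triples, universe):
    return ConstraintSet(frozenset(triples), frozenset(universe))


class TestTriples:
    def test_canonical_pair_order(self):
        assert RootedTriple.of("b", "a", "c") == RootedTriple.of("a", "b", "c")
        with pytest.raises(ValueError):
            RootedTriple("a", "a", "c")

    @pytest.mark.parametrize(
        "C, L, expect",
        [
            ({"a", "b"}, {"a", "b", "c"}, {RootedTriple.of("a", "b", "c")}),
            (
                {"a", "b"},
                {"a", "b", "c", "d"},
                {RootedTriple.of("a", "b", "c"), RootedTriple.of("a", "b", "d")},
            ),
        ],
    )
    def test_examples(self, C, L, expect):
        assert cluster_triples(C, L) == expect

    @given(st.integers(0, 5_000))
    def test_combinatorial_count(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 9)
        L = {f"x{i}" for i in range(n)}
        k = rng.randint(2, n - 1)
        C = set(rng.sample(sorted(L), k))
        out = cluster_triples(C, L)
        assert len(out) == k * (k - 1) // 2 * (n - k)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            cluster_triples({"a"}, {"a", "b"})
        with pytest.raises(ValueError):
            cluster_triples({"a", "b"}, {"a", "b"})


class TestConsistency:
    def test_single_triple_consistent(self):
        assert is_consistent(CS({RootedTriple.of("a", "b", "c")}, "abc"))

    def test_contradictory_pair_inconsistent(self):
        assert not is_consistent(
            CS(
                {RootedTriple.of("a", "b", "c"), RootedTriple.of("a", "c", "b")},
                "abc",
            )
        )

    def test_agrees_with_exhaustive_enumeration(self):
        """Random triple sets on ≤6 leaves versus a scan of every rooted
        binary tree (binary resolutions suffice for displayability)."""
        rng = random.Random(42)
        for _ in range(150):
            n = rng.randint(3, 6)
            U = tuple(f"x{i}" for i in range(n))
            triples = set()
            for _ in range(rng.randint(1, 5)):
                a, b, c = rng.sample(U, 3)
                triples.add(RootedTriple.of(a, b, c))
            got = is_consistent(CS(triples, U))
            want = consistent_by_enumeration(U, triples)
            assert got == want, (U, triples)


class TestBuildTree:
    def test_no_constraints_gives_star(self):
        assert write_newick(build_tree(CS(set(), "abc"))) == "(a,b,c);"

    def test_single_triple(self):
        t = build_tree(CS({RootedTriple.of("a", "b", "c")}, "abc"))
        assert write_newick(t) == "((a,b),c);"

    def test_inconsistent_raises(self):
        with pytest.raises(InconsistentConstraints):
            build_tree(
                CS(
                    {RootedTriple.of("a", "b", "c"), RootedTriple.of("a", "c", "b")},
                    "abc",
                )
            )

    def test_output_displays_every_triple(self):
        rng = random.Random(7)
        done = 0
        while done < 60:
            n = rng.randint(3, 7)
            U = tuple(f"x{i}" for i in range(n))
            triples = set()
            for _ in range(rng.randint(1, 4)):
                a, b, c = rng.sample(U, 3)
                triples.add(RootedTriple.of(a, b, c))
            S = CS(triples, U)
            if not is_consistent(S):
                continue
            tree = build_tree(S)
            assert tree.leaf_set == frozenset(U)
            for t in triples:
                ab = tree.cluster_of(mrca(tree, {t.a, t.b}))
                assert t.c not in ab, (write_newick(tree), t)
            done += 1

    def test_minimal_resolution_no_uninformed_nodes(self):
        # one triple on a 5-leaf universe: everything else stays at the root
        t = build_tree(CS({RootedTriple.of("a", "b", "c")}, "abcde"))
        assert write_newick(t) == "((a,b),c,d,e);"


class TestSynthesize:
    def test_taxonomy_sole_source_equals_taxonomy_tree(self, sim_world):
        tax = sim_world["taxonomy"]
        res = synthesize(
            [source_from_taxonomy(tax)], tax.species_under(tax.root_id)
        )
        assert write_newick(res.tree) == write_newick(tax.to_tree())
        assert all(not e["rejected"] for e in res.ledger.values())

    def test_rank_precedence_on_conflict(self):
        first = source_from_tree("first", parse_newick("((a,b),c);"))
        second = source_from_tree("second", parse_newick("((a,c),b);"))
        star = source_from_tree("taxonomy", parse_newick("(a,b,c);"))
        res = synthesize([first, second, star], {"a", "b", "c"})
        assert write_newick(res.tree) == "((a,b),c);"
        assert res.rejected("second") == [frozenset({"a", "c"})]
        assert res.accepted("first") == [frozenset({"a", "b"})]
        # 3-leaf ground truth: the only trees displaying ab|c and ac|b differ
        assert not consistent_by_enumeration(
            ("a", "b", "c"),
            {RootedTriple.of("a", "b", "c"), RootedTriple.of("a", "c", "b")},
        )

    def test_broken_genus_basal_accumulation(self):
        """Taxonomy genera G1={a,b,x}, G2={c,d}; a rank-1 tree interleaving
        them wins, and the unsampled x falls back to a basal polytomy at the
        node above."""
        study = source_from_tree("study", parse_newick("((a,c),(b,d));"))
        taxonomy = type(study)(
            source_id="taxonomy",
            leaf_set=frozenset("abcdx"),
            clusters=(frozenset("abx"), frozenset("cd")),
        )
        res = synthesize([study, taxonomy], set("abcdx"))
        assert res.rejected("taxonomy") == [
            frozenset("abx"),
            frozenset("cd"),
        ] or set(res.rejected("taxonomy")) == {frozenset("abx"), frozenset("cd")}
        tree = res.tree
        assert tree.cluster_of(mrca(tree, {"a", "c"})) == {"a", "c"}
        assert tree.cluster_of(mrca(tree, {"b", "d"})) == {"b", "d"}
        # x attaches at the mrca of all five leaves
        x_parent_cluster = tree.cluster_of(tree.leaf_node("x").parent)
        assert x_parent_cluster == frozenset("abcdx")

    def test_leaf_conservation_and_unnamed_species_at_root(self):
        src = source_from_tree("s", parse_newick("((a,b),c);"))
        res = synthesize([src], {"a", "b", "c", "zz"})
        labels = res.tree.leaf_labels()
        assert sorted(labels) == ["a", "b", "c", "zz"]
        assert res.tree.leaf_node("zz").parent is res.tree.root

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            synthesize([], set())

    def test_source_outside_universe_rejected(self):
        src = source_from_tree("s", parse_newick("((a,b),c);"))
        with pytest.raises(ValueError, match="outside the universe"):
            synthesize([src], {"a", "b"})

    def test_rank1_supremacy_random_corpora(self, sim_world):
        """Every nontrivial cluster of the first-ranked source is displayed
        in the output even under heavy conflict from later sources."""
        cfg = SimConfig(seed=21, n_orders=2, n_studies=4, n_perturbations=3)
        tax, _, _ = gen_taxonomy(cfg)
        tree, _ = gen_true_tree(tax, 0.4, (21, 4))
        corpus = gen_study_corpus(tree, tax, cfg)
        sources = [source_from_tree(m.study_id, t) for t, m in corpus]
        sources.append(source_from_taxonomy(tax))
        res = synthesize(sources, tax.species_under(tax.root_id))
        first = sources[0]
        assert not res.rejected(first.source_id)
        restricted = restrict(res.tree, first.leaf_set)
        shown = nontrivial_clusters(restricted)
        for C in first.clusters:
            assert C in shown

    def test_determinism_byte_identical(self, sim_world):
        tax = sim_world["taxonomy"]
        cfg = sim_world["cfg"]
        tree = sim_world["true_tree"]
        corpus = gen_study_corpus(tree, tax, cfg)
        sources = [source_from_tree(m.study_id, t) for t, m in corpus]
        sources.append(source_from_taxonomy(tax))
        U = tax.species_under(tax.root_id)
        a = write_newick(synthesize(sources, U).tree)
        b = write_newick(synthesize(sources, U).tree)
        assert a == b
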