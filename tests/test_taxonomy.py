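"""Taxonomy store: validation, hierarchy queries, and tip-name resolution."""

import pytest

from ranksynth.simulate import SimConfig, corrupt_labels, gen_taxonomy
from ranksynth.taxonomy import (
    Taxonomy,
    TaxonRecord,
    TaxonomyError,
    load_taxonomy,
    read_taxonomy_tsv,
    validate_names,
    write_taxonomy_tsv,
)

from conftest import dp_levenshtein


class TestLoad:
    def test_minimal_three_rank_hierarchy(self):
        tax = load_taxonomy(
            [
                ("t1", "", "Thecostraca", "subclass", "accepted", ""),
                ("t2", "t1", "Iblidae", "family", "accepted", ""),
                ("t3", "t2", "Ibla cumingi", "species", "accepted", ""),
            ]
        )
        assert tax.root_id == "t1"
        assert tax.species_under("t1") == {"t3"}

    @pytest.mark.parametrize(
        "rows, message",
        [
            (
                [("a", "b", "A", "genus", "accepted", ""),
                 ("b", "a", "B", "family", "accepted", "")],
                "cycle|root",
            ),
            (
                [("a", "", "A", "subclass", "accepted", ""),
                 ("b", "", "B", "subclass", "accepted", "")],
                "multiple roots",
            ),
            (
                [("a", "", "A", "subclass", "accepted", ""),
                 ("b", "zzz", "B", "order", "accepted", "")],
                "dangling",
            ),
            (
                [("a", "", "A", "subclass", "accepted", ""),
                 ("y1", "", "B", "species", "synonym", "y2"),
                 ("y2", "", "C", "species", "synonym", "y1")],
                "synonym",
            ),
            (
                [("a", "", "A", "kingdom", "accepted", "")],
                "unknown rank",
            ),
        ],
    )
    def test_invalid_tables_rejected(self, rows, message):
        with pytest.raises(TaxonomyError):
            load_taxonomy(rows)

    def test_child_rank_must_be_finer(self):
        with pytest.raises(TaxonomyError):
            load_taxonomy(
                [
                    ("a", "", "A", "genus", "accepted", ""),
                    ("b", "a", "B", "family", "accepted", ""),
                ]
            )

    def test_tsv_round_trip_is_identity(self, tmp_path):
        tax, _, _ = gen_taxonomy(SimConfig(seed=1))
        path = tmp_path / "tax.tsv"
        write_taxonomy_tsv(tax, path)
        back = read_taxonomy_tsv(path)
        orig = {r.taxon_id: r for r in tax.records() if not r.pseudo}
        loaded = {r.taxon_id: r for r in back.records()}
        assert orig.keys() == loaded.keys()
        for tid, rec in orig.items():
            assert loaded[tid] == rec

    def test_ott_pipe_dialect(self, tmp_path):
        path = tmp_path / "ott.tsv"
        path.write_text(
            "uid | parent_uid | name | rank | status | synonym_of\n"
            "1 |  | Thecostraca | subclass |  | \n"
            "2 | 1 | Ibla | genus |  | \n",
            encoding="utf-8",
        )
        tax = read_taxonomy_tsv(path, ott_dialect=True)
        assert tax.root_id == "1" and tax.record("2").name == "Ibla"


class TestSpeciesUnder:
    def test_leaf_returns_itself(self, small_taxonomy):
        assert small_taxonomy.species_under("s1") == {"s1"}

    def test_genus_returns_direct_children(self, small_taxonomy):
        assert small_taxonomy.species_under("g1") == {"s1", "s2"}

    def test_count_matches_generator_shape(self):
        cfg = SimConfig(
            seed=2,
            n_orders=1,
            families_per_order=(1, 1),
            genera_per_family=(3, 3),
            species_per_genus=(4, 4),
        )
        tax, _, _ = gen_taxonomy(cfg)
        assert len(tax.species_under(tax.root_id)) == 12

    def test_rejects_synonym_and_unknown(self, small_taxonomy):
        with pytest.raises(TaxonomyError):
            small_taxonomy.species_under("y1")
        with pytest.raises(TaxonomyError):
            small_taxonomy.species_under("nope")

    def test_sibling_sets_disjoint_and_nest(self, sim_world):
        tax = sim_world["taxonomy"]
        for tid in tax.accepted_ids():
            kids = tax.children(tid)
            sets = [tax.species_under(k) for k in kids if tax.record(k).is_accepted]
            union = frozenset().union(*sets) if sets else frozenset()
            assert union <= tax.species_under(tid)
            for i in range(len(sets)):
                for j in range(i + 1, len(sets)):
                    assert not (sets[i] & sets[j])


class TestValidateNames:
    def test_exact_match(self, small_taxonomy):
        (r,) = validate_names(["Balanus balanus"], small_taxonomy)
        assert (r.matched_id, r.match_kind, r.edit_distance) == ("s1", "exact", 0)

    def test_synonym_resolves_to_target(self, small_taxonomy):
        (r,) = validate_names(["Lepas balanus"], small_taxonomy)
        assert (r.matched_id, r.match_kind) == ("s1", "synonym")

    def test_normalized_whitespace_and_case(self, small_taxonomy):
        (r,) = validate_names(["  balanus   BALANUS "], small_taxonomy)
        assert (r.matched_id, r.match_kind) == ("s1", "normalized")

    def test_fuzzy_unique_minimizer_with_bruteforce_oracle(self, small_taxonomy):
        query = "Ballanus balanus"  # 1 edit from "Balanus balanus"
        (r,) = validate_names([query], small_taxonomy, fuzzy_threshold=2)
        assert (r.match_kind, r.edit_distance) == ("fuzzy", 1)
        # oracle: exhaustive DP scan over all accepted species names
        accepted = [
            rec for rec in small_taxonomy.records()
            if rec.is_accepted and rec.rank == "species"
        ]
        dists = {
            rec.taxon_id: dp_levenshtein(query.casefold(), rec.name.casefold())
            for rec in accepted
        }
        best = min(dists.values())
        minimizers = [t for t, d in dists.items() if d == best]
        assert minimizers == [r.matched_id] and best == 1

    def test_genus_word_typo_still_resolves(self, small_taxonomy):
        # the misspelling sits in the genus word itself
        (r,) = validate_names(["Ballanus balanus"], small_taxonomy, fuzzy_threshold=2)
        assert (r.matched_id, r.match_kind, r.edit_distance) == ("s1", "fuzzy", 1)

    def test_same_genus_candidates_beat_cross_genus_ties(self):
        # "Balanus balanut" is 1 edit from both a congener and a species of a
        # similarly spelled genus; the same-genus candidate must win
        tax = load_taxonomy(
            [
                ("r", "", "Root", "subclass", "accepted", ""),
                ("g1", "r", "Balanus", "genus", "accepted", ""),
                ("g2", "r", "Calanus", "genus", "accepted", ""),
                ("sa", "g1", "Balanus balanus", "species", "accepted", ""),
                ("sb", "g2", "Calanus balanut", "species", "accepted", ""),
            ]
        )
        (r,) = validate_names(["Balanus balanut"], tax, fuzzy_threshold=2)
        assert (r.matched_id, r.match_kind, r.edit_distance) == ("sa", "fuzzy", 1)

    def test_far_genus_word_stays_unmatched(self, small_taxonomy):
        # a garbled genus word beyond the edit budget disqualifies the name
        (r,) = validate_names(["Xyzanus balanus"], small_taxonomy, fuzzy_threshold=2)
        assert r.match_kind == "unmatched"

    def test_ambiguous_fuzzy_is_unmatched(self):
        tax = load_taxonomy(
            [
                ("r", "", "Root", "subclass", "accepted", ""),
                ("g", "r", "Abla", "genus", "accepted", ""),
                ("sa", "g", "Abla cara", "species", "accepted", ""),
                ("sb", "g", "Abla carb", "species", "accepted", ""),
            ]
        )
        (r,) = validate_names(["Abla carc"], tax, fuzzy_threshold=2)
        assert r.match_kind == "unmatched"

    def test_genus_only_tip_registered_and_retained(self, small_taxonomy):
        (r,) = validate_names(["Chthamalus sp. A"], small_taxonomy)
        assert r.match_kind == "genus_only" and r.edit_distance == 0
        assert r.matched_id in small_taxonomy
        assert r.matched_id in small_taxonomy.species_under("g3")

    def test_unmatched_is_a_result_not_an_error(self, small_taxonomy):
        (r,) = validate_names(["Nonexistens speciesus"], small_taxonomy)
        assert r.matched_id is None and r.match_kind == "unmatched"

    def test_idempotent_on_accepted_names(self, sim_world):
        tax = sim_world["taxonomy"]
        names = [tax.name_of(t) for t in sorted(tax.species_under(tax.root_id))]
        first = validate_names(names, tax)
        again = validate_names([tax.name_of(r.matched_id) for r in first], tax)
        assert all(r.match_kind == "exact" and r.edit_distance == 0 for r in again)

    def test_corruption_recovery_is_total(self, sim_world):
        """Planted synonyms and ≤2-edit unique-minimizer typos all resolve
        back to their original taxon."""
        tax, synonyms, typos = (
            sim_world["taxonomy"],
            sim_world["synonyms"],
            sim_world["typos"],
        )
        import numpy as np

        labels = sorted(tax.species_under(tax.root_id))
        corrupted, truth = corrupt_labels(
            labels, tax, synonyms, typos, np.random.default_rng(5),
            synonym_rate=0.3, typo_rate=0.3,
        )
        results = validate_names(corrupted, tax, fuzzy_threshold=2)
        assert len(results) == len(labels)
        for res in results:
            assert res.matched_id == truth[res.query_label], res


class TestClusters:
    def test_size_ordering_family_before_genera(self):
        tax = load_taxonomy(
            [
                ("r", "", "Root", "subclass", "accepted", ""),
                ("f", "r", "Fam", "family", "accepted", ""),
                ("g1", "f", "Ga", "genus", "accepted", ""),
                ("g2", "f", "Gb", "genus", "accepted", ""),
                ("a1", "g1", "Ga a", "species", "accepted", ""),
                ("a2", "g1", "Ga b", "species", "accepted", ""),
                ("b1", "g2", "Gb a", "species", "accepted", ""),
                ("b2", "g2", "Gb b", "species", "accepted", ""),
                ("b3", "g2", "Gb c", "species", "accepted", ""),
            ]
        )
        clusters = tax.clusters()
        assert [tid for tid, _ in clusters] == ["f", "g2", "g1"]
        assert [len(s) for _, s in clusters] == [5, 3, 2]

    def test_monotypic_genus_contributes_nothing(self, small_taxonomy):
        ids = [tid for tid, _ in small_taxonomy.clusters()]
        assert "g2" not in ids  # Amphibalanus has one species

    def test_sets_match_species_under_and_sizes_non_increasing(self, sim_world):
        tax = sim_world["taxonomy"]
        clusters = tax.clusters()
        sizes = [len(s) for _, s in clusters]
        assert sizes == sorted(sizes, reverse=True)
        for tid, s in clusters:
            assert s == tax.species_under(tid)
            assert len(s) >= 2


class TestToTree:
    def test_genus_pair(self):
        tax = load_taxonomy(
            [
                ("r", "", "Root", "subclass", "accepted", ""),
                ("g", "r", "G", "genus", "accepted", ""),
                ("a", "g", "G a", "species", "accepted", ""),
                ("b", "g", "G b", "species", "accepted", ""),
            ]
        )
        from ranksynth.trees import write_newick

        assert write_newick(tax.to_tree()) == "(a,b);"

    def test_unary_suppression(self):
        tax = load_taxonomy(
            [
                ("r", "", "Root", "subclass", "accepted", ""),
                ("f", "r", "F", "family", "accepted", ""),
                ("g", "f", "G", "genus", "accepted", ""),
                ("h", "f", "H", "genus", "accepted", ""),
                ("a", "g", "G a", "species", "accepted", ""),
                ("b", "h", "H b", "species", "accepted", ""),
                ("c", "h", "H c", "species", "accepted", ""),
            ]
        )
        from ranksynth.trees import write_newick

        # monotypic genus G collapses; family node holds ((b,c),a)
        assert write_newick(tax.to_tree()) == "(a,(b,c));"

    def test_zero_species_is_an_error(self):
        tax = load_taxonomy([("r", "", "Root", "subclass", "accepted", "")])
        with pytest.raises(TaxonomyError):
            tax.to_tree()


class TestRestrictTo:
    def test_root_restriction_drops_outside_taxa(self, small_taxonomy):
        sub = small_taxonomy.restrict_to("o1")
        assert sub.root_id == "o1"
        assert sub.species_under("o1") == {"s1", "s2", "s3", "s4", "s5"}
        assert "s6" not in sub
        # synonym of a surviving species survives
        assert "y1" in sub
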