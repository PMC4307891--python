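"""Hyponym expansion, faceting/refinement, and the microarray filter."""

import pytest

from predqa.features import (
    EmptyGeneSetError,
    ExpansionSpec,
    FilterSpec,
    apply_filter,
    compute_facets,
    expand_argument,
    microarray_clause,
    refine_with_facet,
)
from predqa.io import Experiment, GeneEntry
from predqa.query import OrNode, TermClause, build_index, parse_query, search
from predqa.synth import SynthConfig, generate_synthetic_experiment, generate_synthetic_store

from oracles import brute_force_search


class TestExpansion:
    def test_hyponyms_join_the_clause_as_phrases(self, mini_store):
        ast = parse_query("arg_name:antipsychotic treats")
        spec = ExpansionSpec(field="arg_name", seed_word="antipsychotic")
        expanded = expand_argument(ast, spec, mini_store)
        or_node = expanded.children[0]
        assert isinstance(or_node, OrNode)
        terms = {c.term for c in or_node.children}
        assert {"antipsychotic", "clozapine", "olanzapine"} <= terms

    def test_expansion_widens_results(self, mini_store):
        idx = build_index(mini_store)
        ast = parse_query("arg_name:antipsychotic treats")
        before = search(idx, ast)
        spec = ExpansionSpec(field="arg_name", seed_word="antipsychotic")
        after = search(idx, expand_argument(ast, spec, mini_store))
        assert before.predication_ids < after.predication_ids
        # Clozapine-TREATS-Schizophrenia is reachable only via expansion.
        assert any(
            "Clozapine"
            in [
                mini_store.concepts[c].preferred_name
                for c in mini_store.predications[pid].subject_cuis
            ]
            for pid in after
        )

    def test_concept_without_hyponyms_is_unchanged_semantically(self, mini_store):
        idx = build_index(mini_store)
        ast = parse_query("arg_name:levodopa")
        spec = ExpansionSpec(field="arg_name", seed_word="levodopa")
        expanded = expand_argument(ast, spec, mini_store)
        assert search(idx, expanded).predication_ids == search(idx, ast).predication_ids

    def test_seed_matches_by_whole_token_only(self, mini_store):
        """'anti' is a substring of 'antipsychotic' but not a token of any name."""
        ast = parse_query("arg_name:anti treats")
        spec = ExpansionSpec(field="arg_name", seed_word="anti")
        expanded = expand_argument(ast, spec, mini_store)
        clause = expanded.children[0]
        assert clause == TermClause(field="arg_name", term="anti")  # nothing added

    def test_cap_keeps_top_hundred_by_isa_attestation(self):
        store = generate_synthetic_store(
            SynthConfig(
                n_concepts=200, n_relations=160, n_instances=800,
                isa_tree_depth=1, isa_branching=150, n_isa_roots=1,
                gene_fraction=0.1, seed=9,
            )
        )
        links = store.isa_links
        (root,) = {next(iter(p)) for p in links.values()}
        root_word = store.concepts[root].preferred_name.split()[0]
        ast = parse_query(f"arg_name:{root_word}")
        spec = ExpansionSpec(field="arg_name", seed_word=root_word, cap=100)
        expanded = expand_argument(ast, spec, store)
        phrases = [c for c in expanded.children if c.phrase]
        assert len(phrases) == 100
        # Sort-and-slice oracle over the generated forest.
        children = store.isa_children(root)
        expected = sorted(
            children, key=lambda c: (-store.isa_instance_count(c, root), c)
        )[:100]
        expected_names = [store.concepts[c].preferred_name.lower() for c in expected]
        assert [c.term for c in phrases] == expected_names

    def test_depth_two_reaches_grandchildren(self):
        store = generate_synthetic_store(
            SynthConfig(n_concepts=100, n_relations=60, n_instances=150,
                        isa_tree_depth=2, isa_branching=3, n_isa_roots=1,
                        gene_fraction=0.0, seed=12)
        )
        links = store.isa_links
        (root,) = {next(iter(p)) for p in links.values()} - set(links)
        root_word = store.concepts[root].preferred_name.split()[0]
        ast = parse_query(f"arg_name:{root_word}")
        shallow = expand_argument(
            ast, ExpansionSpec("arg_name", root_word, depth=1), store
        )
        deep = expand_argument(
            ast, ExpansionSpec("arg_name", root_word, depth=2), store
        )
        n_shallow = len([c for c in shallow.children if c.phrase])
        n_deep = len([c for c in deep.children if c.phrase])
        assert n_shallow == 3 and n_deep == 12

    def test_multiword_seed_rejected(self):
        with pytest.raises(ValueError, match="single word"):
            ExpansionSpec(field="arg_name", seed_word="down syndrome")

    def test_missing_clause_rejected(self, mini_store):
        ast = parse_query("treats")
        with pytest.raises(ValueError, match="no clause"):
            expand_argument(
                ast, ExpansionSpec(field="arg_name", seed_word="levodopa"), mini_store
            )

    def test_unfielded_expansion_rejected(self):
        with pytest.raises(ValueError, match="name field"):
            ExpansionSpec(field="relation", seed_word="treats")


class TestFacets:
    def test_empty_results_empty_facets(self, mini_store):
        idx = build_index(mini_store)
        results = search(idx, parse_query("nonexistenttoken"))
        f = compute_facets(results, mini_store, 5)
        assert f.subjects == () and f.relations == () and f.objects == ()

    def test_counts_equal_brute_force_recount(self, mini_store, synth_store):
        for store, query_text in [
            (mini_store, "relation:treats"),
            (synth_store, "dsyn"),
            (synth_store, "relation:isa"),
        ]:
            idx = build_index(store)
            results = search(idx, parse_query(query_text))
            f = compute_facets(results, store, 1000)
            recount: dict = {}
            for pid in results:
                p = store.predications[pid]
                for cui in set(p.subject_cuis):
                    name = store.concepts[cui].preferred_name
                    recount[name] = recount.get(name, 0) + 1
            assert {e.value: e.relation_count for e in f.subjects} == recount
            assert all(e.relation_count <= len(results) for e in f.subjects)

    def test_most_frequent_subject_heads_the_facet(self, mini_store):
        idx = build_index(mini_store)
        results = search(idx, parse_query("relation:treats"))
        f = compute_facets(results, mini_store, 3)
        assert f.subjects[0].value == "Donepezil"
        assert f.subjects[0].relation_count == 3
        assert f.relations[0].value == "TREATS"

    def test_ranking_is_descending_with_alpha_ties(self, synth_store):
        idx = build_index(synth_store)
        results = search(idx, parse_query("relation:isa"))
        f = compute_facets(results, synth_store, 50)
        for entries in (f.subjects, f.relations, f.objects):
            keys = [(-e.relation_count, e.value) for e in entries]
            assert keys == sorted(keys)

    def test_n_must_be_positive(self, mini_store):
        idx = build_index(mini_store)
        results = search(idx, parse_query("treats"))
        with pytest.raises(ValueError):
            compute_facets(results, mini_store, 0)


class TestRefinement:
    def test_refine_by_relation_restricts_predicate(self, mini_store):
        idx = build_index(mini_store)
        ast = parse_query("arg_name:parkinson")
        refined = refine_with_facet(ast, "relation", "CAUSES")
        results = search(idx, refined)
        assert len(results) >= 1
        for pid in results:
            assert mini_store.predications[pid].predicate == "CAUSES"

    def test_refined_results_are_subset(self, synth_store):
        idx = build_index(synth_store)
        ast = parse_query("dsyn")
        base = search(idx, ast)
        f = compute_facets(base, synth_store, 3)
        for kind, entries in [("subject", f.subjects), ("relation", f.relations),
                              ("object", f.objects)]:
            for entry in entries:
                refined = search(idx, refine_with_facet(ast, kind, entry.value))
                assert refined.predication_ids <= base.predication_ids

    def test_refine_by_subject_checks_against_brute_force(self, mini_store):
        ast = parse_query("relation:treats")
        refined = refine_with_facet(ast, "subject", "Donepezil")
        idx = build_index(mini_store)
        assert search(idx, refined).predication_ids == brute_force_search(
            mini_store, refined
        )

    def test_refining_twice_is_idempotent(self, mini_store):
        idx = build_index(mini_store)
        ast = parse_query("arg_name:parkinson")
        once = refine_with_facet(ast, "relation", "CAUSES")
        twice = refine_with_facet(once, "relation", "CAUSES")
        assert once == twice
        assert search(idx, once).predication_ids == search(idx, twice).predication_ids


def _experiment(*genes):
    return Experiment(name="fixture", genes=tuple(genes))


GENE_UP = GeneEntry(entrez_id=6622, symbol="SNCA", direction="up", measure=2.1, p_value=0.001)
GENE_DOWN = GeneEntry(entrez_id=351, symbol="APP", direction="down", measure=-1.4, p_value=0.02)


class TestMicroarrayFilter:
    def test_subject_slot_up_only(self, mini_store):
        idx = build_index(mini_store)
        ast = parse_query("relation:(ASSOCIATED_WITH OR PREDISPOSES OR CAUSES)")
        spec = FilterSpec(experiment=_experiment(GENE_UP, GENE_DOWN),
                          slot="subject", direction="up")
        filtered = apply_filter(ast, microarray_clause(spec))
        results = search(idx, filtered)
        assert len(results) >= 1
        for pid in results:
            entrez = {
                mini_store.concepts[c].entrez_gene_id
                for c in mini_store.predications[pid].subject_cuis
            }
            assert 6622 in entrez

    def test_either_slot_single_gene(self, mini_store):
        idx = build_index(mini_store)
        ast = parse_query("relation:(ASSOCIATED_WITH OR CAUSES OR TREATS)")
        spec = FilterSpec(experiment=_experiment(GENE_DOWN), slot="either",
                          direction="both")
        results = search(idx, apply_filter(ast, microarray_clause(spec)))
        for pid in results:
            p = mini_store.predications[pid]
            entrez = {
                mini_store.concepts[c].entrez_gene_id
                for c in p.subject_cuis + p.object_cuis
            }
            assert 351 in entrez

    def test_both_directions_equal_union_of_up_and_down(self, synth_store):
        exp = generate_synthetic_experiment(synth_store, seed=21)
        idx = build_index(synth_store)
        ast = parse_query("relation:(treats OR causes OR inhibits OR stimulates "
                          "OR associated_with OR affects OR interacts_with)")

        def run(direction):
            spec = FilterSpec(experiment=exp, slot="either", direction=direction)
            return search(idx, apply_filter(ast, microarray_clause(spec))).predication_ids

        assert run("both") == run("up") | run("down")

    def test_filter_equals_posthoc_brute_force(self, synth_store):
        """Query rewriting == filtering the unfiltered results afterwards."""
        exp = generate_synthetic_experiment(synth_store, seed=22)
        up_ids = {g.entrez_id for g in exp.subset("up")}
        idx = build_index(synth_store)
        ast = parse_query("aapp OR gngm")
        unfiltered = search(idx, ast)
        spec = FilterSpec(experiment=exp, slot="subject", direction="up")
        filtered = search(idx, apply_filter(ast, microarray_clause(spec)))
        posthoc = {
            pid
            for pid in unfiltered
            if any(
                synth_store.concepts[c].entrez_gene_id in up_ids
                for c in synth_store.predications[pid].subject_cuis
            )
        }
        assert filtered.predication_ids == posthoc

    def test_measure_threshold_prunes_genes(self):
        spec = FilterSpec(
            experiment=_experiment(GENE_UP, GENE_DOWN),
            slot="either", direction="both", min_abs_measure=2.0,
        )
        assert spec.selected_genes() == [6622]

    def test_p_value_threshold(self):
        spec = FilterSpec(
            experiment=_experiment(GENE_UP, GENE_DOWN),
            slot="either", direction="both", max_p_value=0.005,
        )
        assert spec.selected_genes() == [6622]

    def test_empty_gene_set_is_an_explicit_error(self):
        spec = FilterSpec(experiment=_experiment(GENE_UP), slot="subject",
                          direction="down")
        with pytest.raises(EmptyGeneSetError):
            microarray_clause(spec)

    def test_invalid_slot_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(experiment=_experiment(GENE_UP), slot="verb")
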