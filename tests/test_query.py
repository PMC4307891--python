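"""The template query language: parser, index, Boolean search, vocabularies."""

import pytest

from predqa.model import PredicationStore
from predqa.query import (
    AndNode,
    NotNode,
    OrNode,
    QueryError,
    QueryParseError,
    ResultSet,
    TermClause,
    build_index,
    list_vocabularies,
    parse_query,
    search,
)

from oracles import brute_force_search, random_queries


def T(field, term, phrase=False):
    return TermClause(field=field, term=term, phrase=phrase)


class TestParser:
    def test_bare_words_become_implicit_and_over_all_fields(self):
        ast = parse_query("donepezil treats down syndrome")
        assert ast == AndNode(
            (T("ANY", "donepezil"), T("ANY", "treats"), T("ANY", "down"), T("ANY", "syndrome"))
        )

    def test_field_binds_exactly_one_token(self):
        ast = parse_query("sub_name:donepezil AND relation:treats AND obj_name:down syndrome")
        assert ast == AndNode(
            (
                T("sub_name", "donepezil"),
                T("relation", "treats"),
                T("obj_name", "down"),
                T("ANY", "syndrome"),  # trailing token falls back to all fields
            )
        )

    def test_capitalized_not_inside_conjunction(self):
        ast = parse_query("NOT sub_semtype:phsu AND relation:treats AND obj_name:Alzheimer")
        assert ast == AndNode(
            (
                NotNode(T("sub_semtype", "phsu")),
                T("relation", "treats"),
                T("obj_name", "alzheimer"),
            )
        )

    def test_field_distributes_over_group(self):
        ast = parse_query(
            "sub_semtype:(aapp OR gngm) AND relation:(CAUSES OR PREDISPOSES OR ASSOCIATED_WITH)"
        )
        assert ast == AndNode(
            (
                OrNode((T("sub_semtype", "aapp"), T("sub_semtype", "gngm"))),
                OrNode(
                    (
                        T("relation", "causes"),
                        T("relation", "predisposes"),
                        T("relation", "associated_with"),
                    )
                ),
            )
        )

    def test_lowercase_operators_are_search_terms(self):
        ast = parse_query("bed and breakfast")
        assert ast == AndNode((T("ANY", "bed"), T("ANY", "and"), T("ANY", "breakfast")))

    def test_terms_are_lowercased(self):
        assert parse_query("Donepezil") == T("ANY", "donepezil")

    def test_quoted_phrase(self):
        assert parse_query('"down syndrome"') == T("ANY", "down syndrome", phrase=True)
        assert parse_query('obj_name:"down syndrome"') == T(
            "obj_name", "down syndrome", phrase=True
        )

    def test_unknown_field_prefix_is_literal_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ast = parse_query("xyz:donepezil")
        assert ast == AndNode((T("ANY", "xyz"), T("ANY", "donepezil")))
        assert any("unknown field prefix" in r.message for r in caplog.records)

    @pytest.mark.parametrize(
        "bad",
        ["", "   ", "a AND", "OR a", "(a OR b", "a)", "sub_name:", 'a "unclosed'],
    )
    def test_syntax_errors(self, bad):
        with pytest.raises(QueryParseError):
            parse_query(bad)


class TestSearch:
    def test_empty_store_empty_index(self):
        idx = build_index(PredicationStore())
        assert idx.doc_count == 0
        assert len(search(idx, parse_query("anything"))) == 0

    def test_shared_subject_matches_both_relations(self, mini_store):
        idx = build_index(mini_store)
        results = search(idx, parse_query("donepezil treats"))
        names = {
            mini_store.concepts[mini_store.predications[pid].object_cuis[0]].preferred_name
            for pid in results
        }
        assert {"Alzheimer's Disease", "Schizophrenia", "Down Syndrome"} == names

    def test_arg_name_unions_subject_and_object(self, mini_store):
        idx = build_index(mini_store)
        assert len(search(idx, parse_query("arg_name:levodopa"))) == 1
        assert len(search(idx, parse_query("arg_name:parkinson"))) >= 2

    def test_no_match_gives_empty_result(self, mini_store):
        idx = build_index(mini_store)
        assert len(search(idx, parse_query("nonexistenttoken"))) == 0

    def test_not_restricted_to_positive_candidates(self, mini_store):
        idx = build_index(mini_store)
        treats_all = search(idx, parse_query("relation:treats"))
        no_donepezil = search(idx, parse_query("relation:treats NOT donepezil"))
        assert no_donepezil.predication_ids < treats_all.predication_ids
        for pid in no_donepezil:
            sub_names = [
                mini_store.concepts[c].preferred_name
                for c in mini_store.predications[pid].subject_cuis
            ]
            assert "Donepezil" not in sub_names

    def test_purely_negative_query_rejected(self, mini_store):
        idx = build_index(mini_store)
        with pytest.raises(QueryError):
            search(idx, parse_query("NOT donepezil"))
        with pytest.raises(QueryError):
            search(idx, parse_query("NOT donepezil NOT levodopa"))

    def test_entrez_field(self, mini_store):
        idx = build_index(mini_store)
        results = search(idx, parse_query("sub_entrez:6622"))
        assert len(results) == 2  # SNCA causes parkinson; SNCA+APP associated_with

    def test_phrase_requires_contiguity(self, mini_store):
        idx = build_index(mini_store)
        assert len(search(idx, parse_query('"parkinson disease"'))) >= 1
        assert len(search(idx, parse_query('"disease parkinson"'))) == 0

    def test_document_count_equals_relation_count(self, synth_store):
        assert build_index(synth_store).doc_count == len(synth_store.predications)


class TestQueryLaws:
    def test_case_insensitivity(self, mini_store):
        idx = build_index(mini_store)
        for q in ["Donepezil TREATS Down Syndrome", "donepezil treats down syndrome"]:
            assert search(idx, parse_query(q)).predication_ids == search(
                idx, parse_query(q.lower())
            ).predication_ids

    def test_implicit_and_equals_explicit_and(self, mini_store, synth_store):
        for store in (mini_store, synth_store):
            idx = build_index(store)
            some_tokens = ["treats", "isa", "dsyn", "phsu"]
            for a in some_tokens:
                for b in some_tokens:
                    implicit = search(idx, parse_query(f"{a} {b}"))
                    explicit = search(idx, parse_query(f"{a} AND {b}"))
                    assert implicit.predication_ids == explicit.predication_ids

    def test_field_monotonicity(self, synth_store):
        """sub_name:x <= arg_name:x <= unfielded x, for tokens in the corpus."""
        idx = build_index(synth_store)
        tokens = set()
        for p in list(synth_store.predications.values())[:50]:
            for cui in p.subject_cuis:
                tokens.update(
                    synth_store.concepts[cui].preferred_name.lower().split()
                )
        for tok in sorted(tokens)[:30]:
            sub = search(idx, parse_query(f"sub_name:{tok}")).predication_ids
            arg = search(idx, parse_query(f"arg_name:{tok}")).predication_ids
            anyf = search(idx, parse_query(tok)).predication_ids
            assert sub <= arg <= anyf

    def test_reindexing_is_idempotent(self, synth_store):
        idx1 = build_index(synth_store)
        idx2 = build_index(synth_store)
        for q in ["treats", "dsyn", "relation:isa", "phsu AND treats"]:
            ast = parse_query(q)
            assert search(idx1, ast).predication_ids == search(idx2, ast).predication_ids


class TestOracleEquivalence:
    def test_indexed_search_equals_brute_force_scan(self, big_synth_store):
        """200+ random Boolean queries agree with a linear document scan."""
        idx = build_index(big_synth_store)
        queries = random_queries(big_synth_store, n=220, seed=314)
        for ast in queries:
            assert search(idx, ast).predication_ids == brute_force_search(
                big_synth_store, ast
            ), f"disagreement on {ast}"

    def test_oracle_equivalence_on_mini_store(self, mini_store):
        idx = build_index(mini_store)
        for ast in random_queries(mini_store, n=60, seed=99):
            assert search(idx, ast).predication_ids == brute_force_search(mini_store, ast)


class TestVocabularies:
    def test_empty_store(self):
        listing = list_vocabularies(PredicationStore())
        assert listing.predicates == () and listing.semantic_types == ()

    def test_ranked_by_descending_instances(self, synth_store):
        listing = list_vocabularies(synth_store)
        inst_counts = [row[2] for row in listing.predicates]
        assert inst_counts == sorted(inst_counts, reverse=True)
        st_counts = [row[3] for row in listing.semantic_types]
        assert st_counts == sorted(st_counts, reverse=True)

    def test_counts_match_recount(self, mini_store):
        listing = list_vocabularies(mini_store)
        by_name = {name: (rels, insts) for name, rels, insts in listing.predicates}
        # Manual recount over the fixture: TREATS has 6 relations / 7 instances.
        assert by_name["TREATS"] == (6, 7)
        assert by_name["ISA"] == (2, 3)

    def test_full_names_resolved_from_vocabulary(self, mini_store):
        listing = list_vocabularies(mini_store)
        names = {abbr: full for abbr, full, _, _ in listing.semantic_types}
        assert names["dsyn"] == "Disease or Syndrome"


class TestResultSet:
    def test_counts_track_store_frequencies(self, mini_store):
        idx = build_index(mini_store)
        results = search(idx, parse_query("relation:treats"))
        for pid in results:
            assert results.counts[pid] == mini_store.predications[pid].instance_count
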