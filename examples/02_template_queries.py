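"""Pose template queries and read frequency-ranked relation answers.

Shows the query grammar on a small hand-built dementia corpus: bare terms
(implicit AND over all fields), explicit field binding, semantic-type
abbreviations, Boolean operators, and NOT within a conjunction.  Answers
are relations sorted by how many sentences assert them.
"""

from predqa import (
    Citation,
    Concept,
    PredicationStore,
    Sentence,
    build_index,
    parse_query,
    rank_relations,
    search,
)

DONEPEZIL = Concept("C0527316", "Donepezil", ("phsu", "orch"))
GALANTAMINE = Concept("C0016967", "Galantamine", ("phsu",))
ALZHEIMER = Concept("C0002395", "Alzheimer's Disease", ("dsyn",))
EXERCISE = Concept("C0015259", "Exercise", ("topp",))

store = PredicationStore()
serial = 0
for subject, n_sentences in [(DONEPEZIL, 3), (GALANTAMINE, 2), (EXERCISE, 1)]:
    for _ in range(n_sentences):
        serial += 1
        text = f"{subject.preferred_name} treats Alzheimer's Disease."
        store.add_instance(
            subjects=[subject], predicate="TREATS", objects=[ALZHEIMER],
            sentence=Sentence(f"s{serial}", 9_000_000 + serial, "abstract", text),
            citation=Citation(9_000_000 + serial),
            instance_id=f"i{serial}",
            subject_spans=[(0, len(subject.preferred_name))],
            object_spans=[(len(text) - 20, len(text) - 1)],
            predicate_span=(len(subject.preferred_name) + 1,
                            len(subject.preferred_name) + 7),
            subject_score=850, object_score=850, arg_predicate_distance=0,
        )

index = build_index(store)
for query_text in [
    "treats alzheimer",                       # bare terms, implicit AND
    "sub_name:donepezil relation:treats",     # explicit field binding
    "sub_semtype:phsu treats",                # semantic-type abbreviation
    "treats alzheimer NOT sub_semtype:topp",  # NOT inside the conjunction
]:
    results = search(index, parse_query(query_text))
    print(f"\nquery: {query_text!r} -> {len(results)} relations")
    for answer in rank_relations(results, store):
        print(f"  freq={answer.frequency}  "
              f"{' and '.join(answer.subjects)}-{answer.predicate}-"
              f"{' and '.join(answer.objects)}")
# freq counts supporting sentences: Donepezil (3) outranks Galantamine (2).
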