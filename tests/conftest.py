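"""Shared fixtures: a hand-built miniature corpus and seeded synthetic stores."""

from __future__ import annotations

import pytest

from predqa.model import Citation, Concept, PredicationStore, Sentence
from predqa.synth import SynthConfig, generate_synthetic_store

# -- concepts of the miniature hand-built corpus ----------------------------

LEVODOPA = Concept("C0023570", "Levodopa", ("phsu",))
PARKINSON = Concept("C0030567", "Parkinson Disease", ("dsyn",))
DONEPEZIL = Concept("C0527316", "Donepezil", ("phsu", "orch"))
ALZHEIMER = Concept("C0002395", "Alzheimer's Disease", ("dsyn",))
SCHIZOPHRENIA = Concept("C0036341", "Schizophrenia", ("mobd",))
DOWN_SYNDROME = Concept("C0013080", "Down Syndrome", ("dsyn",))
ANTIPSYCHOTIC = Concept("C0040615", "Antipsychotic Agents", ("phsu",))
CLOZAPINE = Concept("C0009079", "Clozapine", ("orch", "phsu"))
OLANZAPINE = Concept("C0171023", "Olanzapine", ("orch", "phsu"))
APP_GENE = Concept("C0002210", "APP gene", ("gngm",), entrez_gene_id=351)
SNCA_GENE = Concept("C1419287", "SNCA gene", ("gngm", "aapp"), entrez_gene_id=6622)

_PAPER_SENTENCE = (
    "Since the introduction of levodopa to treat Parkinson's disease (PD), "
    "several new therapies have been directed at improving symptom control, "
    "which can decline after a few years of levodopa therapy."
)


def add_simple_instance(
    store: PredicationStore,
    subjects,
    predicate: str,
    objects,
    pmid: int,
    serial: int,
    distance: int = 0,
    with_predicate_span: bool = True,
) -> None:
    """Compose a sentence embedding the arguments and register one instance."""
    indicator = "is a" if predicate == "ISA" else predicate.lower().replace("_", " ")
    sub_text = " and ".join(c.preferred_name for c in subjects)
    obj_text = " and ".join(c.preferred_name for c in objects)
    filler = "".join(f" the item{i}," for i in range(distance))
    text = f"{sub_text} {indicator}{filler} {obj_text}."
    sub_spans, cursor = [], 0
    for i, c in enumerate(subjects):
        if i:
            cursor += 5
        sub_spans.append((cursor, cursor + len(c.preferred_name)))
        cursor += len(c.preferred_name)
    pred_span = (cursor + 1, cursor + 1 + len(indicator))
    obj_start = len(text) - 1 - len(obj_text)
    obj_spans, cursor = [], obj_start
    for i, c in enumerate(objects):
        if i:
            cursor += 5
        obj_spans.append((cursor, cursor + len(c.preferred_name)))
        cursor += len(c.preferred_name)
    store.add_instance(
        subjects=subjects,
        predicate=predicate,
        objects=objects,
        sentence=Sentence(f"s{serial:04d}", pmid, "abstract", text),
        citation=Citation(pmid),
        instance_id=f"i{serial:04d}",
        subject_spans=sub_spans,
        object_spans=obj_spans,
        predicate_span=pred_span if with_predicate_span else None,
        subject_score=800,
        object_score=800,
        arg_predicate_distance=distance,
    )


@pytest.fixture
def mini_store() -> PredicationStore:
    """A hand-built corpus around dementia treatments and the ISA hierarchy."""
    store = PredicationStore()
    serial = 0

    def add(subjects, predicate, objects, pmid, **kw):
        nonlocal serial
        serial += 1
        add_simple_instance(store, subjects, predicate, objects, pmid, serial, **kw)

    # Levodopa TREATS Parkinson Disease, with the real surface sentence.
    text = _PAPER_SENTENCE
    store.add_instance(
        subjects=[LEVODOPA],
        predicate="TREATS",
        objects=[PARKINSON],
        sentence=Sentence("s_levo", 10641989, "abstract", text),
        citation=Citation(10641989),
        instance_id="i_levo",
        subject_spans=[(text.index("levodopa"), text.index("levodopa") + len("levodopa"))],
        object_spans=[
            (text.index("Parkinson's disease"), text.index("Parkinson's disease") + len("Parkinson's disease"))
        ],
        predicate_span=(text.index("treat "), text.index("treat ") + len("treat")),
        subject_score=861,
        object_score=861,
        arg_predicate_distance=0,
    )
    serial += 1

    add([DONEPEZIL], "TREATS", [ALZHEIMER], 11111001, distance=0)
    add([DONEPEZIL], "TREATS", [ALZHEIMER], 11111002, distance=2)
    add([DONEPEZIL], "TREATS", [SCHIZOPHRENIA], 11111003, distance=1)
    add([DONEPEZIL], "TREATS", [DOWN_SYNDROME], 11111004)
    add([CLOZAPINE], "ISA", [ANTIPSYCHOTIC], 11111005)
    add([CLOZAPINE], "ISA", [ANTIPSYCHOTIC], 11111006)
    add([OLANZAPINE], "ISA", [ANTIPSYCHOTIC], 11111007)
    add([ANTIPSYCHOTIC], "TREATS", [SCHIZOPHRENIA], 11111008)
    add([CLOZAPINE], "TREATS", [SCHIZOPHRENIA], 11111009, with_predicate_span=False)
    add([APP_GENE], "ASSOCIATED_WITH", [ALZHEIMER], 11111010)
    add([SNCA_GENE], "CAUSES", [PARKINSON], 11111011, distance=3)
    add([SNCA_GENE, APP_GENE], "ASSOCIATED_WITH", [PARKINSON], 11111012)
    return store


@pytest.fixture(scope="session")
def synth_store() -> PredicationStore:
    """Mid-size seeded synthetic corpus shared across tests (read-only)."""
    return generate_synthetic_store(SynthConfig(seed=20240612))


@pytest.fixture(scope="session")
def big_synth_store() -> PredicationStore:
    """Larger synthetic corpus for the oracle-equivalence battery."""
    return generate_synthetic_store(
        SynthConfig(
            n_concepts=600,
            n_relations=400,
            n_instances=1600,
            isa_tree_depth=2,
            isa_branching=4,
            n_isa_roots=3,
            seed=977,
        )
    )
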