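"""Domain types and the in-memory predication store.

A *predication* is a subject-PREDICATE-object assertion (e.g. "Levodopa
TREATS Parkinson Disease") aggregated over the corpus; a *predication
instance* is one occurrence of it in one sentence, carrying character spans
for highlighting, extraction-confidence scores, and the argument-predicate
distance (number of noun phrases between an argument and the indicator
word) used for ranking instances.

The :class:`PredicationStore` holds the whole corpus — concepts, citations,
sentences, predications, instances — plus the ISA (hyponymy) links derived
from predications whose predicate is ISA, and the two controlled
vocabularies.  ``validate_store`` checks every type invariant and all
referential integrity, returning violations as data rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import vocab

logger = logging.getLogger(__name__)

__all__ = [
    "Concept",
    "Citation",
    "Sentence",
    "Predication",
    "PredicationInstance",
    "PredicationStore",
    "Violation",
    "RelationIdentity",
    "relation_identity",
    "validate_store",
]

SECTIONS = ("title", "abstract")


@dataclass(frozen=True)
class Concept:
    """A biomedical concept: CUI, preferred name, semantic types, gene id.

    ``cui`` is the canonical key ("C" + 7 digits for UMLS-derived data; any
    unique token for synthetic corpora).  ``entrez_gene_id`` is set for gene
    concepts and is the key the microarray filter matches on.
    """

    cui: str
    preferred_name: str
    semantic_types: tuple[str, ...]
    entrez_gene_id: Optional[int] = None


@dataclass(frozen=True)
class Citation:
    pmid: int
    pub_date: Optional[str] = None  # ISO date


@dataclass(frozen=True)
class Sentence:
    sentence_id: str
    pmid: int
    section: str  # "title" | "abstract"
    text: str


@dataclass(frozen=True)
class Predication:
    """An aggregated relation: subject concept(s), predicate, object concept(s).

    Either argument may hold more than one concept (coordinated noun
    phrases).  ``instance_count`` must equal the number of instance records
    referencing this predication.
    """

    predication_id: str
    subject_cuis: tuple[str, ...]
    predicate: str
    object_cuis: tuple[str, ...]
    instance_count: int


Span = tuple[int, int]  # 0-based, half-open [start, end)


@dataclass(frozen=True)
class PredicationInstance:
    """One extraction of a predication from one sentence.

    Spans are 0-based half-open character intervals into the sentence text.
    ``predicate_span`` may be absent (indicators such as prepositions are
    not always localized).  ``arg_predicate_distance`` counts noun phrases
    between argument and indicator; lower distances correlate with correct
    extractions, so instances are ranked ascending by it.
    """

    instance_id: str
    predication_id: str
    sentence_id: str
    subject_spans: tuple[Span, ...]
    object_spans: tuple[Span, ...]
    predicate_span: Optional[Span]
    subject_score: int
    object_score: int
    arg_predicate_distance: int


RelationIdentity = tuple[tuple[str, ...], str, tuple[str, ...]]


def relation_identity(
    subjects: Iterable[str] | Iterable[Concept],
    predicate: str,
    objects: Iterable[str] | Iterable[Concept],
) -> RelationIdentity:
    """Canonical identity key of a relation.

    Two relations are the same iff they have the same subject CUI set, the
    same predicate, and the same object CUI set; argument order within a
    list never matters, but subject/object direction does.  The key is a
    hashable tuple, stable across runs.

    Raises ``ValueError`` on an empty argument list or an empty predicate.
    """
    subs = tuple(sorted(c.cui if isinstance(c, Concept) else str(c) for c in subjects))
    objs = tuple(sorted(c.cui if isinstance(c, Concept) else str(c) for c in objects))
    pred = str(predicate).upper()
    if not subs or not objs:
        raise ValueError("relation identity requires at least one subject and one object")
    if not pred:
        raise ValueError("relation identity requires a predicate")
    return (subs, pred, objs)


def identity_token(ident: RelationIdentity) -> str:
    """Deterministic printable id for a relation identity (used as predication_id)."""
    subs, pred, objs = ident
    return "|".join(subs) + "=" + pred + "=" + "|".join(objs)


@dataclass
class PredicationStore:
    """The queryable corpus of predications and their provenance.

    ``isa_links`` maps a narrower concept's CUI to the set of broader CUIs
    it ISA-links to (derived from ISA predications; the basis of argument
    expansion).  ``skipped_rows`` surfaces how many malformed input rows an
    ingest dropped.
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    citations: dict[int, Citation] = field(default_factory=dict)
    sentences: dict[str, Sentence] = field(default_factory=dict)
    predications: dict[str, Predication] = field(default_factory=dict)
    instances: dict[str, PredicationInstance] = field(default_factory=dict)
    semantic_type_vocab: dict[str, vocab.SemanticTypeEntry] = field(
        default_factory=vocab.semantic_type_vocabulary
    )
    predicate_vocab: dict[str, vocab.PredicateEntry] = field(
        default_factory=vocab.predicate_vocabulary
    )
    skipped_rows: int = 0

    # -- derived views -------------------------------------------------

    @property
    def isa_links(self) -> dict[str, set[str]]:
        """narrower-CUI -> set of broader CUIs, from ISA predications."""
        links: dict[str, set[str]] = {}
        for pred in self.predications.values():
            if pred.predicate == "ISA":
                for sub in pred.subject_cuis:
                    for obj in pred.object_cuis:
                        links.setdefault(sub, set()).add(obj)
        return links

    def isa_children(self, cui: str) -> list[str]:
        """CUIs of concepts ISA-linked to ``cui`` as narrower concepts."""
        out = []
        for pred in self.predications.values():
            if pred.predicate == "ISA" and cui in pred.object_cuis:
                out.extend(c for c in pred.subject_cuis if c != cui)
        return sorted(set(out))

    def isa_instance_count(self, narrower: str, broader: str) -> int:
        """Instance count of the ISA predication linking narrower to broader (0 if none)."""
        best = 0
        for pred in self.predications.values():
            if (
                pred.predicate == "ISA"
                and narrower in pred.subject_cuis
                and broader in pred.object_cuis
            ):
                best = max(best, pred.instance_count)
        return best

    def instances_of(self, predication_id: str) -> list[PredicationInstance]:
        return [i for i in self.instances.values() if i.predication_id == predication_id]

    # -- mutation ------------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        existing = self.concepts.get(concept.cui)
        if existing is not None and existing != concept:
            logger.warning("concept %s re-added with differing fields; keeping first", concept.cui)
            return
        self.concepts[concept.cui] = concept

    def add_instance(
        self,
        subjects: Sequence[Concept],
        predicate: str,
        objects: Sequence[Concept],
        sentence: Sentence,
        citation: Citation,
        instance_id: str,
        subject_spans: Sequence[Span],
        object_spans: Sequence[Span],
        predicate_span: Optional[Span],
        subject_score: int,
        object_score: int,
        arg_predicate_distance: int,
    ) -> PredicationInstance:
        """Register one predication instance, creating/aggregating the relation.

        Concepts, citation and sentence are deduplicated by their keys; the
        owning predication is found by :func:`relation_identity` and its
        instance_count incremented (never read from input).
        """
        predicate = predicate.upper()
        if predicate not in self.predicate_vocab:
            logger.warning("unknown predicate %r accepted into store", predicate)
            self.predicate_vocab[predicate] = vocab.PredicateEntry(predicate)
        for c in list(subjects) + list(objects):
            self.add_concept(c)
        if citation.pmid not in self.citations:
            self.citations[citation.pmid] = citation
        if sentence.sentence_id not in self.sentences:
            self.sentences[sentence.sentence_id] = sentence
        ident = relation_identity(subjects, predicate, objects)
        pid = identity_token(ident)
        prev = self.predications.get(pid)
        if prev is None:
            self.predications[pid] = Predication(
                predication_id=pid,
                subject_cuis=ident[0],
                predicate=predicate,
                object_cuis=ident[2],
                instance_count=1,
            )
        else:
            self.predications[pid] = Predication(
                predication_id=pid,
                subject_cuis=prev.subject_cuis,
                predicate=prev.predicate,
                object_cuis=prev.object_cuis,
                instance_count=prev.instance_count + 1,
            )
        inst = PredicationInstance(
            instance_id=instance_id,
            predication_id=pid,
            sentence_id=sentence.sentence_id,
            subject_spans=tuple((int(a), int(b)) for a, b in subject_spans),
            object_spans=tuple((int(a), int(b)) for a, b in object_spans),
            predicate_span=None if predicate_span is None else (int(predicate_span[0]), int(predicate_span[1])),
            subject_score=int(subject_score),
            object_score=int(object_score),
            arg_predicate_distance=int(arg_predicate_distance),
        )
        if inst.instance_id in self.instances:
            raise ValueError(f"duplicate instance id {inst.instance_id!r}")
        self.instances[inst.instance_id] = inst
        return inst


@dataclass(frozen=True)
class Violation:
    """One integrity violation: the offending record and the broken rule."""

    record: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.record}: {self.rule}"


def _check_spans(spans: Iterable[Span], text_len: int) -> bool:
    return all(0 <= a <= b <= text_len for a, b in spans)


def validate_store(store: PredicationStore) -> list[Violation]:
    """Check every invariant and referential-integrity rule of a store.

    Returns an empty list iff the store is fully consistent.  Violations are
    returned as data (never raised): real extraction output contains
    irregularities and callers decide how strict to be.
    """
    out: list[Violation] = []

    for cui, c in store.concepts.items():
        if cui != c.cui:
            out.append(Violation(f"concept {cui}", "keyed under a different cui"))
        if not c.preferred_name:
            out.append(Violation(f"concept {cui}", "empty preferred_name"))
        if not c.semantic_types:
            out.append(Violation(f"concept {cui}", "no semantic types"))
        for st in c.semantic_types:
            if st not in store.semantic_type_vocab:
                out.append(Violation(f"concept {cui}", f"unknown semantic type {st!r}"))
        if c.entrez_gene_id is not None:
            if c.entrez_gene_id <= 0:
                out.append(Violation(f"concept {cui}", "entrez_gene_id not positive"))
            if not (set(c.semantic_types) & vocab.GENE_SEMANTIC_TYPES):
                # Real data may attach gene ids to concepts typed otherwise.
                logger.warning("concept %s has entrez id but no gene semantic type", cui)

    for pmid, cit in store.citations.items():
        if pmid != cit.pmid:
            out.append(Violation(f"citation {pmid}", "keyed under a different pmid"))
        if cit.pmid <= 0:
            out.append(Violation(f"citation {pmid}", "pmid not positive"))

    for sid, s in store.sentences.items():
        if sid != s.sentence_id:
            out.append(Violation(f"sentence {sid}", "keyed under a different id"))
        if s.section not in SECTIONS:
            out.append(Violation(f"sentence {sid}", f"bad section {s.section!r}"))
        if not s.text:
            out.append(Violation(f"sentence {sid}", "empty text"))
        if s.pmid not in store.citations:
            out.append(Violation(f"sentence {sid}", f"unknown pmid {s.pmid}"))

    seen_idents: dict[RelationIdentity, str] = {}
    counts: dict[str, int] = {pid: 0 for pid in store.predications}
    for pid, p in store.predications.items():
        if pid != p.predication_id:
            out.append(Violation(f"predication {pid}", "keyed under a different id"))
        if not p.subject_cuis or not p.object_cuis:
            out.append(Violation(f"predication {pid}", "empty argument list"))
            continue
        if p.predicate not in store.predicate_vocab:
            out.append(Violation(f"predication {pid}", f"unknown predicate {p.predicate!r}"))
        for cui in p.subject_cuis + p.object_cuis:
            if cui not in store.concepts:
                out.append(Violation(f"predication {pid}", f"unknown concept {cui}"))
        ident = relation_identity(p.subject_cuis, p.predicate, p.object_cuis)
        if ident in seen_idents:
            out.append(
                Violation(f"predication {pid}", f"duplicate identity with {seen_idents[ident]}")
            )
        seen_idents[ident] = pid

    for iid, inst in store.instances.items():
        if iid != inst.instance_id:
            out.append(Violation(f"instance {iid}", "keyed under a different id"))
        if inst.predication_id not in store.predications:
            out.append(Violation(f"instance {iid}", f"unknown predication {inst.predication_id}"))
        else:
            counts[inst.predication_id] += 1
        sent = store.sentences.get(inst.sentence_id)
        if sent is None:
            out.append(Violation(f"instance {iid}", f"unknown sentence {inst.sentence_id}"))
        else:
            all_spans = list(inst.subject_spans) + list(inst.object_spans)
            if inst.predicate_span is not None:
                all_spans.append(inst.predicate_span)
            if not _check_spans(all_spans, len(sent.text)):
                out.append(Violation(f"instance {iid}", "span outside sentence bounds"))
        if inst.arg_predicate_distance < 0:
            out.append(Violation(f"instance {iid}", "negative argument-predicate distance"))
        if inst.subject_score < 0 or inst.object_score < 0:
            out.append(Violation(f"instance {iid}", "negative extraction score"))

    for pid, p in store.predications.items():
        if pid in counts and p.instance_count != counts[pid]:
            out.append(
                Violation(
                    f"predication {pid}",
                    f"instance_count {p.instance_count} != {counts[pid]} instance records",
                )
            )

    # Conservation over the whole store.
    total = sum(p.instance_count for p in store.predications.values())
    if total != len(store.instances):
        out.append(
            Violation(
                "store",
                f"sum of instance_count {total} != {len(store.instances)} instance records",
            )
        )
    return out
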