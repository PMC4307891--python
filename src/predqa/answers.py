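"""Answer assembly: ranked relations, ordered instances, highlighting.

Answers are presented top-down: first the matching relations sorted by
descending evidence frequency (number of instances), then, on demand, the
instances of one relation as sentences ordered by ascending
argument-predicate distance (instances with fewer noun phrases between
argument and indicator are more likely to be correctly extracted), each
with character spans for highlighting the subject, predicate and object
surface text and a PubMed link for the source citation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import PredicationInstance, PredicationStore, Sentence, Span
from .query import ResultSet

__all__ = [
    "RankedAnswer",
    "rank_relations",
    "list_instances",
    "HighlightSpan",
    "RenderedInstance",
    "render_highlights",
    "PUBMED_URL_TEMPLATE",
]

PUBMED_URL_TEMPLATE = "https://pubmed.ncbi.nlm.nih.gov/{pmid}/"


@dataclass(frozen=True)
class RankedAnswer:
    """One answer relation with display names and its evidence frequency."""

    predication_id: str
    subjects: tuple[str, ...]
    predicate: str
    objects: tuple[str, ...]
    frequency: int  # number of instances of this relation


def rank_relations(results: ResultSet, store: PredicationStore) -> list[RankedAnswer]:
    """Order answer relations by descending frequency.

    Ties break ascending by (subject names, predicate, object names), so
    the order is total and deterministic for any result set.
    """
    answers = []
    for pid in results:
        pred = store.predications[pid]
        answers.append(
            RankedAnswer(
                predication_id=pid,
                subjects=tuple(store.concepts[c].preferred_name for c in pred.subject_cuis),
                predicate=pred.predicate,
                objects=tuple(store.concepts[c].preferred_name for c in pred.object_cuis),
                frequency=pred.instance_count,
            )
        )
    answers.sort(key=lambda a: (-a.frequency, a.subjects, a.predicate, a.objects))
    return answers


def list_instances(store: PredicationStore, predication_id: str) -> list[PredicationInstance]:
    """Instances of one relation, ascending by argument-predicate distance.

    Ties break by (pmid, sentence id, instance id).  Raises ``KeyError``
    for an unknown predication.
    """
    if predication_id not in store.predications:
        raise KeyError(f"unknown predication {predication_id!r}")
    instances = store.instances_of(predication_id)
    instances.sort(
        key=lambda i: (
            i.arg_predicate_distance,
            store.sentences[i.sentence_id].pmid,
            i.sentence_id,
            i.instance_id,
        )
    )
    return instances


@dataclass(frozen=True)
class HighlightSpan:
    """A highlighted interval of the sentence, tagged with its role."""

    role: str  # "subject" | "predicate" | "object"
    start: int
    end: int


@dataclass(frozen=True)
class RenderedInstance:
    """A sentence ready for display: text, highlight spans, PubMed link."""

    text: str
    spans: tuple[HighlightSpan, ...]
    pmid: int
    section: str
    link: str
    distance: int
    subject_score: int
    object_score: int


def _spans_for(role: str, spans: tuple[Span, ...]) -> list[HighlightSpan]:
    return [HighlightSpan(role=role, start=a, end=b) for a, b in spans]


def render_highlights(
    instance: PredicationInstance, sentence: Sentence, predication_id: Optional[str] = None
) -> RenderedInstance:
    """Resolve an instance's spans against its sentence for display.

    The highlighted surface text may differ from the concepts' preferred
    names (abbreviations like "AD" for Alzheimer's Disease; prepositions
    as treatment indicators); spans point at what was actually written.
    The predicate role is absent when the instance carries no indicator
    span.  Raises ``ValueError`` if any span exceeds the sentence (which
    signals a corrupt store).
    """
    spans = _spans_for("subject", instance.subject_spans)
    if instance.predicate_span is not None:
        spans.extend(_spans_for("predicate", (instance.predicate_span,)))
    spans.extend(_spans_for("object", instance.object_spans))
    for hs in spans:
        if not (0 <= hs.start <= hs.end <= len(sentence.text)):
            raise ValueError(
                f"instance {instance.instance_id}: span ({hs.start}, {hs.end}) "
                f"outside sentence of length {len(sentence.text)}"
            )
    return RenderedInstance(
        text=sentence.text,
        spans=tuple(sorted(spans, key=lambda s: (s.start, s.end, s.role))),
        pmid=sentence.pmid,
        section=sentence.section,
        link=PUBMED_URL_TEMPLATE.format(pmid=sentence.pmid),
        distance=instance.arg_predicate_distance,
        subject_score=instance.subject_score,
        object_score=instance.object_score,
    )


def answer_to_dict(answer: RankedAnswer, store: PredicationStore) -> dict:
    """JSON form of one answer with its ordered, rendered instances."""
    rendered = []
    for inst in list_instances(store, answer.predication_id):
        sent = store.sentences[inst.sentence_id]
        ri = render_highlights(inst, sent)
        rendered.append(
            {
                "pmid": ri.pmid,
                "section": ri.section,
                "text": ri.text,
                "spans": [
                    {"role": s.role, "start": s.start, "end": s.end} for s in ri.spans
                ],
                "distance": ri.distance,
                "scores": {"subject": ri.subject_score, "object": ri.object_score},
                "link": ri.link,
            }
        )
    return {
        "subjects": list(answer.subjects),
        "predicate": answer.predicate,
        "objects": list(answer.objects),
        "frequency": answer.frequency,
        "instances": rendered,
    }
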