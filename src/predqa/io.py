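"""Readers and writers for the three tabular interchange formats.

* Predication tables: a flat one-row-per-instance TSV (mirroring the shape
  of SemMedDB's PREDICATION table joined with sentence and offset data).
  The store's relational view — deduplicated concepts, citations,
  sentences, relations aggregated by identity — is rebuilt on read;
  instance counts are always computed, never read.
* Gene lists: a TSV of differentially expressed genes (Entrez id, symbol,
  up/down direction, signed effect measure, optional p-value).
* Vote logs: JSON-lines records of per-instance annotation votes.

Multi-concept arguments are encoded with a ``|`` list separator; nested
lists (one concept's several semantic types) use ``,`` inside the ``|``
items.  Spans are ``start-end`` (0-based half-open).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .evalstats import EvaluationLog, EvaluationVote, OUTCOMES
from .model import (
    Citation,
    Concept,
    PredicationStore,
    Sentence,
    Span,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TableDialect",
    "NATIVE_DIALECT",
    "GeneEntry",
    "Experiment",
    "read_predication_table",
    "write_predication_table",
    "read_gene_list",
    "write_gene_list",
    "read_vote_log",
    "write_vote_log",
]

# Logical column names of the predication table.
LOGICAL_COLUMNS = (
    "instance_id",
    "sentence_id",
    "pmid",
    "pub_date",
    "section",
    "sentence_text",
    "predicate",
    "subject_cuis",
    "subject_names",
    "subject_semtypes",
    "subject_entrez",
    "object_cuis",
    "object_names",
    "object_semtypes",
    "object_entrez",
    "subject_spans",
    "predicate_span",
    "object_spans",
    "subject_score",
    "object_score",
    "distance",
)

OPTIONAL_COLUMNS = frozenset({"pub_date", "predicate_span", "subject_entrez", "object_entrez"})


@dataclass(frozen=True)
class TableDialect:
    """How a predication TSV maps onto the logical columns.

    ``columns`` maps logical names to the file's header names; identity by
    default.  ``list_sep`` separates multi-concept argument fields and must
    be a single character.
    """

    columns: dict[str, str] = field(default_factory=dict)
    list_sep: str = "|"
    inner_sep: str = ","
    encoding: str = "utf-8"
    header: bool = True

    def __post_init__(self) -> None:
        if len(self.list_sep) != 1:
            raise ValueError("list separator must be a single character")
        unknown = set(self.columns) - set(LOGICAL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown logical columns in dialect: {sorted(unknown)}")

    def physical(self, logical: str) -> str:
        return self.columns.get(logical, logical)


NATIVE_DIALECT = TableDialect()


# ---------------------------------------------------------------------------
# Predication tables


def _parse_span(text: str) -> Span:
    a, _, b = text.partition("-")
    start, end = int(a), int(b)
    if start < 0 or end < start:
        raise ValueError(f"malformed span {text!r}")
    return (start, end)


def _parse_spans(text: str, sep: str) -> tuple[Span, ...]:
    return tuple(_parse_span(t) for t in text.split(sep) if t)


def _split(text: str, sep: str) -> list[str]:
    return text.split(sep) if text else []


def _row_concepts(
    cuis: str, names: str, semtypes: str, entrez: str, sep: str, inner: str
) -> list[Concept]:
    cui_l = _split(cuis, sep)
    name_l = _split(names, sep)
    st_l = _split(semtypes, sep)
    ez_l = _split(entrez, sep) if entrez else [""] * len(cui_l)
    if not (len(cui_l) == len(name_l) == len(st_l)) or len(ez_l) != len(cui_l):
        raise ValueError("argument list fields have unequal lengths")
    out = []
    for cui, name, sts, ez in zip(cui_l, name_l, st_l, ez_l):
        if not cui:
            raise ValueError("empty cui in argument list")
        out.append(
            Concept(
                cui=cui,
                preferred_name=name,
                semantic_types=tuple(t.lower() for t in sts.split(inner) if t),
                entrez_gene_id=int(ez) if ez else None,
            )
        )
    return out


def read_predication_table(
    path: Union[str, Path], dialect: TableDialect = NATIVE_DIALECT
) -> PredicationStore:
    """Load a one-row-per-instance predication TSV into a store.

    Concepts, sentences and citations are deduplicated; predications are
    aggregated by relation identity with computed instance counts.  Rows
    with malformed or out-of-bounds spans are skipped with a logged
    warning; the skip count is surfaced as ``store.skipped_rows``.

    Raises ``ValueError`` if a required column is missing.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        keep_default_na=False,
        encoding=dialect.encoding,
        header=0 if dialect.header else None,
    )
    if not dialect.header:
        frame.columns = [dialect.physical(c) for c in LOGICAL_COLUMNS[: len(frame.columns)]]
    missing = [
        c
        for c in LOGICAL_COLUMNS
        if c not in OPTIONAL_COLUMNS and dialect.physical(c) not in frame.columns
    ]
    if missing:
        raise ValueError(f"predication table missing required columns: {missing}")

    def col(row: pd.Series, logical: str) -> str:
        name = dialect.physical(logical)
        return str(row[name]) if name in frame.columns else ""

    store = PredicationStore()
    for idx, row in frame.iterrows():
        try:
            subjects = _row_concepts(
                col(row, "subject_cuis"),
                col(row, "subject_names"),
                col(row, "subject_semtypes"),
                col(row, "subject_entrez"),
                dialect.list_sep,
                dialect.inner_sep,
            )
            objects = _row_concepts(
                col(row, "object_cuis"),
                col(row, "object_names"),
                col(row, "object_semtypes"),
                col(row, "object_entrez"),
                dialect.list_sep,
                dialect.inner_sep,
            )
            text = col(row, "sentence_text")
            subject_spans = _parse_spans(col(row, "subject_spans"), dialect.list_sep)
            object_spans = _parse_spans(col(row, "object_spans"), dialect.list_sep)
            pspan_text = col(row, "predicate_span")
            predicate_span = _parse_span(pspan_text) if pspan_text else None
            all_spans = list(subject_spans) + list(object_spans) + (
                [predicate_span] if predicate_span else []
            )
            if any(end > len(text) for _, end in all_spans):
                raise ValueError("span outside sentence bounds")
            sentence = Sentence(
                sentence_id=col(row, "sentence_id").lower(),
                pmid=int(col(row, "pmid")),
                section=col(row, "section").lower(),
                text=text,
            )
            pub_date = col(row, "pub_date") or None
            store.add_instance(
                subjects=subjects,
                predicate=col(row, "predicate"),
                objects=objects,
                sentence=sentence,
                citation=Citation(pmid=sentence.pmid, pub_date=pub_date),
                instance_id=col(row, "instance_id").lower(),
                subject_spans=subject_spans,
                object_spans=object_spans,
                predicate_span=predicate_span,
                subject_score=int(col(row, "subject_score")),
                object_score=int(col(row, "object_score")),
                arg_predicate_distance=int(col(row, "distance")),
            )
        except (ValueError, KeyError) as exc:
            logger.warning("skipping row %s: %s", idx, exc)
            store.skipped_rows += 1
    return store


def _fmt_spans(spans: tuple[Span, ...], sep: str) -> str:
    return sep.join(f"{a}-{b}" for a, b in spans)


def write_predication_table(
    store: PredicationStore, path: Union[str, Path], dialect: TableDialect = NATIVE_DIALECT
) -> None:
    """Write a store back to the flat TSV; deterministic row and column order.

    The output is byte-identical for equal stores (rows sorted by instance
    id), making snapshots directly comparable.
    """
    rows = []
    for iid in sorted(store.instances):
        inst = store.instances[iid]
        pred = store.predications[inst.predication_id]
        sent = store.sentences[inst.sentence_id]
        cit = store.citations[sent.pmid]
        subs = [store.concepts[c] for c in pred.subject_cuis]
        objs = [store.concepts[c] for c in pred.object_cuis]
        sep, inner = dialect.list_sep, dialect.inner_sep
        rows.append(
            {
                dialect.physical("instance_id"): inst.instance_id,
                dialect.physical("sentence_id"): sent.sentence_id,
                dialect.physical("pmid"): str(sent.pmid),
                dialect.physical("pub_date"): cit.pub_date or "",
                dialect.physical("section"): sent.section,
                dialect.physical("sentence_text"): sent.text,
                dialect.physical("predicate"): pred.predicate,
                dialect.physical("subject_cuis"): sep.join(c.cui for c in subs),
                dialect.physical("subject_names"): sep.join(c.preferred_name for c in subs),
                dialect.physical("subject_semtypes"): sep.join(
                    inner.join(c.semantic_types) for c in subs
                ),
                dialect.physical("subject_entrez"): sep.join(
                    "" if c.entrez_gene_id is None else str(c.entrez_gene_id) for c in subs
                ),
                dialect.physical("object_cuis"): sep.join(c.cui for c in objs),
                dialect.physical("object_names"): sep.join(c.preferred_name for c in objs),
                dialect.physical("object_semtypes"): sep.join(
                    inner.join(c.semantic_types) for c in objs
                ),
                dialect.physical("object_entrez"): sep.join(
                    "" if c.entrez_gene_id is None else str(c.entrez_gene_id) for c in objs
                ),
                dialect.physical("subject_spans"): _fmt_spans(inst.subject_spans, sep),
                dialect.physical("predicate_span"): (
                    "" if inst.predicate_span is None else _fmt_spans((inst.predicate_span,), sep)
                ),
                dialect.physical("object_spans"): _fmt_spans(inst.object_spans, sep),
                dialect.physical("subject_score"): str(inst.subject_score),
                dialect.physical("object_score"): str(inst.object_score),
                dialect.physical("distance"): str(inst.arg_predicate_distance),
            }
        )
    columns = [dialect.physical(c) for c in LOGICAL_COLUMNS]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False, encoding=dialect.encoding, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene lists (microarray experiments)


@dataclass(frozen=True)
class GeneEntry:
    """One differentially expressed gene in an experiment."""

    entrez_id: int
    symbol: str
    direction: str  # "up" | "down"
    measure: float  # signed effect measure (e.g. log2 fold change)
    p_value: Optional[float] = None


@dataclass(frozen=True)
class Experiment:
    """A named microarray gene list with up/down directions and measures."""

    name: str
    genes: tuple[GeneEntry, ...] = ()
    description: str = ""
    geo_id: Optional[str] = None

    def subset(self, direction: str) -> tuple[GeneEntry, ...]:
        """Genes with the given direction ("up", "down" or "both")."""
        direction = direction.lower()
        if direction == "both":
            return self.genes
        if direction not in ("up", "down"):
            raise ValueError(f"unknown direction {direction!r}")
        return tuple(g for g in self.genes if g.direction == direction)


def read_gene_list(path: Union[str, Path], experiment_name: str) -> Experiment:
    """Read a gene-list TSV (entrez_id, symbol, direction, measure[, p_value]).

    Direction tokens are case-folded; duplicate Entrez ids are rejected.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["entrez_id", "symbol", "direction", "measure"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"gene list missing required columns: {missing}")
    genes: list[GeneEntry] = []
    seen: set[int] = set()
    for _, row in frame.iterrows():
        entrez = int(row["entrez_id"])
        if entrez in seen:
            raise ValueError(f"duplicate entrez_id {entrez}")
        seen.add(entrez)
        direction = str(row["direction"]).strip().lower()
        if direction not in ("up", "down"):
            raise ValueError(f"unknown direction token {row['direction']!r}")
        p_raw = str(row["p_value"]).strip() if "p_value" in frame.columns else ""
        genes.append(
            GeneEntry(
                entrez_id=entrez,
                symbol=str(row["symbol"]),
                direction=direction,
                measure=float(row["measure"]),
                p_value=float(p_raw) if p_raw else None,
            )
        )
    return Experiment(name=experiment_name, genes=tuple(genes))


def write_gene_list(experiment: Experiment, path: Union[str, Path]) -> None:
    frame = pd.DataFrame(
        [
            {
                "entrez_id": g.entrez_id,
                "symbol": g.symbol,
                "direction": g.direction,
                "measure": g.measure,
                "p_value": "" if g.p_value is None else g.p_value,
            }
            for g in experiment.genes
        ],
        columns=["entrez_id", "symbol", "direction", "measure", "p_value"],
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Vote logs (JSON-lines)


def read_vote_log(path: Union[str, Path]) -> EvaluationLog:
    """Read a JSONL vote log; last vote wins on duplicate (user, instance)."""
    log = EvaluationLog()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            outcome = str(rec["outcome"]).strip().lower()
            if outcome not in OUTCOMES:
                raise ValueError(f"line {lineno}: unknown outcome {rec['outcome']!r}")
            log.record(
                EvaluationVote(
                    user_id=str(rec["user"]),
                    instance_id=str(rec["instance_id"]),
                    outcome=outcome,
                    timestamp=str(rec.get("timestamp", "")),
                )
            )
    return log


def write_vote_log(log: EvaluationLog, path: Union[str, Path]) -> None:
    """Write a vote log as JSONL, sorted by (user, instance) for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        for vote in sorted(log.votes(), key=lambda v: (v.user_id, v.instance_id)):
            fh.write(
                json.dumps(
                    {
                        "user": vote.user_id,
                        "instance_id": vote.instance_id,
                        "outcome": vote.outcome,
                        "timestamp": vote.timestamp,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
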