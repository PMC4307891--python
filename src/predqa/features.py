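"""Argument expansion, faceting and the microarray gene-list filter.

All three features are implemented as *query rewriting*: they take a parsed
query and produce a new query, so retrieval stays pure Boolean and every
feature composes with every other.

* :func:`expand_argument` widens a single-word argument clause with the
  ISA-narrower concepts (hyponyms) of every concept whose name contains
  that word, capped at a fixed number — asking about "antipsychotic" then
  also finds relations about clozapine, olanzapine, and so on.
* :func:`compute_facets` aggregates a result set into top-N subjects,
  relations and objects (counted by the number of answer relations each
  appears in); :func:`refine_with_facet` conjoins a selected facet value
  back onto the query.
* :func:`microarray_clause` turns a differential-expression gene list into
  an OR over Entrez-id clauses so that questions can be restricted to the
  up- and/or down-regulated genes of an experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .io import Experiment
from .model import PredicationStore
from .query import (
    ANY,
    AndNode,
    NotNode,
    OrNode,
    QueryNode,
    ResultSet,
    TermClause,
    tokenize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpansionSpec",
    "expand_argument",
    "FacetEntry",
    "Facets",
    "compute_facets",
    "refine_with_facet",
    "FilterSpec",
    "microarray_clause",
    "apply_filter",
    "EmptyGeneSetError",
]


# ---------------------------------------------------------------------------
# Argument expansion


@dataclass(frozen=True)
class ExpansionSpec:
    """How to expand one argument clause with narrower concepts.

    ``seed_word`` must be a single word: it selects every concept whose
    preferred name contains it as a whole (case-folded) token, and those
    concepts' ISA-narrower descendants down to ``depth`` levels are added.
    At most ``cap`` narrower concepts are used, preferring well-attested
    hyponyms (descending ISA instance count, ties by CUI).
    """

    field: str  # "arg_name" | "sub_name" | "obj_name"
    seed_word: str
    cap: int = 100
    depth: int = 1

    def __post_init__(self) -> None:
        if self.field not in ("arg_name", "sub_name", "obj_name"):
            raise ValueError(f"expansion requires an explicit name field, not {self.field!r}")
        if len(self.seed_word.split()) != 1 or not self.seed_word.strip():
            raise ValueError("only a single word can be used to specify concepts to expand")
        if self.cap < 1 or self.depth < 1:
            raise ValueError("cap and depth must be positive")


def _matching_seed_concepts(store: PredicationStore, seed_word: str) -> list[str]:
    """CUIs of concepts whose preferred name contains the word as a whole token."""
    want = seed_word.lower()
    return sorted(
        cui
        for cui, c in store.concepts.items()
        if want in tokenize(c.preferred_name)
    )


def select_narrower_concepts(
    store: PredicationStore, seed_word: str, cap: int, depth: int
) -> list[str]:
    """The capped, ordered list of narrower-concept CUIs for a seed word.

    Breadth-first over ISA links from every seed-matching concept, to
    ``depth`` levels; ordered by descending ISA instance count (how often
    the hyponym link itself was asserted), ties by CUI; sliced to ``cap``.
    """
    seeds = _matching_seed_concepts(store, seed_word)
    frontier = list(seeds)
    seen: set[str] = set(seeds)
    weight: dict[str, int] = {}
    for _ in range(depth):
        nxt: list[str] = []
        for parent in frontier:
            for child in store.isa_children(parent):
                if child in seen:
                    continue
                seen.add(child)
                weight[child] = store.isa_instance_count(child, parent)
                nxt.append(child)
        frontier = nxt
    ranked = sorted(weight, key=lambda cui: (-weight[cui], cui))
    return ranked[:cap]


def expand_argument(
    ast: QueryNode, spec: ExpansionSpec, store: PredicationStore
) -> QueryNode:
    """Rewrite the clause ``spec.field:spec.seed_word`` as an OR over hyponyms.

    The original term is retained; each selected narrower concept is added
    as a quoted phrase of its preferred name on the same field, so the
    expanded query can only gain results, never lose them.

    Raises ``ValueError`` if no clause on ``spec.field`` carries the seed word.
    """
    target = TermClause(field=spec.field, term=spec.seed_word.lower())
    narrower = select_narrower_concepts(store, spec.seed_word, spec.cap, spec.depth)
    replacement_terms: list[QueryNode] = [target]
    for cui in narrower:
        name = store.concepts[cui].preferred_name
        if tokenize(name):
            replacement_terms.append(TermClause(field=spec.field, term=name.lower(), phrase=True))
    replacement: QueryNode = (
        replacement_terms[0] if len(replacement_terms) == 1 else OrNode(tuple(replacement_terms))
    )

    found = False

    def rewrite(node: QueryNode) -> QueryNode:
        nonlocal found
        if isinstance(node, TermClause):
            if node == target:
                found = True
                return replacement
            return node
        if isinstance(node, AndNode):
            return AndNode(tuple(rewrite(c) for c in node.children))
        if isinstance(node, OrNode):
            return OrNode(tuple(rewrite(c) for c in node.children))
        if isinstance(node, NotNode):
            return NotNode(rewrite(node.child))
        raise TypeError(type(node))  # pragma: no cover

    out = rewrite(ast)
    if not found:
        raise ValueError(
            f"query has no clause {spec.field}:{spec.seed_word.lower()} to expand"
        )
    return out


# ---------------------------------------------------------------------------
# Faceting


@dataclass(frozen=True)
class FacetEntry:
    """One facet value and the number of answer relations it appears in."""

    value: str
    relation_count: int


@dataclass(frozen=True)
class Facets:
    """Top-N subjects, relations and objects of a result set."""

    subjects: tuple[FacetEntry, ...]
    relations: tuple[FacetEntry, ...]
    objects: tuple[FacetEntry, ...]


def _top_n(counts: dict[str, int], n: int) -> tuple[FacetEntry, ...]:
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(FacetEntry(value=v, relation_count=c) for v, c in ranked[:n])


def compute_facets(results: ResultSet, store: PredicationStore, n: int) -> Facets:
    """Aggregate a result set into its top-``n`` subjects, relations, objects.

    A concept's subject-facet count is the number of distinct relations in
    the result set in which it appears as a subject (objects and predicates
    analogous); entries are ranked by descending count, ties alphabetical.
    """
    if n < 1:
        raise ValueError("facet size must be >= 1")
    sub_counts: dict[str, int] = {}
    rel_counts: dict[str, int] = {}
    obj_counts: dict[str, int] = {}
    for pid in results:
        pred = store.predications[pid]
        rel_counts[pred.predicate] = rel_counts.get(pred.predicate, 0) + 1
        for cui in set(pred.subject_cuis):
            name = store.concepts[cui].preferred_name
            sub_counts[name] = sub_counts.get(name, 0) + 1
        for cui in set(pred.object_cuis):
            name = store.concepts[cui].preferred_name
            obj_counts[name] = obj_counts.get(name, 0) + 1
    return Facets(
        subjects=_top_n(sub_counts, n),
        relations=_top_n(rel_counts, n),
        objects=_top_n(obj_counts, n),
    )


_FACET_FIELD = {"subject": "sub_name", "relation": "relation", "object": "obj_name"}


def refine_with_facet(ast: QueryNode, facet_kind: str, value: str) -> QueryNode:
    """Conjoin a selected facet value onto the query.

    Subject/object values (concept names) become quoted phrases on the name
    field; relation values become whole-token predicate clauses.  The
    refined query's results are always a subset of the original's.
    """
    if facet_kind not in _FACET_FIELD:
        raise ValueError(f"unknown facet kind {facet_kind!r}")
    fieldname = _FACET_FIELD[facet_kind]
    if facet_kind == "relation":
        clause = TermClause(field=fieldname, term=value.lower())
    else:
        clause = TermClause(field=fieldname, term=value.lower(), phrase=True)
    if isinstance(ast, AndNode):
        if clause in ast.children:  # refining twice is a no-op
            return ast
        return AndNode(ast.children + (clause,))
    if ast == clause:
        return ast
    return AndNode((ast, clause))


# ---------------------------------------------------------------------------
# Microarray filter


class EmptyGeneSetError(ValueError):
    """The selected direction/threshold combination leaves no genes."""


@dataclass(frozen=True)
class FilterSpec:
    """Restrict answers to relations involving differentially expressed genes.

    ``slot`` selects which argument must be one of the experiment's genes;
    ``direction`` selects the up-regulated and/or down-regulated subset;
    the optional thresholds further restrict by absolute effect measure
    and p-value.  Gene identity is by Entrez id (not symbol), sidestepping
    gene-symbol ambiguity.
    """

    experiment: Experiment
    slot: str = "either"  # "subject" | "object" | "either"
    direction: str = "both"  # "up" | "down" | "both"
    min_abs_measure: Optional[float] = None
    max_p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slot not in ("subject", "object", "either"):
            raise ValueError(f"unknown slot {self.slot!r}")
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        for t in (self.min_abs_measure, self.max_p_value):
            if t is not None and not (t == t and abs(t) != float("inf")):
                raise ValueError("thresholds must be finite")

    def selected_genes(self) -> list[int]:
        """Entrez ids passing the direction and threshold filters, sorted."""
        out = []
        for g in self.experiment.subset(self.direction):
            if self.min_abs_measure is not None and abs(g.measure) < self.min_abs_measure:
                continue
            if self.max_p_value is not None and (
                g.p_value is None or g.p_value > self.max_p_value
            ):
                continue
            out.append(g.entrez_id)
        return sorted(out)


def microarray_clause(spec: FilterSpec) -> QueryNode:
    """Build the query fragment: an OR over Entrez-id clauses for the slot.

    Raises :class:`EmptyGeneSetError` if no gene passes the filters (an
    explicit error, never silently empty results).
    """
    genes = spec.selected_genes()
    if not genes:
        raise EmptyGeneSetError(
            f"experiment {spec.experiment.name!r}: no genes left after "
            f"direction={spec.direction!r} and threshold filtering"
        )
    fields = {"subject": ("sub_entrez",), "object": ("obj_entrez",),
              "either": ("sub_entrez", "obj_entrez")}[spec.slot]
    clauses = tuple(
        TermClause(field=f, term=str(g)) for g in genes for f in fields
    )
    return clauses[0] if len(clauses) == 1 else OrNode(clauses)


def apply_filter(ast: QueryNode, fragment: QueryNode) -> QueryNode:
    """Conjoin a filter fragment onto a query."""
    if isinstance(ast, AndNode):
        return AndNode(ast.children + (fragment,))
    return AndNode((ast, fragment))
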