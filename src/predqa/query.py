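"""Template query language and the relation-level inverted index.

Questions are posed as templates over relation fields rather than natural
language: ``sub_name:donepezil AND relation:treats AND obj_name:down
syndrome``.  The grammar follows the conventions of the original search
syntax:

* adjacent clauses are joined by an implicit AND;
* the Boolean operators must be capitalized (``AND``, ``OR``, ``NOT``);
  lowercase ``and``/``or``/``not`` are ordinary search terms;
* search terms are case-insensitive (folded to lowercase);
* ``field:term`` binds the field to exactly the one following token;
  ``field:(a OR b)`` distributes the field over the group;
* quoted strings are phrases matching contiguous token sequences;
* an unknown ``xxx:`` prefix is not an error — it is searched literally,
  with a warning.

The index holds one document per distinct relation (not per sentence):
tokenized subject/object names, the predicate, semantic-type abbreviations
and Entrez ids, with ``arg_*`` fields as the union of the subject and
object sides.  Retrieval is pure Boolean; all ranking happens downstream
on the result set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .model import PredicationStore

logger = logging.getLogger(__name__)

__all__ = [
    "FIELDS",
    "TermClause",
    "AndNode",
    "OrNode",
    "NotNode",
    "QueryNode",
    "QueryParseError",
    "QueryError",
    "parse_query",
    "Index",
    "build_index",
    "ResultSet",
    "search",
    "list_vocabularies",
]

# The fixed field list; anything else before a ":" is a literal term.
FIELDS = (
    "sub_name",
    "sub_semtype",
    "obj_name",
    "obj_semtype",
    "arg_name",
    "arg_semtype",
    "relation",
    "sub_entrez",
    "obj_entrez",
)
ANY = "ANY"

# Fields whose query tokens are kept whole (not split on punctuation):
# semantic-type abbreviations, predicate names, Entrez ids.
_WHOLE_TOKEN_FIELDS = frozenset(
    {"sub_semtype", "obj_semtype", "arg_semtype", "relation", "sub_entrez", "obj_entrez"}
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """The analyzer: lowercase, split on any non-alphanumeric character."""
    return _TOKEN_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class TermClause:
    """A single search clause: a token or quoted phrase in one field (or ANY)."""

    field: str  # one of FIELDS or "ANY"
    term: str  # lowercased token, or the phrase text when ``phrase``
    phrase: bool = False

    def __post_init__(self) -> None:
        if self.field != ANY and self.field not in FIELDS:
            raise ValueError(f"unknown field {self.field!r}")
        if not self.term:
            raise ValueError("empty term")


@dataclass(frozen=True)
class AndNode:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("AND requires at least two children")


@dataclass(frozen=True)
class OrNode:
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("OR requires at least two children")


@dataclass(frozen=True)
class NotNode:
    child: "QueryNode"


QueryNode = Union[TermClause, AndNode, OrNode, NotNode]


class QueryParseError(ValueError):
    """Raised for syntactically invalid queries (with a character position)."""

    def __init__(self, message: str, position: int = 0) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class QueryError(ValueError):
    """Raised for semantically invalid queries (e.g. purely negative)."""


# ---------------------------------------------------------------------------
# Lexer


@dataclass(frozen=True)
class _Tok:
    kind: str  # "word" | "phrase" | "lparen" | "rparen"
    text: str
    pos: int


def _lex(text: str) -> list[_Tok]:
    tokens: list[_Tok] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            tokens.append(_Tok("lparen", ch, i))
            i += 1
        elif ch == ")":
            tokens.append(_Tok("rparen", ch, i))
            i += 1
        elif ch == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise QueryParseError("unterminated quoted phrase", i)
            tokens.append(_Tok("phrase", text[i + 1 : j], i))
            i = j + 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in '()"':
                j += 1
            tokens.append(_Tok("word", text[i:j], i))
            i = j
    return tokens


# ---------------------------------------------------------------------------
# Parser


class _Parser:
    def __init__(self, tokens: list[_Tok], length: int) -> None:
        self.tokens = tokens
        self.i = 0
        self.length = length
        # Field context: inside "field:( ... )" bare terms bind to the field.
        self.field_ctx: list[str] = [ANY]

    def _peek(self) -> Optional[_Tok]:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> _Tok:
        tok = self._peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", self.length)
        self.i += 1
        return tok

    # query := or_expr
    def parse(self) -> QueryNode:
        node = self.parse_or()
        tok = self._peek()
        if tok is not None:
            raise QueryParseError(f"unexpected {tok.text!r}", tok.pos)
        return node

    def parse_or(self) -> QueryNode:
        children = [self.parse_and()]
        while True:
            tok = self._peek()
            if tok is not None and tok.kind == "word" and tok.text == "OR":
                self._next()
                children.append(self.parse_and())
            else:
                break
        return children[0] if len(children) == 1 else OrNode(tuple(children))

    def _starts_clause(self, tok: Optional[_Tok]) -> bool:
        if tok is None:
            return False
        if tok.kind in ("phrase", "lparen"):
            return True
        return tok.kind == "word" and tok.text != "OR" and tok.text != "AND"

    def parse_and(self) -> QueryNode:
        children = [self.parse_unary()]
        while True:
            tok = self._peek()
            if tok is not None and tok.kind == "word" and tok.text == "AND":
                self._next()
                children.append(self.parse_unary())
            elif self._starts_clause(tok):  # implicit AND
                children.append(self.parse_unary())
            else:
                break
        flat: list[QueryNode] = []
        for c in children:  # flatten nested implicit conjunctions
            if isinstance(c, AndNode):
                flat.extend(c.children)
            else:
                flat.append(c)
        return flat[0] if len(flat) == 1 else AndNode(tuple(flat))

    def parse_unary(self) -> QueryNode:
        tok = self._peek()
        if tok is not None and tok.kind == "word" and tok.text == "NOT":
            self._next()
            return NotNode(self.parse_unary())
        return self.parse_primary()

    def parse_primary(self) -> QueryNode:
        tok = self._next()
        if tok.kind == "lparen":
            node = self.parse_or()
            closing = self._peek()
            if closing is None or closing.kind != "rparen":
                raise QueryParseError("unbalanced parentheses", tok.pos)
            self._next()
            return node
        if tok.kind == "rparen":
            raise QueryParseError("unbalanced parentheses", tok.pos)
        if tok.kind == "phrase":
            return _phrase_clause(self.field_ctx[-1], tok.text, tok.pos)
        # word: either "field:value", "field:" + group, or plain term(s)
        word = tok.text
        if word in ("AND", "OR"):  # capitalized operator with a missing operand
            raise QueryParseError(f"dangling operator {word}", tok.pos)
        prefix, colon, rest = word.partition(":")
        if colon and prefix.lower() in FIELDS:
            fieldname = prefix.lower()
            if rest:
                return _term_clauses(fieldname, rest, tok.pos)
            return self._parse_field_value(fieldname, tok.pos)
        if colon:
            logger.warning("unknown field prefix %r treated as a literal term", prefix)
        return _term_clauses(self.field_ctx[-1], word, tok.pos)

    def _parse_field_value(self, fieldname: str, pos: int) -> QueryNode:
        """After ``field:`` with the value in the next token (group, phrase or word)."""
        tok = self._peek()
        if tok is None:
            raise QueryParseError(f"field {fieldname!r} has no value", pos)
        if tok.kind == "lparen":
            self._next()
            self.field_ctx.append(fieldname)
            try:
                group = self.parse_or()
            finally:
                self.field_ctx.pop()
            closing = self._peek()
            if closing is None or closing.kind != "rparen":
                raise QueryParseError("unbalanced parentheses", tok.pos)
            self._next()
            return group
        if tok.kind == "phrase":
            self._next()
            return _phrase_clause(fieldname, tok.text, tok.pos)
        if tok.kind == "word" and tok.text not in ("AND", "OR", "NOT"):
            self._next()
            return _term_clauses(fieldname, tok.text, tok.pos)
        raise QueryParseError(f"field {fieldname!r} has no value", pos)


def _phrase_clause(fieldname: str, text: str, pos: int) -> QueryNode:
    if not tokenize(text):
        raise QueryParseError("empty phrase", pos)
    return TermClause(field=fieldname, term=text.lower(), phrase=True)


def _term_clauses(fieldname: str, word: str, pos: int) -> QueryNode:
    """Analyze one raw word into clause(s) for a field.

    Whole-token fields (semantic types, relation, entrez) keep the word as
    one lowercased token; name fields split it on punctuation, producing an
    implicit AND when it contains several tokens.
    """
    if fieldname in _WHOLE_TOKEN_FIELDS:
        return TermClause(field=fieldname, term=word.lower())
    parts = tokenize(word)
    if not parts:
        raise QueryParseError(f"term {word!r} contains no searchable characters", pos)
    clauses = [TermClause(field=fieldname, term=p) for p in parts]
    return clauses[0] if len(clauses) == 1 else AndNode(tuple(clauses))


def parse_query(text: str) -> QueryNode:
    """Parse a template query string into its AST.

    Raises :class:`QueryParseError` on empty input, unbalanced parentheses
    or a dangling operator.
    """
    if not text or not text.strip():
        raise QueryParseError("empty query", 0)
    tokens = _lex(text)
    # A whole-token field value may be split by the lexer only on
    # parens/quotes; "relation:treats" arrives as one word. Nothing to fix.
    return _Parser(tokens, len(text)).parse()


# ---------------------------------------------------------------------------
# Index


@dataclass
class Index:
    """Inverted index with one document per distinct relation.

    ``postings``: field -> token -> set of predication ids.
    ``sequences``: predication id -> field -> token tuples (one per concept
    name / predicate), used to verify quoted-phrase contiguity.
    Instance counts are stored for downstream ranking.
    """

    postings: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    sequences: dict[str, dict[str, list[tuple[str, ...]]]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def doc_count(self) -> int:
        return len(self.counts)

    def all_ids(self) -> frozenset[str]:
        return frozenset(self.counts)


def _doc_fields(store: PredicationStore, pid: str) -> dict[str, list[tuple[str, ...]]]:
    """Token sequences per field for one relation document."""
    pred = store.predications[pid]
    subs = [store.concepts[c] for c in pred.subject_cuis]
    objs = [store.concepts[c] for c in pred.object_cuis]
    doc: dict[str, list[tuple[str, ...]]] = {
        "sub_name": [tuple(tokenize(c.preferred_name)) for c in subs],
        "obj_name": [tuple(tokenize(c.preferred_name)) for c in objs],
        "sub_semtype": [(t,) for c in subs for t in c.semantic_types],
        "obj_semtype": [(t,) for c in objs for t in c.semantic_types],
        # Predicate: the whole lowercased name plus its punctuation-split tokens.
        "relation": [(pred.predicate.lower(),), tuple(tokenize(pred.predicate))],
        "sub_entrez": [
            (str(c.entrez_gene_id),) for c in subs if c.entrez_gene_id is not None
        ],
        "obj_entrez": [
            (str(c.entrez_gene_id),) for c in objs if c.entrez_gene_id is not None
        ],
    }
    doc["arg_name"] = doc["sub_name"] + doc["obj_name"]
    doc["arg_semtype"] = doc["sub_semtype"] + doc["obj_semtype"]
    return doc


def build_index(store: PredicationStore) -> Index:
    """Build the inverted index over a store; deterministic given the store."""
    index = Index()
    for pid in sorted(store.predications):
        doc = _doc_fields(store, pid)
        index.sequences[pid] = doc
        index.counts[pid] = store.predications[pid].instance_count
        for fieldname, seqs in doc.items():
            post = index.postings.setdefault(fieldname, {})
            for seq in seqs:
                for token in seq:
                    post.setdefault(token, set()).add(pid)
    return index


# ---------------------------------------------------------------------------
# Search


@dataclass(frozen=True)
class ResultSet:
    """The relations matching a query, with their instance counts."""

    predication_ids: frozenset[str]
    counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.predication_ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.predication_ids)

    def __contains__(self, pid: str) -> bool:
        return pid in self.predication_ids


def _term_matches(index: Index, clause: TermClause) -> set[str]:
    fields = FIELDS if clause.field == ANY else (clause.field,)
    if not clause.phrase:
        out: set[str] = set()
        for f in fields:
            out |= index.postings.get(f, {}).get(clause.term, set())
        return out
    # Phrase: contiguous token run inside a single field sequence.
    want = tuple(tokenize(clause.term))
    if not want:
        return set()
    candidates: set[str] = set()
    for f in fields:
        post = index.postings.get(f, {})
        per_field: Optional[set[str]] = None
        for token in want:
            docs = post.get(token, set())
            per_field = docs.copy() if per_field is None else (per_field & docs)
            if not per_field:
                break
        if per_field:
            for pid in per_field:
                if any(_contains_run(seq, want) for seq in index.sequences[pid].get(f, [])):
                    candidates.add(pid)
    return candidates


def _contains_run(seq: tuple[str, ...], want: tuple[str, ...]) -> bool:
    n, m = len(seq), len(want)
    return any(seq[i : i + m] == want for i in range(n - m + 1))


def _evaluate(index: Index, node: QueryNode) -> set[str]:
    if isinstance(node, TermClause):
        return _term_matches(index, node)
    if isinstance(node, OrNode):
        out: set[str] = set()
        for c in node.children:
            if isinstance(c, NotNode):
                raise QueryError("NOT is only allowed inside a conjunction")
            out |= _evaluate(index, c)
        return out
    if isinstance(node, AndNode):
        positives = [c for c in node.children if not isinstance(c, NotNode)]
        negatives = [c for c in node.children if isinstance(c, NotNode)]
        if not positives:
            raise QueryError("purely negative query is not answerable")
        result: Optional[set[str]] = None
        for c in positives:
            matched = _evaluate(index, c)
            result = matched if result is None else (result & matched)
            if not result:
                break
        assert result is not None
        # NOT = complement within the candidate space of its positive siblings.
        for neg in negatives:
            if isinstance(neg.child, NotNode):
                raise QueryError("doubly negated clause is not supported")
            result -= _evaluate(index, neg.child)
        return result
    if isinstance(node, NotNode):
        raise QueryError("purely negative query is not answerable")
    raise TypeError(type(node))  # pragma: no cover


def search(index: Index, ast: QueryNode) -> ResultSet:
    """Evaluate a query AST against the index (pure Boolean, no ranking).

    Raises :class:`QueryError` for purely negative queries.
    """
    pids = _evaluate(index, ast)
    return ResultSet(
        predication_ids=frozenset(pids),
        counts={pid: index.counts[pid] for pid in pids},
    )


# ---------------------------------------------------------------------------
# Vocabulary listings


@dataclass(frozen=True)
class VocabularyListing:
    """Predicates and semantic types of a store ranked by instance count."""

    predicates: tuple[tuple[str, int, int], ...]  # (name, relation_count, instance_count)
    semantic_types: tuple[tuple[str, str, int, int], ...]  # (abbr, full name, rels, insts)


def list_vocabularies(store: PredicationStore) -> VocabularyListing:
    """Rank predicates and argument semantic types by descending instance count.

    Relation count = number of distinct relations using the predicate (or
    having an argument of the type); instance count sums their instances.
    Ties break alphabetically.
    """
    pred_rel: dict[str, int] = {}
    pred_inst: dict[str, int] = {}
    st_rel: dict[str, int] = {}
    st_inst: dict[str, int] = {}
    for p in store.predications.values():
        pred_rel[p.predicate] = pred_rel.get(p.predicate, 0) + 1
        pred_inst[p.predicate] = pred_inst.get(p.predicate, 0) + p.instance_count
        types = set()
        for cui in p.subject_cuis + p.object_cuis:
            types.update(store.concepts[cui].semantic_types)
        for t in types:
            st_rel[t] = st_rel.get(t, 0) + 1
            st_inst[t] = st_inst.get(t, 0) + p.instance_count
    predicates = tuple(
        (name, pred_rel[name], pred_inst[name])
        for name in sorted(pred_rel, key=lambda n: (-pred_inst[n], n))
    )
    semantic_types = tuple(
        (
            abbr,
            store.semantic_type_vocab[abbr].full_name
            if abbr in store.semantic_type_vocab
            else abbr,
            st_rel[abbr],
            st_inst[abbr],
        )
        for abbr in sorted(st_rel, key=lambda a: (-st_inst[a], a))
    )
    return VocabularyListing(predicates=predicates, semantic_types=semantic_types)
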