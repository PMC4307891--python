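"""Independent oracles for the test suite.

The query oracle evaluates a query AST by a linear scan over every relation
in the store, with its own tokenizer and per-document Boolean predicate —
no inverted index, no shared evaluation code — so agreement with
``predqa.query.search`` is meaningful.
"""

from __future__ import annotations

import random
import re

from predqa.model import PredicationStore
from predqa.query import AndNode, NotNode, OrNode, QueryNode, TermClause

_TOK = re.compile(r"[a-z0-9]+")


def toks(text: str) -> list[str]:
    return _TOK.findall(text.lower())


def scan_doc(store: PredicationStore, pid: str) -> dict[str, list[list[str]]]:
    """Field -> token sequences for one relation, built directly from the store."""
    p = store.predications[pid]
    subs = [store.concepts[c] for c in p.subject_cuis]
    objs = [store.concepts[c] for c in p.object_cuis]
    doc = {
        "sub_name": [toks(c.preferred_name) for c in subs],
        "obj_name": [toks(c.preferred_name) for c in objs],
        "sub_semtype": [[t] for c in subs for t in c.semantic_types],
        "obj_semtype": [[t] for c in objs for t in c.semantic_types],
        "relation": [[p.predicate.lower()], toks(p.predicate)],
        "sub_entrez": [[str(c.entrez_gene_id)] for c in subs if c.entrez_gene_id is not None],
        "obj_entrez": [[str(c.entrez_gene_id)] for c in objs if c.entrez_gene_id is not None],
    }
    doc["arg_name"] = doc["sub_name"] + doc["obj_name"]
    doc["arg_semtype"] = doc["sub_semtype"] + doc["obj_semtype"]
    return doc


def _clause_matches(doc: dict[str, list[list[str]]], clause: TermClause) -> bool:
    fields = list(doc) if clause.field == "ANY" else [clause.field]
    if clause.phrase:
        want = toks(clause.term)
        for f in fields:
            for seq in doc.get(f, []):
                for i in range(len(seq) - len(want) + 1):
                    if seq[i : i + len(want)] == want:
                        return True
        return False
    return any(clause.term in seq for f in fields for seq in doc.get(f, []))


def doc_matches(doc: dict[str, list[list[str]]], node: QueryNode) -> bool:
    if isinstance(node, TermClause):
        return _clause_matches(doc, node)
    if isinstance(node, AndNode):
        for c in node.children:
            if isinstance(c, NotNode):
                if doc_matches(doc, c.child):
                    return False
            elif not doc_matches(doc, c):
                return False
        return True
    if isinstance(node, OrNode):
        return any(doc_matches(doc, c) for c in node.children)
    raise TypeError(f"oracle cannot evaluate {type(node)}")


def brute_force_search(store: PredicationStore, node: QueryNode) -> frozenset[str]:
    """All relation ids whose document satisfies the query, by linear scan."""
    return frozenset(
        pid for pid in store.predications if doc_matches(scan_doc(store, pid), node)
    )


# ---------------------------------------------------------------------------
# Random query generation (over vocabulary actually present in a store)


def _token_pool(store: PredicationStore) -> dict[str, list[str]]:
    names: set[str] = set()
    semtypes: set[str] = set()
    entrez: set[str] = set()
    for c in store.concepts.values():
        names.update(toks(c.preferred_name))
        semtypes.update(c.semantic_types)
        if c.entrez_gene_id is not None:
            entrez.add(str(c.entrez_gene_id))
    relations = {p.predicate.lower() for p in store.predications.values()}
    return {
        "name": sorted(names),
        "semtype": sorted(semtypes),
        "relation": sorted(relations),
        "entrez": sorted(entrez),
    }


_FIELD_CHOICES = [
    ("sub_name", "name"),
    ("obj_name", "name"),
    ("arg_name", "name"),
    ("sub_semtype", "semtype"),
    ("obj_semtype", "semtype"),
    ("arg_semtype", "semtype"),
    ("relation", "relation"),
    ("sub_entrez", "entrez"),
    ("obj_entrez", "entrez"),
    ("ANY", "name"),
    ("ANY", "semtype"),
    ("ANY", "relation"),
]


def random_queries(
    store: PredicationStore, n: int, seed: int, max_depth: int = 3
) -> list[QueryNode]:
    """Deterministic battery of random query ASTs over the store's vocabulary."""
    rng = random.Random(seed)
    pool = _token_pool(store)
    concept_names = sorted(c.preferred_name.lower() for c in store.concepts.values())

    def leaf() -> QueryNode:
        field, kind = rng.choice(_FIELD_CHOICES)
        if kind == "name" and rng.random() < 0.2:
            return TermClause(field=field, term=rng.choice(concept_names), phrase=True)
        options = pool[kind] or ["zzznomatch"]
        # Sprinkle in unmatchable terms so empty results get exercised too.
        term = rng.choice(options) if rng.random() < 0.9 else "zzznomatch"
        return TermClause(field=field, term=term)

    def tree(depth: int) -> QueryNode:
        if depth >= max_depth or rng.random() < 0.4:
            return leaf()
        kind = rng.choice(["and", "or", "andnot"])
        k = rng.randint(2, 3)
        if kind == "or":
            return OrNode(tuple(tree(depth + 1) for _ in range(k)))
        children: list[QueryNode] = [tree(depth + 1) for _ in range(k)]
        if kind == "andnot":
            children.append(NotNode(leaf()))
            rng.shuffle(children)
        return AndNode(tuple(children))

    return [tree(0) for _ in range(n)]
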