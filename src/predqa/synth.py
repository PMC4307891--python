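"""Synthetic corpus generator: predication stores, gene lists, vote logs.

Emulates the shape of a literature-extraction corpus at desk scale: a
concept vocabulary with pronounceable pseudo-word names (so no synthetic
name token can collide with a 4-letter semantic-type abbreviation), an ISA
hyponym forest of configurable depth and branching, relation frequencies
with a Zipf-like skew, and per-instance sentences whose argument and
indicator spans are correct by construction.

Everything is a pure function of its config (including the mandatory
seed): two runs with the same config produce byte-identical snapshots.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from . import vocab
from .evalstats import EvaluationLog, record_vote
from .io import Experiment, GeneEntry
from .model import Citation, Concept, PredicationStore, Sentence

__all__ = [
    "SynthConfig",
    "generate_synthetic_store",
    "generate_synthetic_experiment",
    "generate_synthetic_votes",
]

_SYLLABLES = [
    c + v
    for c in "bcdfglmnprstvz"
    for v in "aeiou"
]

# Predicates eligible for random (non-ISA) relations.
_RELATION_PREDICATES = tuple(
    p.name for p in vocab.DEFAULT_PREDICATES if p.name != "ISA"
)

_NON_GENE_TYPES = tuple(
    t.abbreviation
    for t in vocab.DEFAULT_SEMANTIC_TYPES
    if t.abbreviation not in vocab.GENE_SEMANTIC_TYPES
)

_INDICATOR = {"ISA": "is a"}  # others: predicate name, lowercased, "_" -> " "


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic corpus.

    The ISA forest has ``n_isa_roots`` trees, each fully ``isa_branching``-
    ary to ``isa_tree_depth`` levels; every tree edge is an ISA predication,
    counted inside ``n_relations``.  ``zipf_exponent`` skews how the
    ``n_instances`` are shared among relations (every relation keeps at
    least one instance).  ``gene_fraction`` of concepts are genes: typed
    gngm/aapp and carrying a unique Entrez id.  ``distance_p`` is the
    continuation probability of the geometric argument-predicate distance
    (mean p/(1-p) intervening noun phrases).
    """

    n_concepts: int = 300
    n_relations: int = 200
    n_instances: int = 1000
    isa_tree_depth: int = 2
    isa_branching: int = 3
    n_isa_roots: int = 4
    zipf_exponent: float = 1.1
    gene_fraction: float = 0.2
    max_name_words: int = 2
    distance_p: float = 0.35
    multi_arg_fraction: float = 0.1
    predicate_span_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_concepts", "n_relations", "n_instances",
                     "isa_tree_depth", "isa_branching", "n_isa_roots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.gene_fraction < 1):
            raise ValueError("gene_fraction must be in [0, 1)")

    @property
    def isa_tree_nodes(self) -> int:
        per_tree = sum(self.isa_branching**d for d in range(self.isa_tree_depth + 1))
        return self.n_isa_roots * per_tree

    @property
    def isa_edges(self) -> int:
        per_tree = sum(self.isa_branching**d for d in range(1, self.isa_tree_depth + 1))
        return self.n_isa_roots * per_tree


def _check_feasible(cfg: SynthConfig) -> None:
    if cfg.isa_tree_nodes > cfg.n_concepts * (1 - cfg.gene_fraction):
        raise ValueError(
            f"ISA forest needs {cfg.isa_tree_nodes} non-gene concepts but only "
            f"~{int(cfg.n_concepts * (1 - cfg.gene_fraction))} are available"
        )
    if cfg.isa_edges > cfg.n_relations:
        raise ValueError(
            f"ISA forest has {cfg.isa_edges} edges but only {cfg.n_relations} relations"
        )
    if cfg.n_instances < cfg.n_relations:
        raise ValueError("need at least one instance per relation")
    if cfg.n_relations - cfg.isa_edges > cfg.n_concepts * (cfg.n_concepts - 1) // 2:
        raise ValueError("more relations requested than distinct concept pairs")


def _word(rng: random.Random) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(3, 4)))


def _make_concepts(cfg: SynthConfig, rng: random.Random) -> list[Concept]:
    n_genes = int(cfg.n_concepts * cfg.gene_fraction)
    names: set[str] = set()
    concepts: list[Concept] = []
    for i in range(cfg.n_concepts):
        while True:
            n_words = rng.randint(1, cfg.max_name_words)
            name = " ".join(_word(rng) for _ in range(n_words))
            if name not in names:
                names.add(name)
                break
        is_gene = i < n_genes
        if is_gene:
            sts = (rng.choice(sorted(vocab.GENE_SEMANTIC_TYPES)),)
            entrez: Optional[int] = 1000 + i
        else:
            k = rng.randint(1, 2)
            sts = tuple(sorted(rng.sample(_NON_GENE_TYPES, k)))
            entrez = None
        concepts.append(
            Concept(
                cui=f"C{i + 1:07d}",
                preferred_name=name,
                semantic_types=sts,
                entrez_gene_id=entrez,
            )
        )
    return concepts


def _make_relations(
    cfg: SynthConfig, rng: random.Random, concepts: list[Concept]
) -> list[tuple[tuple[str, ...], str, tuple[str, ...]]]:
    """(subject cuis, predicate, object cuis) triples: ISA forest + random rest."""
    n_genes = int(cfg.n_concepts * cfg.gene_fraction)
    non_gene = [c.cui for c in concepts[n_genes:]]
    triples: list[tuple[tuple[str, ...], str, tuple[str, ...]]] = []

    # ISA forest: consume non-gene concepts breadth-first per tree.
    cursor = 0
    for _ in range(cfg.n_isa_roots):
        level = [non_gene[cursor]]
        cursor += 1
        for _ in range(cfg.isa_tree_depth):
            nxt = []
            for parent in level:
                for _ in range(cfg.isa_branching):
                    child = non_gene[cursor]
                    cursor += 1
                    triples.append(((child,), "ISA", (parent,)))
                    nxt.append(child)
            level = nxt

    all_cuis = [c.cui for c in concepts]
    seen = {(t[0], t[1], t[2]) for t in triples}
    attempts = 0
    while len(triples) < cfg.n_relations:
        attempts += 1
        if attempts > 50 * cfg.n_relations:
            raise ValueError("could not place requested relations; config too dense")
        predicate = rng.choice(_RELATION_PREDICATES)
        n_sub = 2 if rng.random() < cfg.multi_arg_fraction else 1
        n_obj = 2 if rng.random() < cfg.multi_arg_fraction else 1
        args = rng.sample(all_cuis, n_sub + n_obj)
        subs = tuple(sorted(args[:n_sub]))
        objs = tuple(sorted(args[n_sub:]))
        key = (subs, predicate, objs)
        if key in seen:
            continue
        seen.add(key)
        triples.append(key)
    return triples


def _zipf_allocation(cfg: SynthConfig, rng: random.Random, n_rel: int) -> list[int]:
    """Instance counts per relation: >=1 each, remainder split by Zipf weights."""
    ranks = list(range(n_rel))
    rng.shuffle(ranks)  # which relation gets which frequency rank
    weights = [(ranks[i] + 1) ** -cfg.zipf_exponent for i in range(n_rel)]
    total_w = sum(weights)
    remainder = cfg.n_instances - n_rel
    raw = [remainder * w / total_w for w in weights]
    counts = [1 + int(r) for r in raw]
    short = cfg.n_instances - sum(counts)
    by_frac = sorted(range(n_rel), key=lambda i: (-(raw[i] - int(raw[i])), i))
    for i in by_frac[:short]:
        counts[i] += 1
    return counts


def _sentence_for(
    rng: random.Random,
    cfg: SynthConfig,
    sub_names: list[str],
    predicate: str,
    obj_names: list[str],
):
    """Compose a sentence embedding the arguments; spans are exact by construction."""
    indicator = _INDICATOR.get(predicate, predicate.lower().replace("_", " "))
    distance = 0
    while rng.random() < cfg.distance_p and distance < 6:
        distance += 1
    fillers = [f"the {_word(rng)}" for _ in range(distance)]

    parts: list[str] = []
    pos = 0
    sub_spans = []
    for i, name in enumerate(sub_names):
        if i:
            parts.append(" and ")
            pos += 5
        parts.append(name)
        sub_spans.append((pos, pos + len(name)))
        pos += len(name)
    parts.append(" ")
    pos += 1
    pred_span = (pos, pos + len(indicator))
    parts.append(indicator)
    pos += len(indicator)
    for f in fillers:
        parts.append(" " + f + ",")
        pos += len(f) + 2
    parts.append(" ")
    pos += 1
    obj_spans = []
    for i, name in enumerate(obj_names):
        if i:
            parts.append(" and ")
            pos += 5
        parts.append(name)
        obj_spans.append((pos, pos + len(name)))
        pos += len(name)
    parts.append(".")
    text = "".join(parts)
    use_pred_span = rng.random() < cfg.predicate_span_fraction
    return text, sub_spans, (pred_span if use_pred_span else None), obj_spans, distance


def generate_synthetic_store(config: SynthConfig) -> PredicationStore:
    """Generate a complete, internally consistent predication store.

    The result passes ``validate_store`` with zero violations, conserves
    instance counts (sum over relations == number of instance records) and
    is byte-identical across runs with the same config.

    Raises ``ValueError`` for infeasible configs.
    """
    _check_feasible(config)
    rng = random.Random(config.seed)
    concepts = _make_concepts(config, rng)
    by_cui = {c.cui: c for c in concepts}
    triples = _make_relations(config, rng, concepts)
    counts = _zipf_allocation(config, rng, len(triples))

    store = PredicationStore()
    n_citations = max(1, config.n_instances // 3)
    serial = 0
    for (subs, predicate, objs), n_inst in zip(triples, counts):
        sub_names = [by_cui[c].preferred_name for c in subs]
        obj_names = [by_cui[c].preferred_name for c in objs]
        for _ in range(n_inst):
            serial += 1
            text, sub_spans, pred_span, obj_spans, distance = _sentence_for(
                rng, config, sub_names, predicate, obj_names
            )
            pmid = 10_000_000 + rng.randrange(n_citations)
            sentence = Sentence(
                sentence_id=f"s{serial:07d}",
                pmid=pmid,
                section="title" if rng.random() < 0.15 else "abstract",
                text=text,
            )
            citation = Citation(
                pmid=pmid, pub_date=f"{rng.randint(1990, 2012)}-01-01"
            )
            store.add_instance(
                subjects=[by_cui[c] for c in subs],
                predicate=predicate,
                objects=[by_cui[c] for c in objs],
                sentence=sentence,
                citation=citation,
                instance_id=f"i{serial:07d}",
                subject_spans=sub_spans,
                object_spans=obj_spans,
                predicate_span=pred_span,
                subject_score=rng.randint(500, 1000),
                object_score=rng.randint(500, 1000),
                arg_predicate_distance=distance,
            )
    return store


def generate_synthetic_experiment(
    store: PredicationStore,
    seed: int,
    name: str = "synthetic-experiment",
    n_genes: Optional[int] = None,
) -> Experiment:
    """A gene list drawn from the store's gene concepts, half up, half down."""
    rng = random.Random(seed)
    gene_concepts = sorted(
        (c for c in store.concepts.values() if c.entrez_gene_id is not None),
        key=lambda c: c.cui,
    )
    if not gene_concepts:
        raise ValueError("store has no gene concepts")
    if n_genes is None:
        n_genes = max(1, len(gene_concepts) // 2)
    chosen = rng.sample(gene_concepts, min(n_genes, len(gene_concepts)))
    genes = []
    for i, c in enumerate(sorted(chosen, key=lambda c: c.cui)):
        direction = "up" if i % 2 == 0 else "down"
        magnitude = round(rng.uniform(0.5, 4.0), 3)
        genes.append(
            GeneEntry(
                entrez_id=c.entrez_gene_id,  # type: ignore[arg-type]
                symbol=c.preferred_name.split()[0].upper()[:6],
                direction=direction,
                measure=magnitude if direction == "up" else -magnitude,
                p_value=round(rng.uniform(1e-6, 0.05), 6),
            )
        )
    return Experiment(name=name, genes=tuple(genes), description="synthetic gene list")


def generate_synthetic_votes(
    store: PredicationStore,
    seed: int,
    n_users: int = 12,
    mean_evaluators: float = 1.6,
    p_correct: float = 0.68,
    p_undecided: float = 0.02,
    n_instances: Optional[int] = None,
) -> EvaluationLog:
    """Votes over the store's instances with 1-3 evaluators per instance."""
    rng = random.Random(seed)
    users = [f"u{i + 1:03d}" for i in range(n_users)]
    log = EvaluationLog()
    ids = sorted(store.instances)
    if n_instances is not None:
        ids = ids[:n_instances]
    w3 = max(0.0, (mean_evaluators - 1.0) / 2.0)
    for iid in ids:
        k = rng.choices([1, 2, 3], weights=[max(0.0, 2 - mean_evaluators) + w3, 1.0, w3])[0]
        for user in rng.sample(users, min(k, n_users)):
            r = rng.random()
            if r < p_undecided:
                outcome = "undecided"
            elif r < p_undecided + (1 - p_undecided) * p_correct:
                outcome = "correct"
            else:
                outcome = "not_correct"
            record_vote(log, user, iid, outcome, timestamp="2013-05-01T12:00:00")
    return log
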