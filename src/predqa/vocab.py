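"""Controlled vocabularies: predicate names and UMLS semantic-type abbreviations.

The predications in the store use a fixed inventory of predicate names
(TREATS, CAUSES, ISA, ...) and each concept argument carries one or more
UMLS semantic-type abbreviations (``dsyn`` = Disease or Syndrome, ``phsu`` =
Pharmacologic Substance, ...).  The abbreviations double as query tokens:
they are four lowercase characters, unique, and never occur as a word inside
a concept's preferred name, so a query term like ``dsyn`` is unambiguous.

The tables below carry reference statistics from a full-scale MEDLINE
extraction run (number of distinct relations and number of relation
instances per predicate / per argument semantic type).  They seed the
default vocabularies; stores built from other corpora may extend them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = [
    "PredicateEntry",
    "SemanticTypeEntry",
    "DEFAULT_PREDICATES",
    "DEFAULT_SEMANTIC_TYPES",
    "predicate_vocabulary",
    "semantic_type_vocabulary",
]


@dataclass(frozen=True)
class PredicateEntry:
    """A predicate name with optional reference corpus statistics."""

    name: str  # uppercase token, e.g. "TREATS"
    relation_count: Optional[int] = None
    instance_count: Optional[int] = None


@dataclass(frozen=True)
class SemanticTypeEntry:
    """A semantic-type abbreviation, its full name, and reference statistics.

    ``abbreviation`` is a 4-character lowercase token; it must never collide
    with a word appearing in any concept preferred name, which is what makes
    it safe as a bare query token.
    """

    abbreviation: str
    full_name: str
    relation_count: Optional[int] = None
    instance_count: Optional[int] = None


# Top 15 predicates by instance count in the reference extraction run,
# plus the remaining core predicate names used in queries and examples.
DEFAULT_PREDICATES: tuple[PredicateEntry, ...] = (
    PredicateEntry("PROCESS_OF", 739217, 12908669),
    PredicateEntry("LOCATION_OF", 2033678, 9560753),
    PredicateEntry("PART_OF", 1132906, 8736983),
    PredicateEntry("TREATS", 993417, 5435929),
    PredicateEntry("ISA", 306793, 3752806),
    PredicateEntry("COEXISTS_WITH", 1149505, 2496628),
    PredicateEntry("AFFECTS", 1008068, 2124063),
    PredicateEntry("INTERACTS_WITH", 956926, 1824826),
    PredicateEntry("USES", 225686, 1391375),
    PredicateEntry("ASSOCIATED_WITH", 544318, 1316494),
    PredicateEntry("CAUSES", 525082, 1164132),
    PredicateEntry("ADMINISTERED_TO", 140881, 1079967),
    PredicateEntry("STIMULATES", 442904, 845725),
    PredicateEntry("INHIBITS", 424125, 749490),
    PredicateEntry("AUGMENTS", 384689, 742944),
    # Core predicate names without reference counts (below the top-15 cut).
    PredicateEntry("PREVENTS"),
    PredicateEntry("MANIFESTATION_OF"),
    PredicateEntry("DISRUPTS"),
    PredicateEntry("PREDISPOSES"),
    PredicateEntry("CO-EXISTS_WITH"),
)

# The 25 most frequent semantic types (of 133) appearing as relation
# arguments in the reference run, by descending instance count.
DEFAULT_SEMANTIC_TYPES: tuple[SemanticTypeEntry, ...] = (
    SemanticTypeEntry("dsyn", "Disease or Syndrome", 2603234, 12591865),
    SemanticTypeEntry("aapp", "Amino Acid, Peptide, or Protein", 4345793, 11503829),
    SemanticTypeEntry("podg", "Patient or Disabled Group", 199404, 9258258),
    SemanticTypeEntry("bpoc", "Body Part, Organ, or Organ Component", 1392967, 8711584),
    SemanticTypeEntry("gngm", "Gene or Genome", 3422406, 6946503),
    SemanticTypeEntry("topp", "Therapeutic or Preventive Procedure", 991912, 5108457),
    SemanticTypeEntry("neop", "Neoplastic Process", 802419, 4650747),
    SemanticTypeEntry("cell", "Cell", 807092, 4346530),
    SemanticTypeEntry("mamm", "Mammal", 456140, 4230378),
    SemanticTypeEntry("phsu", "Pharmacologic Substance", 1100842, 4226225),
    SemanticTypeEntry("orch", "Organic Chemical", 1550322, 3485563),
    SemanticTypeEntry("bacs", "Biologically Active Substance", 951043, 2922549),
    SemanticTypeEntry("fndg", "Finding", 592051, 2906281),
    SemanticTypeEntry("patf", "Pathologic Function", 667378, 2828014),
    SemanticTypeEntry("popg", "Population Group", 339502, 2419899),
    SemanticTypeEntry("aggp", "Age Group", 179259, 2191630),
    SemanticTypeEntry("tisu", "Tissue", 291668, 1634166),
    SemanticTypeEntry("celc", "Cell Component", 349980, 1606480),
    SemanticTypeEntry("humn", "Human", 94088, 1537291),
    SemanticTypeEntry("sosy", "Sign or Symptom", 275794, 1400138),
    SemanticTypeEntry("diap", "Diagnostic Procedure", 271705, 1385473),
    SemanticTypeEntry("orgf", "Organism Function", 292346, 1307166),
    SemanticTypeEntry("inpo", "Injury or Poisoning", 200300, 1076107),
    SemanticTypeEntry("celf", "Cell Function", 370243, 1004738),
    SemanticTypeEntry("mobd", "Mental or Behavioral Dysfunction", 186453, 997544),
)

# Semantic types that mark gene/protein concepts: only these may carry an
# Entrez Gene ID in synthetic data.
GENE_SEMANTIC_TYPES = frozenset({"gngm", "aapp"})


def predicate_vocabulary() -> dict[str, PredicateEntry]:
    """Default predicate vocabulary keyed by (uppercase) name."""
    return {p.name: p for p in DEFAULT_PREDICATES}


def semantic_type_vocabulary() -> dict[str, SemanticTypeEntry]:
    """Default semantic-type vocabulary keyed by abbreviation."""
    return {t.abbreviation: t for t in DEFAULT_SEMANTIC_TYPES}
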