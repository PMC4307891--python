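# Methods

## The predication store

The corpus is modeled as five record types — concepts, citations,
sentences, relations (predications) and relation instances — plus two
controlled vocabularies (predicate names; semantic-type abbreviations with
full names and reference corpus statistics). A relation's identity is the
triple *(sorted subject CUIs, predicate, sorted object CUIs)*: argument
order within a side never matters, direction always does. Instance counts
are derived, never trusted from input, and the store-wide conservation law
(Σ instance_count = number of instance records) is part of validation.

Backing storage is a flat one-row-per-instance TSV snapshot rather than a
relational database: at the scales this package targets the relational
view (deduplicated concepts/sentences/citations, aggregated relations) is
rebuilt in memory on read in well under a second, and a single text file
is portable, diffable and trivially fixture-friendly. For the same reason
the inverted index is not persisted: it is a deterministic pure function
of the store and is rebuilt on load.

Character spans are 0-based half-open `[start, end)` — the convention of
Python slicing — since the source material does not fix one. Spans point
at the *surface* text, which may differ from the concept's preferred name
(an abbreviation like "AD", a preposition serving as a treatment
indicator); the highlighting layer therefore never assumes it can find
the preferred name in the sentence.

`validate_store` returns violations as data instead of raising: real
extraction output contains irregularities, and ingest policy (skip row,
warn, fail) belongs to the caller. Rows with malformed or out-of-bounds
spans are skipped with a logged warning and surfaced as a skip count.

## Query language and index

The grammar is a small Boolean template language: nine fields
(`sub_name`, `sub_semtype`, `obj_name`, `obj_semtype`, `arg_name`,
`arg_semtype`, `relation`, `sub_entrez`, `obj_entrez`), implicit AND
between adjacent clauses, capitalized `AND`/`OR`/`NOT` (lowercase forms
are ordinary terms), quoted phrases, parenthesized grouping, and
case-folded terms. Parsing is recursive descent over a hand-written
lexer; errors carry a character position.

Decisions where the behavior was genuinely open:

* **Tokenization.** Split on any non-alphanumeric character, lowercase.
  Predicate names, semantic-type abbreviations and Entrez ids are
  *additionally* indexed whole in their own fields, and query tokens on
  those fields are kept whole, so `relation:ASSOCIATED_WITH` matches as
  one token while unfielded `associated with` still matches via the split
  tokens.
* **Single-token field binding.** `obj_name:down syndrome` binds only
  `down`; the trailing `syndrome` falls back to all-fields search. This
  keeps the grammar predictable and still answers the canonical examples;
  `field:(...)` and `field:"..."` are the explicit multi-token forms.
* **NOT semantics.** A `NOT` clause is set complement restricted to the
  candidate space of its positive siblings in the enclosing conjunction;
  purely negative queries are rejected as unanswerable rather than
  answered with "everything else".
* **Unknown `xxx:` prefixes** are searched literally with a warning —
  users typo field names, and silently empty results are worse than noisy
  ones.
* **No retrieval-time scoring.** Retrieval is strictly Boolean; every
  ordering (frequency, distance) is applied to the result set downstream.
  This makes the index trivially checkable against a linear scan, which
  the test suite and the acceptance script both do.

The index holds one document per relation with per-field token sequences
(one per concept name), so quoted phrases are verified as contiguous runs
within a single name — `"down syndrome"` matches the concept *Down
Syndrome* but not a relation that mentions `down` and `syndrome` in
different arguments.

## Expansion, facets, filter

All three features are query rewrites, so they compose and stay pure
functions of (store, query, spec).

**Expansion** takes a single-word seed on an explicit name field, matches
every concept whose preferred name contains that word as a whole token
(substring matching would let "ase" match half a biochemical vocabulary),
walks ISA links to the configured depth (default 1 — transitive closure
is available via `depth`), and keeps at most `cap` (default 100) narrower
concepts. The cap's ordering is descending ISA-link instance count with
CUI tie-break: deterministic, and it prefers well-attested hyponyms. The
seed term is retained in the rewritten OR, so expansion is monotone: an
expanded query can gain answers but never lose them. Selected concept
names enter the query as quoted phrases, which is what makes multi-word
hyponyms safe.

**Facets** count, for each concept name (or predicate), the number of
distinct relations in the answer set where it appears in the given role;
ties are alphabetical. Refinement conjoins the selected value back onto
the query — as a whole-token clause for predicates, as a quoted phrase on
the name field for concepts. A phrase can in principle also match a longer
name containing it; exact-name refinement would require a keyword field
the query language deliberately does not expose.

**The microarray filter** selects genes from an experiment by direction
(up/down/both) and optional |measure| and p-value thresholds (defaults: no
thresholding), then builds an OR of Entrez-id clauses on `sub_entrez` /
`obj_entrez` per the chosen slot. Gene identity is by Entrez id, never by
symbol — gene symbols are ambiguous (CT, MR). An empty selection raises an
explicit error instead of silently returning nothing.

## Answer ordering

Relations are ranked by descending instance frequency; ties break
ascending by (subject names, predicate, object names) so the order is
total. Instances of a relation are ranked by ascending
argument–predicate distance — extractions whose arguments sit close to
the indicator word are more likely correct — with (pmid, sentence id,
instance id) as the tie-break. Both tie-break chains are this package's
own choice; only the primary keys are inherent to the method.

## Annotation statistics

Votes are one-per-(user, instance), latest wins; outcomes are `correct`,
`not_correct`, `undecided`. Undecided votes are excluded from every
percentage denominator and from evaluator counts — in the reference
campaign the correct and wrong tallies alone account for every reported
evaluation. Evaluator count means *distinct users with a decided vote on
the instance*. Percentages are integer percents rounded half up; the
reference report itself rounds inconsistently (some figures floor, some
round to nearest), so the suite and the acceptance script assert only
figures that are identical under both modes. The agreement measure is the
plain unanimity ratio among instances with exactly *k* evaluators — no
chance correction (kappa) is attempted, matching the simple ratio the
method defines. The published campaign marginals are not mutually
consistent as one dataset (the per-evaluator-count breakdown does not sum
to the vote total), so each reproduced figure is recomputed from its own
minimal vote-log fixture built to the printed counts for that figure.

## Synthetic corpus generator

The generator emulates the *shape* of an extraction corpus, not its
content: pseudo-word concept names (3–4 two-letter syllables per word,
hence ≥6 characters — no collision with 4-letter semantic-type
abbreviations is possible); a gene fraction (default 0.2) typed
`gngm`/`aapp` with unique Entrez ids; an ISA forest of configurable root
count, branching and depth whose edges are ordinary ISA relations; the
remaining relations drawn uniformly over concept pairs and non-ISA
predicates, with ~10% multi-concept arguments; instance counts skewed by
a Zipf law (default exponent 1.1, every relation keeping at least one
instance); and per-instance sentences composed around the argument names
and an indicator word, with geometric argument–predicate distance
(default continuation probability 0.35) realized as interposed filler
noun phrases, exact spans by construction, and ~10% of instances lacking
an indicator span. Defaults (300 concepts, 200 relations, 1,000
instances) keep every generated relation exercised by multiple features
while the full test suite stays in seconds. Everything derives from one
`random.Random(seed)` stream, so equal configs give byte-identical
snapshots. Note the store keeps only concepts that participate in some
relation, so a snapshot may contain fewer concepts than `n_concepts`.

What the generator does **not** emulate: natural-language sentence
structure (fillers are synthetic noun phrases), extraction errors
(spans are always correct; scores are noise), concept-name ambiguity and
abbreviations, polyhierarchy (each synthetic concept has one ISA parent),
and realistic per-predicate type constraints. Passing tests therefore
demonstrate the engine's semantics — Boolean correctness, monotonicity,
conservation, ordering, determinism — not robustness to messy extraction
output; the reader tests plus the skip-count mechanism cover the
irregular-input side at unit scale.

## Scale of the shipped checks

The oracle-equivalence battery runs 200+ random Boolean queries against a
400-relation corpus (and 200 more in the acceptance script against a
200-relation corpus); the linear-scan oracle is quadratic in corpus size,
and a few hundred relations already exercises every operator, field and
phrase path while keeping the whole suite under ten seconds. The
annotation-arithmetic reproductions run at the campaign's true size
(12,083 votes, 7,510 instances) since that is already desk-scale.

## Known limitations

* The query language has no ranges, fuzziness or boosting, and no
  natural-language input; questions are templates.
* A query that is only negative is rejected by design.
* Refinement-by-name uses phrase containment, not exact name equality.
* Expansion requires an explicit name field and a single-word seed (the
  seed selects concepts by token containment, so multi-word concepts are
  still reachable through any of their words).
* Multiple relations between the same argument sets with different
  predicates are distinct relations; there is no cross-predicate
  aggregation.
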