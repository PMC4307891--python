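# predqa

Question answering over a store of semantic predications extracted from
biomedical literature.

Literature search engines return documents; a researcher asking "what
treats Alzheimer's disease?" then has to read them. `predqa` instead
answers from a corpus of *semantic predications* — subject–PREDICATE–object
assertions such as `Donepezil-TREATS-Alzheimer's Disease`, each backed by
the sentences it was extracted from. It is aimed at clinicians and
biomedical researchers doing evidence lookup, literature-based discovery,
or interpretation of differential-expression gene lists, and at developers
who need a testable, headless engine for predication corpora.

## The model

The corpus is a set of relations *R = (S, p, O)* with subject concepts
*S*, predicate *p* (TREATS, CAUSES, ISA, ...) and object concepts *O*;
each relation aggregates *instances* — occurrences in individual sentences
carrying character spans, extraction scores and the argument–predicate
distance *d* (number of noun phrases between argument and indicator word).
Concepts carry a CUI, one or more UMLS semantic types (`dsyn`, `phsu`,
`gngm`, ...) and, for genes, an Entrez id.

Questions are templates over relation fields, not natural language:

```
sub_name:donepezil AND relation:treats AND obj_name:down syndrome
sub_semtype:(aapp OR gngm) AND relation:(CAUSES OR PREDISPOSES OR ASSOCIATED_WITH)
NOT sub_semtype:phsu treats Alzheimer
```

Adjacent clauses are joined by an implicit AND; operators must be
capitalized (lowercase `and`/`or`/`not` are search terms); terms are
case-insensitive; `field:term` binds exactly one following token (use
parentheses or quotes for more). Retrieval is pure Boolean over a
relation-level inverted index. On top of it:

* **hyponym expansion** — a single-word argument is widened with the
  ISA-narrower concepts of every concept whose name contains that word
  (at most 100, best-attested first);
* **facets** — top-*N* subjects, relations and objects of an answer set,
  counted by the number of relations each appears in, for drill-down
  refinement;
* **microarray filter** — restricts an argument slot to the up- and/or
  down-regulated Entrez ids of a loaded experiment;
* **answer ranking** — relations descending by instance frequency;
  instances ascending by *d* (low-distance extractions are more often
  correct);
* **annotation statistics** — per-instance correct/not-correct/undecided
  votes, outcome classes, and a unanimity-based agreement ratio.

## Worked example

`examples/02_template_queries.py` builds a six-sentence corpus and runs
four queries; it prints:

```
query: 'treats alzheimer' -> 3 relations
  freq=3  Donepezil-TREATS-Alzheimer's Disease
  freq=2  Galantamine-TREATS-Alzheimer's Disease
  freq=1  Exercise-TREATS-Alzheimer's Disease

query: 'treats alzheimer NOT sub_semtype:topp' -> 2 relations
  freq=3  Donepezil-TREATS-Alzheimer's Disease
  freq=2  Galantamine-TREATS-Alzheimer's Disease
```

`freq` is the number of sentences asserting each relation — Donepezil,
with three supporting sentences, outranks Galantamine with two; the NOT
clause removes the relation whose subject is a therapeutic procedure
(`topp`) while keeping the pharmacologic substances. The other examples
cover corpus generation, expansion + facets, the microarray filter and
annotation statistics; each prints the numbers it computes and what they
mean.

A CLI mirrors the workflow (`predqa synth | ingest | index | query |
instances | evaluate | stats`, all with `--format json`); see
`predqa --help`.

## Data formats

* **Predication table** — UTF-8 TSV, one row per instance; multi-concept
  arguments use `|`, per-concept semantic-type lists use `,`, spans are
  `start-end` (0-based half-open). Column list in
  `src/predqa/io.py::LOGICAL_COLUMNS`; custom headers map via
  `TableDialect`.
* **Gene list** — TSV: `entrez_id, symbol, direction (up|down), measure,
  p_value`.
* **Vote log** — JSON-lines: `{"user", "instance_id", "outcome",
  "timestamp"}` with outcome `correct | not_correct | undecided`.

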