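"""Restrict answers to the differentially expressed genes of an experiment.

A microarray comparison yields lists of up- and down-regulated genes with
Entrez ids.  The filter rewrites a query so that a chosen argument slot
must carry one of those Entrez ids — asking, e.g., "to which diseases are
my up-regulated genes etiologically related?" over hundreds of genes at
once.
"""

from predqa import (
    FilterSpec,
    SynthConfig,
    apply_filter,
    build_index,
    generate_synthetic_experiment,
    generate_synthetic_store,
    microarray_clause,
    parse_query,
    rank_relations,
    search,
)

store = generate_synthetic_store(SynthConfig(seed=42))
experiment = generate_synthetic_experiment(store, seed=43, name="synthetic-array")
print(f"experiment {experiment.name!r}: {len(experiment.subset('up'))} up-regulated, "
      f"{len(experiment.subset('down'))} down-regulated genes")

ast = parse_query("relation:(ASSOCIATED_WITH OR PREDISPOSES OR CAUSES)")
unfiltered = search(build_index(store), ast)

spec = FilterSpec(experiment=experiment, slot="subject", direction="up")
filtered_ast = apply_filter(ast, microarray_clause(spec))
index = build_index(store)
filtered = search(index, filtered_ast)

print(f"etiology query: {len(unfiltered)} relations unfiltered, "
      f"{len(filtered)} with an up-regulated gene as subject")
for answer in rank_relations(filtered, store)[:5]:
    print(f"  freq={answer.frequency}  "
          f"{' and '.join(answer.subjects)}-{answer.predicate}-"
          f"{' and '.join(answer.objects)}")
# Each listed subject is a gene from the experiment's up-regulated list.
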