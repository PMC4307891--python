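"""Widen a query with ISA hyponyms, then drill down through facets.

On a synthetic corpus with a hyponym forest: querying a broad concept's
name finds only relations mentioning it literally; expansion rewrites the
clause into an OR over its ISA-narrower concepts (capped at 100), and
facets aggregate the enlarged answer set for refinement.
"""

from predqa import (
    ExpansionSpec,
    SynthConfig,
    build_index,
    compute_facets,
    expand_argument,
    generate_synthetic_store,
    parse_query,
    refine_with_facet,
    search,
)

store = generate_synthetic_store(
    SynthConfig(n_concepts=300, n_relations=200, n_instances=1000,
                isa_tree_depth=2, isa_branching=4, n_isa_roots=2, seed=42)
)
index = build_index(store)

# Pick a broad concept: one that has ISA-narrower concepts.
links = store.isa_links
broad_cui = next(iter({next(iter(p)) for p in links.values()} - set(links)))
word = store.concepts[broad_cui].preferred_name.split()[0]

ast = parse_query(f"arg_name:{word}")
before = search(index, ast)

expanded_ast = expand_argument(
    ast, ExpansionSpec(field="arg_name", seed_word=word, cap=100, depth=2), store
)
after = search(index, expanded_ast)
print(f"query arg_name:{word}: {len(before)} relations before expansion, "
      f"{len(after)} after (hyponyms of {store.concepts[broad_cui].preferred_name!r})")

facets = compute_facets(after, store, n=3)
print("\ntop relation facet entries (predicate, number of answer relations):")
for entry in facets.relations:
    print(f"  {entry.value:<16} {entry.relation_count}")

chosen = facets.relations[0].value
refined = refine_with_facet(expanded_ast, "relation", chosen)
print(f"\nrefined by relation={chosen}: {len(search(index, refined))} relations "
      f"(a subset of the {len(after)} expanded answers)")
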