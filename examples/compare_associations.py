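"""Comparative annotation analytics on the merged graph.

Shows, for disorders described by several sources, which gene/phenotype
annotations are common to all annotating sources and which are unique to
one — the "what do all sources agree on?" query — plus the endpoint-style
listing of disorders associated with a given gene, provenance included.
"""
import taxoprov as tp

bundle = tp.curated_fixture()
graph, _ = tp.merge(list(bundle.sources), bundle.alignment)

maroteaux = tp.find_by_label(
    graph, "Spondyloepimetaphyseal dysplasia Maroteaux type")
comparison = tp.association_comparison(graph, maroteaux)
print("Maroteaux-type disorder:")
print(f"  genes per agent:      "
      f"{ {a: sorted(v) for a, v in comparison.genes_by_agent.items()} }")
print(f"  genes common to all:  {sorted(comparison.common_genes)}")
print(f"  phenotypes unique to one agent: "
      f"{ {a: sorted(v) for a, v in comparison.unique_phenotypes.items() if v} }")

fgfr3 = tp.find_by_label(graph, "FGFR3")
print("\ndisorders associated with FGFR3 (with provenance):")
for disorder, relation, agents in tp.query_associations(graph, fgfr3):
    print(f"  {graph.entities[disorder].label:45s} "
          f"{relation.value.lower():16s} {sorted(agents)}")

# FGFR3 is common to both classifications for Achondroplasia, while the
# Genu valgum phenotype of the Maroteaux-type disorder is asserted only by
# the OMIM-derived annotations of the nosology side.
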