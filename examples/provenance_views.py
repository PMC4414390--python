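"""Backwards compatibility: re-create one source from the merged graph.

A provenance view keeps only the entities and statements attributed to the
chosen agents.  Restricting the merged worked-examples graph to the
nosology side (ISDS plus its OMIM-derived phenotype annotations) recovers
that source exactly — same statements, same attribution, same labels.
"""
import taxoprov as tp
from taxoprov.merge import build_canonical_map, canonicalize_source

bundle = tp.curated_fixture()
graph, _ = tp.merge(list(bundle.sources), bundle.alignment)
cmap = build_canonical_map(list(bundle.sources), bundle.alignment)

for doc in bundle.sources:
    agents = {a.id for a in doc.all_agents()}
    view = tp.provenance_view(graph, agents)
    original = canonicalize_source(doc, cmap)
    print(f"view by {sorted(agents)}: {len(view.entities)} entities, "
          f"{len(view.statement_keys())} statements; "
          f"equals the ingested source: {view == original}")

# A disorder the two sources place differently keeps only the chosen
# source's placement in the view:
maroteaux = tp.find_by_label(
    graph, "Spondyloepimetaphyseal dysplasia Maroteaux type")
for agent in ("ISDS", "Orphanet"):
    view = tp.provenance_view(graph, {agent})
    parents = [view.entities[s].label for (s, p, o, _q) in view.statement_keys()
               if o == maroteaux and p is tp.Predicate.MEMBER]
    print(f"{agent} places the Maroteaux-type disorder in: {parents}")
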