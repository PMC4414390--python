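# taxoprov

Loose integration of expert disease classifications into a single
provenance-annotated knowledge graph.

## The problem

Several expert communities often classify the same disease domain in
parallel. In the rare-bone-disorder domain, a society nosology groups
skeletal dysplasias by clinical or molecular criteria, while Orphanet
maintains a deeper taxonomy with its own grouping choices, curated gene
associations, and frequency-qualified phenotype annotations. The two
censuses disagree substantially — in disorder coverage, in which concepts
are *groups* versus *disorders*, in hierarchy depth, and in the
disorder–phenotype associations themselves. None of these disagreements
is an error to be fixed: they are different expert perspectives, and a
useful integrated resource must keep all of them, attributed to whoever
asserted them.

`taxoprov` is a library (plus a thin CLI) for exactly that. It consumes
two or more *source classification documents* (JSON) and an expert
*alignment table* (TSV — the manual cross-source mapping, consumed as
data, never computed), and produces one knowledge graph in which:

- disorder **groups** behave like SKOS Collections, connected to their
  members by `skos:member`; groups nest arbitrarily deep;
- **sub-typing** between disorders uses the mutually inverse
  `skos:narrowerTransitive` / `skos:broaderTransitive` relations, so a
  disorder that *has narrower* sub-types is transitively broader than all
  of them; cycles are rejected at insertion;
- disorders link to genes, phenotypes (HPO CURIEs, optionally carrying an
  Orphanet-style frequency-of-occurrence qualifier) and modes of
  inheritance;
- **every entity and every statement** carries a non-empty set of
  provenance agents (`prov:wasAttributedTo`). Identical assertions from
  several sources collapse into one statement credited to all of them;
  conflicting assertions coexist side by side, each with its own
  provenance.

Because provenance is recorded at statement level, the original
classifications remain recoverable: a *provenance view* filtered to one
source's agents reproduces that source exactly — the integrated resource
is backwards compatible by construction. On top of the merged graph the
library answers the comparative questions this kind of resource exists
for: which annotations are common to all sources, where do the groupings
diverge, how deep does each taxonomy nest, and how much of one census the
other covers.

The merged graph serializes to a canonical RDF Turtle dialect: each
concept identifier is *punned* (typed both as an OWL class and a SKOS
Concept instance), each statement is emitted as its plain triple plus an
`owl:Axiom` annotation node carrying the per-agent attribution, and the
output is byte-stable for equal graphs.

## Worked example

```python
import taxoprov as tp

bundle = tp.curated_fixture()            # two sources + expert alignment
graph, report = tp.merge(list(bundle.sources), bundle.alignment)

maroteaux = tp.find_by_label(
    graph, "Spondyloepimetaphyseal dysplasia Maroteaux type")
comparison = tp.association_comparison(graph, maroteaux)
print(sorted(comparison.common_genes))
print({a: sorted(v) for a, v in comparison.unique_phenotypes.items() if v})
```

prints

```
['GENE0000002']
{'Orphanet': ['HP:0000926'], 'OMIM': ['HP:0002857']}
```

meaning: both classifications independently associate the Maroteaux-type
disorder with the TRPV4 gene (one canonical gene id, attributed to both
agents), while its Genu valgum phenotype (HP:0002857) comes only from the
OMIM-derived annotations of the nosology side and Platyspondyly
(HP:0000926) only from Orphanet. The same disorder sits in two groups —
the TRPV4 group on the nosology side, the spondylo-epi(-meta)physeal
dysplasias on the Orphanet side — each membership statement carrying its
own attribution. The scripts in `examples/` walk through merging,
provenance views, association comparison and the coverage/divergence/
depth reports, each printing the numbers it computes.

A thin CLI mirrors the library:

```
taxoprov fixture --out bundle --seed 7
taxoprov merge bundle/left.json bundle/right.json \
    --alignment bundle/alignment.tsv -o merged.ttl
taxoprov view merged.ttl --agents ISDS -o nosology_view.ttl
taxoprov coverage merged.ttl --left ISDS --right ORPHA
```

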