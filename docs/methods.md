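# Methods

## Model

A `KnowledgeGraph` holds entities, statements and an agent registry.
Entities have a closed kind enumeration — GROUP, DISORDER, GENE,
PHENOTYPE, INHERITANCE_MODE — where GROUP carries SKOS Collection
semantics and the rest SKOS Concept semantics. Statements are edges over
six predicates with fixed domain/range constraints:

| predicate              | subject → object      | vocabulary property        |
|------------------------|-----------------------|----------------------------|
| `MEMBER`               | group → group/disorder| `skos:member`              |
| `NARROWER_T`           | disorder → disorder   | `skos:narrowerTransitive`  |
| `BROADER_T`            | disorder → disorder   | `skos:broaderTransitive`   |
| `ASSOCIATED_GENE`      | disorder → gene       | `rbdo:associated_gene`     |
| `ASSOCIATED_PHENOTYPE` | disorder → phenotype  | `rbdo:associated_phenotype`|
| `MODE_OF_INHERITANCE`  | disorder → mode       | `rbdo:mode_of_inheritance` |

`NARROWER_T(a, b)` reads "a **has narrower** b" — the subject is the
broader disorder, matching strict SKOS usage of
`skos:narrowerTransitive` (a listing such as *Rubinstein-Taybi syndrome
narrowerTransitive Rubinstein-Taybi due to 16p13.3 microdeletion* puts
the sub-type in object position). The inverse `BROADER_T` edge is
materialized automatically with identical attribution, so serialization
always contains both directions explicitly and validation can check the
pairing. Hierarchy-facing operations (closure, depth, children,
divergence parents) treat `MEMBER` and `NARROWER_T` as the parent→child
edges.

Statement identity is the quadruple (subject, predicate, object,
frequency qualifier). Including the qualifier means the same
disorder–phenotype pair asserted as "very frequent" by one source and
unqualified by another yields two coexisting statements — each source's
assertion survives verbatim, which is the conflict-retention policy of
the whole design. Re-adding an entity or statement unions labels,
cross-references and attribution sets; no operation ever removes an agent
from an attribution set, and no entity or statement can exist with an
empty one.

Cycles in sub-typing (and in nested group membership) are rejected at
insertion rather than tolerated: transitivity over a cycle would make
every member broader than itself, destroying the hierarchy the relations
exist to express. Because `MEMBER` never points from a disorder back to a
group, the combined containment graph is acyclic whenever the two
per-relation graphs are, so depth is well defined.

### Group-vs-disorder heuristic

`classify_node_kind` is advisory only (declared kinds come from the
sources and the expert alignment): a node whose children are all
sub-type-linked disorders is a DISORDER; any group child, or any child
held via plain membership, makes it a GROUP; a node without children
keeps its declared kind. The rule is deliberately simpler than a fuller
formulation that also demands each child have the node as its sole
broader parent within one source: that extra condition can contradict the
invariant "purely sub-typed children never yield GROUP", so the
children-only rule is used and the sole-parent refinement is documented
as a possible extension. During merge, the heuristic is consulted only
for aligned pairs whose declared kinds disagree under an AUTO decision,
and only nodes that actually have children contribute a verdict.

## Serialization

The Turtle dialect is written by the package itself (rdflib parses it
back): rdflib terms provide the escaping, but the canonical layout —
prefixes, ontology header, agents, entities, plain statement triples,
axiom nodes, each section sorted lexicographically — is part of the
format contract, so equal graphs serialize byte-identically. Entity kinds
are recoverable from type markers (`rbdo:BoneDisorder`, `rbdo:Gene`,
`skos:Collection`/`rbdo:BoneDisorderGroup`) or, for phenotypes and
inheritance modes, from `rdfs:subClassOf` links to the HPO roots
HP:0000118 and HP:0000005. Disorders, genes, phenotypes and modes are
punned: one IRI typed both `owl:Class` and `skos:Concept`.

Each statement yields one plain triple plus one `owl:Axiom` node carrying
`owl:annotatedSource/Property/Target`, one `prov:wasAttributedTo` triple
per agent, and — for qualified phenotype associations — an
`rbdo:frequency` literal. Two qualifier variants of the same triple share
one plain triple but keep separate axiom nodes. Agents live in a separate
IRI namespace (`…/agent#`) so an agent token can never collide with an
entity id. The reader rejects, with `DialectError`, any triple outside
the dialect, axiom nodes missing one of their three links, and plain
statement triples without an axiom node. Entity ids that are not safe
Turtle local names are percent-encoded into full IRIs; HP CURIEs map to
OBO-style `HP_` IRIs.

The frequency vocabulary is this package's closed six-value enumeration
(obligate, very_frequent, frequent, occasional, very_rare, unspecified);
source ingestion accepts a configurable synonym table for the prose forms
("very frequently", …).

## Merge

Canonical ids are minted deterministically: alignment rows are closed
under union-find (so three-way alignments compose transitively), aligned
clusters come first, then unaligned entities, each ordered by (agent id,
local id), numbered `BD…`/`BDG…`/`GENE…` with 7-digit zero padding;
phenotype and inheritance-mode CURIEs pass through unchanged. Sources are
processed in lexicographic agent order, which fixes the preferred label
(first contributor wins; other labels become alt-labels) and makes the
merge independent of call order. Aligned records that disagree on a
cross-reference namespace keep both values, flagged in the merge report.
Kind conflicts inside an aligned pair are settled by precedence: explicit
expert decision, then agreement of declared kinds, then the children
heuristic; anything still open is an error rather than a silent choice.

The merge never invents precedence between contradicting placements
(e.g. a disorder grouped by one source and sub-typed by the other): both
statements coexist with their own provenance.

## Provenance views and recovery

`provenance_view(graph, agents)` keeps entities and statements whose
attribution intersects the agent set, restricted to it. To make the
backwards-compatibility property exact, the graph records each
`add_entity` call as a *contribution*; a view replays only the matching
contributions, so labels and cross-references contributed by other
sources do not leak in. The contribution log is in-memory bookkeeping:
it does not participate in graph equality and is not carried through
Turtle (a round-tripped graph has one contribution per entity, so a view
of it still restricts correctly, just without per-source label
splitting). Views are idempotent and monotone in the agent set, and a
view of a merge by one source's agents equals that source under the
canonical id map — tested as a property over seeded random fixtures.

## Analytics

*Common* annotations for a disorder intersect over the agents that
annotate it at all — an agent silent on a disorder does not force the
intersection empty, otherwise any disorder absent from one source would
trivially have no common annotations. *Unique* annotations are those no
other agent asserts (and, for a single annotating agent, the unique set
is empty so it stays disjoint from the common set). Frequency qualifiers
are ignored for set membership. Phenotype matching is exact-id;
HPO-ancestor-aware matching is a possible extension, not implemented.

Coverage counts a disorder for an agent iff the *entity* attribution
contains that agent (a disorder mentioned only inside statements still
counts for whoever attributed the entity). Percentages are rounded
half-up to one decimal — 202 of 524 prints as 38.5. Taxonomy depth is
counted in edges over the combined membership/sub-typing hierarchy, from
roots (nodes without incoming containment edges); both relations
contribute because real taxonomies interleave groups and sub-types.

## Synthetic fixtures

`generate_fixture` emulates the two-source study conditions: a
nosology-style left source and an Orphanet-style right source (the right
one attaches frequency qualifiers), with defaults of 24 disorders and 6
groups per source, half the disorders expert-aligned, a 40-term phenotype
vocabulary, 2–6 phenotype annotations per disorder with 50% of the
smaller annotation set shared on aligned disorders, 1–2 genes per
disorder, and hierarchies nested up to 4 levels. These sizes keep every
structural regime present (aligned/unaligned, nested groups, sub-type
chains, shared and unique annotations) while remaining small enough for
property tests to run in seconds; the coverage census is the same
generator run at 524 disorders with 322 aligned. All randomness flows
through one seeded `random.Random`; identical parameters produce
byte-identical bundles, and a manifest of ground-truth tallies (aligned
counts, per-disorder overlap triples, per-source depth) is written at
generation time by direct counting, independently of the library's
analytics.

Hierarchy edges always point from lower to higher index on each side and
aligned entities share their index, which guarantees the union of both
hierarchies is acyclic — the generator exercises divergence, not
inconsistency. What the generator does *not* emulate: real label
variation across sources for aligned entities beyond xrefs, kind
disagreements (covered by dedicated unit tests instead), HPO's internal
hierarchy, and the scale of a full classification (thousands of
disorders). Passing property tests therefore demonstrate structural and
provenance correctness, not robustness to noisy real-world label
matching — which is out of scope, since alignment is expert input here.

`curated_fixture` is a hand-written bundle encoding the worked examples —
the Maroteaux-type disorder in two groups with split attribution and a
jointly asserted TRPV4 association, the OMIM-attributed Genu valgum
annotation, the Achondroplasia–FGFR3 association asserted by both
sources, the Holt-Oram grouping-vs-sub-typing divergence, the
three-disorder polydactyly sub-typing chain, the Rubinstein-Taybi
narrower/broader pair, and a mixed group holding two groups and a
disorder. Its manifest tallies are computed by direct arithmetic over the
entity lists.

## Numerical and degenerate-input choices

- Percentage rounding: decimal half-up to one decimal place, exact in
  `Decimal` arithmetic.
- Empty graph: serializes to prefix declarations only and reads back as
  the empty graph; fact-sheet counts are zero; depth of an edge-free
  hierarchy is 0.
- An empty alignment is the identity alignment for duplicate sources:
  merging a source with an exact copy of itself changes nothing, because
  entity identity is (agent, local id).
- Validation never raises; it returns a report listing every violation
  (missing endpoints, empty attribution, unregistered agents, kind
  breaches, missing inverse edges, cycles). Operations that require a
  valid graph (closure, depth, serialization, fact sheet) raise
  `InvalidGraphError` wrapping that report.

## Known limitations

- No description-logic reasoning: OWL restriction semantics are
  represented at the data level only; no consistency checking over
  instance data.
- Phenotype-level logical conflicts are retained by design, never
  detected or resolved.
- Per-source label/xref recovery in views relies on the in-memory
  contribution log; after a Turtle round-trip, views still restrict
  attribution correctly but cannot split unioned labels by source.
- Alignment is pairwise rows; quality of the integration is bounded by
  the expert table, as intended — no automatic matching is attempted.
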