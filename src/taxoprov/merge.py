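"""Integration of several source documents under an expert alignment.

The merge is a *loose* integration: every source's entities and statements
survive, rewritten onto canonical identifiers, with attribution recording
exactly which agents asserted what.  Nothing is reconciled away — a
disorder placed in a group by one source and sub-typed by another keeps
both placements side by side, each with its own provenance; conflicting
phenotype assertions (different frequency qualifiers included) coexist.

Canonical ids are minted deterministically (BD… for disorders, BDG… for
groups, GENE… for genes, 7-digit zero padding; phenotype and
inheritance-mode CURIEs pass through unchanged), so the merge is
independent of the order in which the sources are supplied.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import (
    DuplicateLocalIdError,
    InvalidGraphError,
    KindClashAcrossSourcesError,
    UnknownAlignedIdError,
    UnresolvableKindError,
)
from .model import (
    EntityKind,
    EntityRecord,
    KnowledgeGraph,
    Predicate,
    Statement,
    classify_node_kind,
    validate,
)
from .source_io import AlignmentTable, Decision, SourceDocument

#: canonical id prefix per minted kind
_PREFIX = {EntityKind.DISORDER: "BD", EntityKind.GROUP: "BDG",
           EntityKind.GENE: "GENE"}

SourceKey = tuple[str, str]  # (source agent id, source-local id)


@dataclass(frozen=True)
class CanonicalIdMap:
    """Total mapping (source agent, local id) → canonical id."""

    mapping: Mapping[SourceKey, str]
    kinds: Mapping[str, EntityKind]
    #: canonical ids that arose from a cluster of two or more source ids
    aligned: frozenset[str]

    def __getitem__(self, key: SourceKey) -> str:
        return self.mapping[key]


@dataclass(frozen=True)
class MergeReport:
    """Bookkeeping of one merge, for comparative analysis downstream."""

    entity_counts: Mapping[str, Mapping[str, int]]  # agent -> kind -> n
    aligned_count: int
    unaligned_counts: Mapping[str, int]
    kind_conflicts: tuple[tuple[str, dict, str], ...]
    statement_counts: Mapping[str, Mapping[str, int]]
    xref_clashes: tuple[tuple[str, str, tuple[str, ...]], ...]

    def to_dict(self) -> dict:
        return {
            "entity_counts": {a: dict(k) for a, k in self.entity_counts.items()},
            "aligned_count": self.aligned_count,
            "unaligned_counts": dict(self.unaligned_counts),
            "kind_conflicts": [list(c) for c in self.kind_conflicts],
            "statement_counts": {p: dict(c)
                                 for p, c in self.statement_counts.items()},
            "xref_clashes": [[cid, ns, list(vals)]
                             for cid, ns, vals in self.xref_clashes],
        }


def resolve_kind(decision: Decision, left_kind: EntityKind,
                 right_kind: EntityKind,
                 heuristic_verdict: EntityKind | None = None) -> EntityKind:
    """Settle the group-vs-disorder nature of an aligned pair.

    Precedence: an explicit expert decision, then agreement of the
    declared kinds, then the children-based heuristic verdict.
    """
    if decision is Decision.GROUP:
        return EntityKind.GROUP
    if decision is Decision.DISORDER:
        return EntityKind.DISORDER
    if left_kind is right_kind:
        return left_kind
    if heuristic_verdict is not None:
        return heuristic_verdict
    raise UnresolvableKindError(
        f"declared kinds disagree ({left_kind.value} vs {right_kind.value}) "
        "with decision AUTO and no heuristic verdict")


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[SourceKey, SourceKey] = {}

    def find(self, key: SourceKey) -> SourceKey:
        self.parent.setdefault(key, key)
        root = key
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[key] != root:
            self.parent[key], key = root, self.parent[key]
        return root

    def union(self, a: SourceKey, b: SourceKey) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller key becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _index_entities(sources: Sequence[SourceDocument]
                    ) -> dict[SourceKey, EntityRecord]:
    index: dict[SourceKey, EntityRecord] = {}
    for doc in sources:
        for record in doc.entities:
            key = (doc.agent.id, record.id)
            prior = index.get(key)
            if prior is not None and prior.kind is not record.kind:
                raise DuplicateLocalIdError(
                    f"{key} declared with kinds {prior.kind.value} "
                    f"and {record.kind.value}")
            index.setdefault(key, record)
    return index


def build_canonical_map(sources: Sequence[SourceDocument],
                        alignment: AlignmentTable,
                        source_graphs: Mapping[str, KnowledgeGraph] | None = None,
                        ) -> CanonicalIdMap:
    """Mint deterministic canonical ids for all input entities.

    Aligned clusters (the union-find closure of all alignment rows) come
    first, then unaligned entities, each ordered by (agent id, local id);
    equal inputs yield identical maps regardless of source order.
    """
    index = _index_entities(sources)
    uf = _UnionFind()
    decisions: dict[frozenset, Decision] = {}
    for row in alignment.rows:
        left = (row.left_source, row.left_id)
        right = (row.right_source, row.right_id)
        for key in (left, right):
            if key not in index:
                raise UnknownAlignedIdError(
                    f"alignment references undeclared entity {key}")
        uf.union(left, right)
        if row.decision is not Decision.AUTO:
            decisions[frozenset((left, right))] = row.decision

    clusters: dict[SourceKey, list[SourceKey]] = {}
    for key in sorted(index):
        clusters.setdefault(uf.find(key), []).append(key)
    ordered = sorted(clusters.values(), key=lambda members: members[0])
    aligned = [c for c in ordered if len(c) > 1]
    singles = [c for c in ordered if len(c) == 1]

    graphs: dict[str, KnowledgeGraph] = dict(source_graphs or {})

    def heuristic(key: SourceKey) -> EntityKind | None:
        """Children-based verdict; None when the node has no children in
        its source (the declared-kind fallback carries no information)."""
        agent_id, local_id = key
        if agent_id not in graphs:
            doc = next(d for d in sources if d.agent.id == agent_id)
            graphs[agent_id] = doc.to_graph()
        graph = graphs[agent_id]
        has_children = any(
            s == local_id and p in (Predicate.MEMBER, Predicate.NARROWER_T)
            for (s, p, _o, _q) in graph.statement_keys())
        if not has_children:
            return None
        return classify_node_kind(graph, local_id)

    def cluster_kind(members: list[SourceKey]) -> EntityKind:
        kinds = {index[m].kind for m in members}
        if len(kinds) == 1:
            kind = kinds.pop()
            # an explicit expert decision may override even agreement
            explicit = {decisions[pair] for pair in decisions
                        if pair <= frozenset(members)}
            if len(explicit) == 1:
                return EntityKind(next(iter(explicit)).value)
            return kind
        if not kinds <= {EntityKind.GROUP, EntityKind.DISORDER}:
            raise KindClashAcrossSourcesError(
                f"cluster {members} mixes kinds "
                f"{sorted(k.value for k in kinds)}")
        explicit = {decisions[pair] for pair in decisions
                    if pair <= frozenset(members)}
        if len(explicit) > 1:
            raise KindClashAcrossSourcesError(
                f"cluster {members} carries conflicting expert decisions")
        if explicit:
            return EntityKind(explicit.pop().value)
        verdicts = {v for v in (heuristic(m) for m in members)
                    if v is not None}
        if len(verdicts) == 1:
            return verdicts.pop()
        raise KindClashAcrossSourcesError(
            f"cluster {members}: kinds disagree, decision AUTO and the "
            "children heuristic is inconclusive")

    mapping: dict[SourceKey, str] = {}
    kinds_out: dict[str, EntityKind] = {}
    aligned_ids: set[str] = set()
    counters = {prefix: 0 for prefix in _PREFIX.values()}

    def mint(members: list[SourceKey]) -> None:
        kind = cluster_kind(members)
        if kind in _PREFIX:
            prefix = _PREFIX[kind]
            counters[prefix] += 1
            canonical = f"{prefix}{counters[prefix]:07d}"
        else:
            # HP-style CURIEs pass through unchanged
            canonical = min(local for (_a, local) in members)
        for member in members:
            mapping[member] = canonical
        kinds_out[canonical] = kind
        if len(members) > 1:
            aligned_ids.add(canonical)

    for members in aligned:
        mint(members)
    for members in singles:
        mint(members)

    return CanonicalIdMap(mapping=mapping, kinds=kinds_out,
                          aligned=frozenset(aligned_ids))


def canonicalize_source(doc: SourceDocument, cmap: CanonicalIdMap,
                        ) -> KnowledgeGraph:
    """A single source's graph rewritten onto canonical ids — the image a
    lossless merge must contain, and what a provenance view should
    recover."""
    graph = KnowledgeGraph(graph_id=doc.agent.id)
    for agent in doc.all_agents():
        graph.register_agent(agent.id, agent.label)
    for record in doc.entities:
        canonical = cmap[(doc.agent.id, record.id)]
        graph.add_entity(replace(record, id=canonical,
                                 kind=cmap.kinds[canonical]))
    for stmt in doc.statements:
        graph.add_statement(replace(
            stmt,
            subject=cmap[(doc.agent.id, stmt.subject)],
            object=cmap[(doc.agent.id, stmt.object)],
        ))
    return graph


def merge(sources: Sequence[SourceDocument], alignment: AlignmentTable,
          ) -> tuple[KnowledgeGraph, MergeReport]:
    """Integrate the sources into one provenance-annotated graph.

    Entities and statements are unioned under the canonical map; identical
    assertions from several sources collapse into one statement attributed
    to all of them.  Sources are processed in lexicographic agent order,
    so the first source (in that order) to contribute an entity supplies
    its preferred label and the merge is independent of call order.
    """
    if not sources:
        raise ValueError("merge requires at least one source document")
    docs = sorted(sources, key=lambda d: (d.agent.id, d.name, d.version))
    source_graphs = {doc.agent.id: doc.to_graph() for doc in docs}
    cmap = build_canonical_map(docs, alignment, source_graphs)

    merged = KnowledgeGraph(graph_id="merged:" + "+".join(
        sorted({d.agent.id for d in docs})))
    for doc in docs:
        for agent in doc.all_agents():
            merged.register_agent(agent.id, agent.label)

    kind_conflicts: list[tuple[str, dict, str]] = []
    declared: dict[str, dict[str, str]] = {}
    for doc in docs:
        for record in doc.entities:
            canonical = cmap[(doc.agent.id, record.id)]
            declared.setdefault(canonical, {})[doc.agent.id] = record.kind.value
            merged.add_entity(replace(record, id=canonical,
                                      kind=cmap.kinds[canonical]))
    for canonical, by_agent in sorted(declared.items()):
        if len(set(by_agent.values())) > 1:
            kind_conflicts.append(
                (canonical, dict(sorted(by_agent.items())),
                 cmap.kinds[canonical].value))

    for doc in docs:
        for stmt in doc.statements:
            merged.add_statement(replace(
                stmt,
                subject=cmap[(doc.agent.id, stmt.subject)],
                object=cmap[(doc.agent.id, stmt.object)],
            ))

    report = validate(merged)
    if not report.ok:
        raise InvalidGraphError(report)

    entity_counts: dict[str, dict[str, int]] = {}
    unaligned: dict[str, int] = {}
    for doc in docs:
        counts = entity_counts.setdefault(doc.agent.id,
                                          {k.value: 0 for k in EntityKind})
        unaligned.setdefault(doc.agent.id, 0)
        for record in doc.entities:
            counts[record.kind.value] += 1
            if cmap[(doc.agent.id, record.id)] not in cmap.aligned:
                unaligned[doc.agent.id] += 1

    statement_counts: dict[str, dict[str, int]] = {
        p.value: {"total": 0, "single_source": 0, "multi_source": 0}
        for p in Predicate}
    for key in merged.statement_keys():
        agents = merged.statement_agents(key)
        bucket = statement_counts[key[1].value]
        bucket["total"] += 1
        bucket["single_source" if len(agents) == 1 else "multi_source"] += 1

    xref_clashes = tuple(
        (entity_id, ns, tuple(sorted(values)))
        for entity_id, record in sorted(merged.entities.items())
        for ns, values in sorted(record.xrefs.items())
        if len(values) > 1
    )

    return merged, MergeReport(
        entity_counts=entity_counts,
        aligned_count=len(cmap.aligned),
        unaligned_counts=unaligned,
        kind_conflicts=tuple(kind_conflicts),
        statement_counts=statement_counts,
        xref_clashes=xref_clashes,
    )
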