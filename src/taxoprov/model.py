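"""In-memory model for provenance-annotated classification graphs.

A :class:`KnowledgeGraph` holds the integrated (or per-source) view of a
disease-classification domain: disorder *groups* behave like SKOS
Collections, while disorders, genes, phenotypes and modes of inheritance
behave like SKOS Concepts.  Two structural relations build the hierarchy —

* ``MEMBER`` (skos:member): a group contains a disorder or a nested group;
* ``NARROWER_T`` (skos:narrowerTransitive): a disorder *has narrower*
  sub-type, i.e. the subject is the broader disorder.  Its inverse
  ``BROADER_T`` (skos:broaderTransitive) is materialized automatically so
  both directions are always present with identical attribution.

Three descriptive relations attach genes, phenotypes (optionally qualified
by an Orphanet-style frequency of occurrence) and inheritance modes to
disorders.

Every entity and every statement carries a non-empty set of provenance
agents (prov:wasAttributedTo).  Re-adding an entity or statement never
replaces anything: labels, cross-references and attribution sets are
unioned, which is what lets several sources assert the same fact and be
credited jointly.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    CycleError,
    DanglingEndpointError,
    EmptyAttributionError,
    InvalidGraphError,
    KindClashError,
    KindConstraintError,
    NotClassifiableError,
    UnknownEntityError,
)


class EntityKind(str, Enum):
    """Closed enumeration of node kinds.

    GROUP has SKOS Collection semantics; the other four have SKOS Concept
    semantics.
    """

    GROUP = "GROUP"
    DISORDER = "DISORDER"
    GENE = "GENE"
    PHENOTYPE = "PHENOTYPE"
    INHERITANCE_MODE = "INHERITANCE_MODE"


class Predicate(str, Enum):
    """Closed enumeration of edge types.

    ``NARROWER_T(a, b)`` reads "a has narrower b" — a is the broader
    disorder, matching skos:narrowerTransitive.  ``BROADER_T`` is its
    inverse ("a has broader b").
    """

    MEMBER = "MEMBER"
    NARROWER_T = "NARROWER_T"
    BROADER_T = "BROADER_T"
    ASSOCIATED_GENE = "ASSOCIATED_GENE"
    ASSOCIATED_PHENOTYPE = "ASSOCIATED_PHENOTYPE"
    MODE_OF_INHERITANCE = "MODE_OF_INHERITANCE"


class FrequencyQualifier(str, Enum):
    """Degree of occurrence of a phenotype within a disorder.

    Only valid on ASSOCIATED_PHENOTYPE statements; an absent qualifier is
    normalized to UNSPECIFIED.
    """

    OBLIGATE = "obligate"
    VERY_FREQUENT = "very_frequent"
    FREQUENT = "frequent"
    OCCASIONAL = "occasional"
    VERY_RARE = "very_rare"
    UNSPECIFIED = "unspecified"


#: subject-kind / object-kind constraints per predicate
DOMAIN_RANGE: dict[Predicate, tuple[frozenset[EntityKind], frozenset[EntityKind]]] = {
    Predicate.MEMBER: (
        frozenset({EntityKind.GROUP}),
        frozenset({EntityKind.GROUP, EntityKind.DISORDER}),
    ),
    Predicate.NARROWER_T: (
        frozenset({EntityKind.DISORDER}),
        frozenset({EntityKind.DISORDER}),
    ),
    Predicate.BROADER_T: (
        frozenset({EntityKind.DISORDER}),
        frozenset({EntityKind.DISORDER}),
    ),
    Predicate.ASSOCIATED_GENE: (
        frozenset({EntityKind.DISORDER}),
        frozenset({EntityKind.GENE}),
    ),
    Predicate.ASSOCIATED_PHENOTYPE: (
        frozenset({EntityKind.DISORDER}),
        frozenset({EntityKind.PHENOTYPE}),
    ),
    Predicate.MODE_OF_INHERITANCE: (
        frozenset({EntityKind.DISORDER}),
        frozenset({EntityKind.INHERITANCE_MODE}),
    ),
}

_INVERSE = {Predicate.NARROWER_T: Predicate.BROADER_T,
            Predicate.BROADER_T: Predicate.NARROWER_T}

#: statement identity: (subject, predicate, object, qualifier)
StatementKey = tuple[str, Predicate, str, FrequencyQualifier]


def _freeze_xrefs(xrefs: Mapping[str, object] | None) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for ns, values in (xrefs or {}).items():
        if isinstance(values, str):
            values = [values]
        vals = frozenset(str(v) for v in values)
        if not vals or any(not v for v in vals):
            raise ValueError(f"empty xref value for namespace {ns!r}")
        out[ns] = vals
    return out


@dataclass(frozen=True)
class EntityRecord:
    """One node: group, disorder, gene, phenotype or inheritance mode."""

    id: str
    kind: EntityKind
    label: str
    alt_labels: frozenset[str] = frozenset()
    xrefs: Mapping[str, frozenset[str]] = field(default_factory=dict)
    attributed_to: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("entity id must be non-empty")
        object.__setattr__(self, "kind", EntityKind(self.kind))
        object.__setattr__(self, "alt_labels", frozenset(self.alt_labels))
        object.__setattr__(self, "xrefs", _freeze_xrefs(self.xrefs))
        object.__setattr__(self, "attributed_to", frozenset(self.attributed_to))


@dataclass(frozen=True)
class Statement:
    """One provenance-annotated edge.

    Identity is (subject, predicate, object, qualifier): the same
    disorder–phenotype pair asserted with two different frequency
    qualifiers yields two distinct statements, so each source's assertion
    is preserved verbatim.
    """

    subject: str
    predicate: Predicate
    object: str
    qualifier: FrequencyQualifier = FrequencyQualifier.UNSPECIFIED
    attributed_to: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicate", Predicate(self.predicate))
        qual = self.qualifier
        if qual is None:
            qual = FrequencyQualifier.UNSPECIFIED
        object.__setattr__(self, "qualifier", FrequencyQualifier(qual))
        object.__setattr__(self, "attributed_to", frozenset(self.attributed_to))

    @property
    def key(self) -> StatementKey:
        return (self.subject, self.predicate, self.object, self.qualifier)


@dataclass(frozen=True)
class Violation:
    code: str
    subjects: tuple[str, ...]
    message: str


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[Violation, ...]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.ok


class KnowledgeGraph:
    """Entities + statements + agent registry.

    Mutating operations (:meth:`add_entity`, :meth:`add_statement`) are
    idempotent and attribution-monotone, and return the graph so calls can
    be chained.
    """

    def __init__(self, graph_id: str = "graph"):
        self.graph_id = graph_id
        self.agents: dict[str, str] = {}
        self.entities: dict[str, EntityRecord] = {}
        self._statements: dict[StatementKey, set[str]] = {}
        self._contributions: dict[str, list[EntityRecord]] = {}
        # adjacency caches for fast cycle checks at insertion time
        self._narrower: dict[str, set[str]] = {}  # broader -> narrower disorders
        self._members: dict[str, set[str]] = {}   # group -> nested child groups

    # -- agents -------------------------------------------------------------

    def register_agent(self, agent_id: str, label: str | None = None) -> "KnowledgeGraph":
        if not agent_id:
            raise ValueError("agent id must be non-empty")
        if agent_id not in self.agents:
            self.agents[agent_id] = label if label is not None else agent_id
        elif label is not None and self.agents[agent_id] == agent_id:
            self.agents[agent_id] = label
        return self

    # -- entities -----------------------------------------------------------

    def add_entity(self, record: EntityRecord) -> "KnowledgeGraph":
        """Insert or union-merge an entity.

        Same id + same kind: labels, alt-labels, xrefs and attribution are
        unioned (the existing preferred label wins; a differing incoming
        label becomes an alt-label).  Same id + different kind raises
        :class:`KindClashError`.
        """
        if not record.attributed_to:
            raise EmptyAttributionError(f"entity {record.id!r} has no attribution")
        existing = self.entities.get(record.id)
        if existing is None:
            self.entities[record.id] = record
        else:
            if existing.kind is not record.kind:
                raise KindClashError(
                    f"{record.id!r} already has kind {existing.kind.value}, "
                    f"cannot re-add as {record.kind.value}"
                )
            alt = set(existing.alt_labels) | set(record.alt_labels)
            if record.label != existing.label:
                alt.add(record.label)
            alt.discard(existing.label)
            xrefs: dict[str, frozenset[str]] = dict(existing.xrefs)
            for ns, vals in record.xrefs.items():
                xrefs[ns] = xrefs.get(ns, frozenset()) | vals
            self.entities[record.id] = replace(
                existing,
                alt_labels=frozenset(alt),
                xrefs=xrefs,
                attributed_to=existing.attributed_to | record.attributed_to,
            )
        for agent in record.attributed_to:
            self.register_agent(agent)
        self._contributions.setdefault(record.id, []).append(record)
        return self

    def contributions(self, entity_id: str) -> tuple[EntityRecord, ...]:
        """The per-add history of an entity, used to rebuild exact
        per-source facets in provenance views."""
        return tuple(self._contributions.get(entity_id, ()))

    # -- statements ---------------------------------------------------------

    def _insert_key(self, key: StatementKey, agents: Iterable[str]) -> None:
        self._statements.setdefault(key, set()).update(agents)
        subject, predicate, obj, _ = key
        if predicate is Predicate.NARROWER_T:
            self._narrower.setdefault(subject, set()).add(obj)
        elif predicate is Predicate.MEMBER and \
                self.entities[obj].kind is EntityKind.GROUP:
            self._members.setdefault(subject, set()).add(obj)

    def add_statement(self, stmt: Statement) -> "KnowledgeGraph":
        """Insert or union-merge a statement.

        Sub-typing edges are inserted together with their materialized
        inverse (same attribution).  An edge that would close a directed
        cycle — among disorder sub-types or among nested groups — raises
        :class:`CycleError` and leaves the graph unchanged.
        """
        if not stmt.attributed_to:
            raise EmptyAttributionError(
                f"statement {stmt.subject} {stmt.predicate.value} {stmt.object} "
                "has no attribution"
            )
        for endpoint in (stmt.subject, stmt.object):
            if endpoint not in self.entities:
                raise DanglingEndpointError(f"unknown entity {endpoint!r}")
        domain, range_ = DOMAIN_RANGE[stmt.predicate]
        skind = self.entities[stmt.subject].kind
        okind = self.entities[stmt.object].kind
        if skind not in domain or okind not in range_:
            raise KindConstraintError(
                f"{stmt.predicate.value} does not admit "
                f"{skind.value} -> {okind.value} "
                f"({stmt.subject} -> {stmt.object})"
            )
        if (stmt.qualifier is not FrequencyQualifier.UNSPECIFIED
                and stmt.predicate is not Predicate.ASSOCIATED_PHENOTYPE):
            raise KindConstraintError(
                "frequency qualifiers are only valid on phenotype associations"
            )
        if stmt.predicate in _INVERSE:
            broader, narrower = (
                (stmt.subject, stmt.object)
                if stmt.predicate is Predicate.NARROWER_T
                else (stmt.object, stmt.subject)
            )
            if broader == narrower or _reachable(self._narrower, narrower, broader):
                raise CycleError(
                    f"sub-typing edge {broader} -> {narrower} would close a cycle"
                )
        if stmt.predicate is Predicate.MEMBER and okind is EntityKind.GROUP:
            if stmt.subject == stmt.object or \
                    _reachable(self._members, stmt.object, stmt.subject):
                raise CycleError(
                    f"group membership {stmt.subject} -> {stmt.object} "
                    "would close a cycle"
                )
        self._insert_key(stmt.key, stmt.attributed_to)
        if stmt.predicate in _INVERSE:
            inverse_key = (stmt.object, _INVERSE[stmt.predicate],
                           stmt.subject, stmt.qualifier)
            self._insert_key(inverse_key, stmt.attributed_to)
        for agent in stmt.attributed_to:
            self.register_agent(agent)
        return self

    @property
    def statements(self) -> tuple[Statement, ...]:
        """All statements, sorted by identity key, with frozen attribution."""
        return tuple(
            Statement(s, p, o, q, frozenset(agents))
            for (s, p, o, q), agents in sorted(
                self._statements.items(),
                key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2], kv[0][3].value),
            )
        )

    def statement_agents(self, key: StatementKey) -> frozenset[str]:
        return frozenset(self._statements[key])

    def statement_keys(self) -> tuple[StatementKey, ...]:
        return tuple(sorted(
            self._statements,
            key=lambda k: (k[0], k[1].value, k[2], k[3].value),
        ))

    def has_statement(self, key: StatementKey) -> bool:
        return key in self._statements

    # -- equality -----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        """Graph equality: equal agent registries, entity maps and
        statement sets with identical attribution (graph_id and the
        contribution log are metadata and do not participate)."""
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.agents == other.agents
            and self.entities == other.entities
            and {k: frozenset(v) for k, v in self._statements.items()}
            == {k: frozenset(v) for k, v in other._statements.items()}
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<KnowledgeGraph {self.graph_id!r}: {len(self.entities)} entities, "
                f"{len(self._statements)} statements, {len(self.agents)} agents>")


def _reachable(adjacency: Mapping[str, set[str]], start: str, goal: str) -> bool:
    stack, seen = [start], {start}
    while stack:
        node = stack.pop()
        if node == goal:
            return True
        for nxt in adjacency.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------

def validate(graph: KnowledgeGraph) -> ValidationReport:
    """Check every structural invariant; violations are report content,
    never exceptions.

    Codes: MissingEndpoint, EmptyAttribution, UnregisteredAgent,
    KindConstraint, MissingInverse, CycleDetected.
    """
    violations: list[Violation] = []

    for entity in graph.entities.values():
        if not entity.attributed_to:
            violations.append(Violation(
                "EmptyAttribution", (entity.id,),
                f"entity {entity.id!r} has an empty attribution set"))
        for agent in sorted(entity.attributed_to):
            if agent not in graph.agents:
                violations.append(Violation(
                    "UnregisteredAgent", (entity.id, agent),
                    f"entity {entity.id!r} attributed to unregistered {agent!r}"))

    for key in graph.statement_keys():
        subject, predicate, obj, qualifier = key
        agents = graph.statement_agents(key)
        sid = f"{subject} {predicate.value} {obj}"
        if not agents:
            violations.append(Violation(
                "EmptyAttribution", (subject, obj),
                f"statement {sid} has an empty attribution set"))
        for agent in sorted(agents):
            if agent not in graph.agents:
                violations.append(Violation(
                    "UnregisteredAgent", (subject, obj, agent),
                    f"statement {sid} attributed to unregistered {agent!r}"))
        missing = [e for e in (subject, obj) if e not in graph.entities]
        if missing:
            violations.append(Violation(
                "MissingEndpoint", tuple(missing),
                f"statement {sid} references unknown entities"))
            continue
        domain, range_ = DOMAIN_RANGE[predicate]
        skind = graph.entities[subject].kind
        okind = graph.entities[obj].kind
        if skind not in domain or okind not in range_:
            violations.append(Violation(
                "KindConstraint", (subject, obj),
                f"{sid}: {skind.value} -> {okind.value} not admitted"))
        if (qualifier is not FrequencyQualifier.UNSPECIFIED
                and predicate is not Predicate.ASSOCIATED_PHENOTYPE):
            violations.append(Violation(
                "KindConstraint", (subject, obj),
                f"{sid}: frequency qualifier on a non-phenotype edge"))
        if predicate in _INVERSE:
            inverse = (obj, _INVERSE[predicate], subject, qualifier)
            if not graph.has_statement(inverse):
                violations.append(Violation(
                    "MissingInverse", (subject, obj),
                    f"{sid} lacks its inverse edge"))
            elif graph.statement_agents(inverse) != agents:
                violations.append(Violation(
                    "MissingInverse", (subject, obj),
                    f"{sid} and its inverse carry different attribution"))

    for code, edges in (
        ("CycleDetected", _subtype_edges(graph)),
        ("CycleDetected", _nested_group_edges(graph)),
    ):
        digraph = nx.DiGraph(edges)
        try:
            cycle = nx.find_cycle(digraph)
        except nx.NetworkXNoCycle:
            continue
        nodes = tuple(dict.fromkeys(n for edge in cycle for n in edge[:2]))
        violations.append(Violation(
            code, nodes, "directed cycle: " + " -> ".join(nodes)))

    return ValidationReport(ok=not violations, violations=tuple(violations))


def _subtype_edges(graph: KnowledgeGraph) -> list[tuple[str, str]]:
    """(broader, narrower) pairs asserted between disorder entities."""
    return [
        (s, o) for (s, p, o, _q) in graph.statement_keys()
        if p is Predicate.NARROWER_T
        and graph.entities.get(s) is not None
        and graph.entities.get(o) is not None
        and graph.entities[s].kind is EntityKind.DISORDER
        and graph.entities[o].kind is EntityKind.DISORDER
    ]


def _nested_group_edges(graph: KnowledgeGraph) -> list[tuple[str, str]]:
    return [
        (s, o) for (s, p, o, _q) in graph.statement_keys()
        if p is Predicate.MEMBER
        and graph.entities.get(s) is not None
        and graph.entities.get(o) is not None
        and graph.entities[o].kind is EntityKind.GROUP
    ]


def hierarchy_edges(graph: KnowledgeGraph) -> list[tuple[str, str]]:
    """Parent→child containment edges: group membership plus sub-typing."""
    edges = set()
    for (s, p, o, _q) in graph.statement_keys():
        if p is Predicate.MEMBER or p is Predicate.NARROWER_T:
            edges.add((s, o))
    return sorted(edges)


def broader_closure(graph: KnowledgeGraph) -> set[tuple[str, str]]:
    """Transitive closure of the asserted sub-typing relation.

    Returns ordered (broader, narrower) disorder-id pairs; the asserted
    pairs are a subset, the result is transitive and — because cycles are
    rejected at insertion — irreflexive.
    """
    report = validate(graph)
    if not report.ok:
        raise InvalidGraphError(report)
    digraph = nx.DiGraph(_subtype_edges(graph))
    closure: set[tuple[str, str]] = set()
    for node in digraph.nodes:
        for descendant in nx.descendants(digraph, node):
            closure.add((node, descendant))
    return closure


def classify_node_kind(graph: KnowledgeGraph, node_id: str) -> EntityKind:
    """Advisory group-vs-disorder heuristic, decided by the node's children.

    Children are the objects of the node's MEMBER and sub-typing
    statements.  All children sub-type-linked disorders → DISORDER; any
    group child, or any child held via plain membership → GROUP; no
    children → the declared kind.  Never mutates the graph.
    """
    record = graph.entities.get(node_id)
    if record is None:
        raise UnknownEntityError(f"unknown entity {node_id!r}")
    if record.kind not in (EntityKind.GROUP, EntityKind.DISORDER):
        raise NotClassifiableError(
            f"{node_id!r} has kind {record.kind.value}; only groups and "
            "disorders can be classified")
    children = [
        (o, p) for (s, p, o, _q) in graph.statement_keys()
        if s == node_id and p in (Predicate.MEMBER, Predicate.NARROWER_T)
    ]
    if not children:
        return record.kind
    if all(
        p is Predicate.NARROWER_T
        and graph.entities[o].kind is EntityKind.DISORDER
        for o, p in children
    ):
        return EntityKind.DISORDER
    return EntityKind.GROUP
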