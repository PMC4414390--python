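"""Readers and writers for the formats the tool exchanges.

* source classification documents — a small JSON dialect, one file per
  expert source (groups, disorders, sub-typing, gene/phenotype
  associations with optional frequency qualifiers);
* expert alignment tables — 6-column TSV, the manual cross-source
  mapping consumed as data;
* the merged-graph RDF Turtle dialect — punned entities, one plain triple
  per statement plus one owl:Axiom reification node carrying the
  prov:wasAttributedTo annotations, canonically ordered so equal graphs
  serialize byte-identically;
* fact sheets — headline counts of a graph.

Turtle is parsed with rdflib; the writer orders and prints the triples
itself because the canonical layout (entities before statements, each
sorted lexicographically) is part of the dialect contract.
"""
from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping
from urllib.parse import quote, unquote

import rdflib
from rdflib import Literal, URIRef
from rdflib.namespace import OWL, PROV, RDF, RDFS, SKOS

from .errors import (
    CycleError,
    DanglingEndpointError,
    DialectError,
    EmptyAttributionError,
    HeaderMismatchError,
    InvalidGraphError,
    KindConstraintError,
    NonFunctionalAlignmentError,
    SchemaError,
    UnknownDecisionError,
)
from .model import (
    EntityKind,
    EntityRecord,
    FrequencyQualifier,
    KnowledgeGraph,
    Predicate,
    Statement,
    validate,
)

DEFAULT_NAMESPACE = "http://purl.org/skeletome/rbdo#"
HP_NAMESPACE = "http://purl.obolibrary.org/obo/HP_"

_HP_CURIE = re.compile(r"^HP:(\d+)$")
_PN_LOCAL_SAFE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.\-]*$")

#: default synonyms accepted (case-insensitively) for frequency tokens
DEFAULT_FREQUENCY_SYNONYMS: dict[str, str] = {
    "very frequent": "very_frequent",
    "very frequently": "very_frequent",
    "frequently": "frequent",
    "very rare": "very_rare",
    "very rarely": "very_rare",
    "occasionally": "occasional",
}


# ---------------------------------------------------------------------------
# source documents (JSON)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentRef:
    id: str
    label: str


@dataclass(frozen=True)
class SourceDocument:
    """One expert source: its agent, declared entities and statements.

    Attribution on entities/statements defaults to the source agent unless
    a record overrides it (e.g. phenotype annotations credited to a
    secondary agent).
    """

    agent: AgentRef
    entities: tuple[EntityRecord, ...]
    statements: tuple[Statement, ...]
    extra_agents: tuple[AgentRef, ...] = ()
    name: str = ""
    version: str = ""

    def all_agents(self) -> tuple[AgentRef, ...]:
        return (self.agent,) + self.extra_agents

    def to_graph(self) -> KnowledgeGraph:
        """Materialize the document as a validated KnowledgeGraph."""
        graph = KnowledgeGraph(graph_id=self.agent.id)
        for agent in self.all_agents():
            graph.register_agent(agent.id, agent.label)
        for record in self.entities:
            graph.add_entity(record)
        for stmt in self.statements:
            graph.add_statement(stmt)
        return graph

    def to_json(self) -> str:
        payload = {
            "source": {"id": self.agent.id, "label": self.agent.label,
                       "version": self.version, "name": self.name},
            "agents": [{"id": a.id, "label": a.label} for a in self.extra_agents],
            "entities": [
                {
                    "id": e.id,
                    "kind": e.kind.value.lower(),
                    "label": e.label,
                    **({"alt_labels": sorted(e.alt_labels)} if e.alt_labels else {}),
                    **({"xrefs": {ns: sorted(vs) for ns, vs in sorted(e.xrefs.items())}}
                       if e.xrefs else {}),
                    **({"attributed_to": sorted(e.attributed_to)}
                       if e.attributed_to != frozenset({self.agent.id}) else {}),
                }
                for e in self.entities
            ],
            "statements": [
                {
                    "subject": s.subject,
                    "predicate": s.predicate.value.lower(),
                    "object": s.object,
                    **({"qualifier": s.qualifier.value}
                       if s.qualifier is not FrequencyQualifier.UNSPECIFIED else {}),
                    **({"attributed_to": sorted(s.attributed_to)}
                       if s.attributed_to != frozenset({self.agent.id}) else {}),
                }
                for s in self.statements
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _require(obj, path: str, key: str, types, optional: bool = False):
    if key not in obj:
        if optional:
            return None
        raise SchemaError(f"{path}.{key}", "missing required field")
    value = obj[key]
    if not isinstance(value, types):
        raise SchemaError(f"{path}.{key}",
                          f"expected {getattr(types, '__name__', types)}")
    return value


def _parse_qualifier(token: str, path: str,
                     synonyms: Mapping[str, str]) -> FrequencyQualifier:
    norm = token.strip().lower()
    norm = synonyms.get(norm, norm)
    try:
        return FrequencyQualifier(norm)
    except ValueError:
        raise SchemaError(path, f"unknown frequency qualifier {token!r}") from None


def read_source(source: str | io.TextIOBase,
                frequency_synonyms: Mapping[str, str] | None = None
                ) -> SourceDocument:
    """Parse and validate a JSON source classification document.

    Predicates, kinds and qualifiers are accepted case-insensitively.
    Referential integrity and acyclicity are checked by materializing the
    graph, so a dangling statement endpoint or a sub-typing cycle is
    rejected here, not at merge time.
    """
    text = source.read() if hasattr(source, "read") else source
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError("$", f"not valid JSON: {exc}") from None
    if not isinstance(data, dict):
        raise SchemaError("$", "document must be a JSON object")

    synonyms = dict(DEFAULT_FREQUENCY_SYNONYMS)
    synonyms.update({k.lower(): v for k, v in (frequency_synonyms or {}).items()})

    src = _require(data, "$", "source", dict)
    agent_id = _require(src, "$.source", "id", str)
    if not agent_id:
        raise SchemaError("$.source.id", "agent id must be non-empty")
    agent = AgentRef(agent_id, _require(src, "$.source", "label", str,
                                        optional=True) or agent_id)
    version = _require(src, "$.source", "version", str, optional=True) or ""
    name = _require(src, "$.source", "name", str, optional=True) or ""

    extra_agents = []
    for i, item in enumerate(data.get("agents") or []):
        path = f"$.agents[{i}]"
        if not isinstance(item, dict):
            raise SchemaError(path, "expected object")
        aid = _require(item, path, "id", str)
        extra_agents.append(AgentRef(aid, _require(item, path, "label", str,
                                                   optional=True) or aid))

    default_attribution = frozenset({agent.id})

    entities = []
    for i, item in enumerate(_require(data, "$", "entities", list)):
        path = f"$.entities[{i}]"
        if not isinstance(item, dict):
            raise SchemaError(path, "expected object")
        kind_token = _require(item, path, "kind", str).strip().upper()
        try:
            kind = EntityKind(kind_token)
        except ValueError:
            raise SchemaError(f"{path}.kind",
                              f"unknown kind {item['kind']!r}") from None
        attributed = item.get("attributed_to")
        if attributed is not None:
            if not isinstance(attributed, list) or not attributed:
                raise SchemaError(f"{path}.attributed_to",
                                  "expected non-empty list of agent ids")
            attribution = frozenset(str(a) for a in attributed)
        else:
            attribution = default_attribution
        xrefs = item.get("xrefs") or {}
        if not isinstance(xrefs, dict):
            raise SchemaError(f"{path}.xrefs", "expected object")
        try:
            entities.append(EntityRecord(
                id=_require(item, path, "id", str),
                kind=kind,
                label=_require(item, path, "label", str),
                alt_labels=frozenset(
                    _require(item, path, "alt_labels", list, optional=True) or []),
                xrefs=xrefs,
                attributed_to=attribution,
            ))
        except ValueError as exc:
            raise SchemaError(path, str(exc)) from None

    statements = []
    for i, item in enumerate(_require(data, "$", "statements", list)):
        path = f"$.statements[{i}]"
        if not isinstance(item, dict):
            raise SchemaError(path, "expected object")
        pred_token = _require(item, path, "predicate", str).strip().upper()
        try:
            predicate = Predicate(pred_token)
        except ValueError:
            raise SchemaError(f"{path}.predicate",
                              f"unknown predicate {item['predicate']!r}") from None
        qualifier = FrequencyQualifier.UNSPECIFIED
        if item.get("qualifier") is not None:
            qualifier = _parse_qualifier(str(item["qualifier"]),
                                         f"{path}.qualifier", synonyms)
        attributed = item.get("attributed_to")
        if attributed is not None:
            if not isinstance(attributed, list) or not attributed:
                raise SchemaError(f"{path}.attributed_to",
                                  "expected non-empty list of agent ids")
            attribution = frozenset(str(a) for a in attributed)
        else:
            attribution = default_attribution
        statements.append(Statement(
            subject=_require(item, path, "subject", str),
            predicate=predicate,
            object=_require(item, path, "object", str),
            qualifier=qualifier,
            attributed_to=attribution,
        ))

    document = SourceDocument(agent=agent, entities=tuple(entities),
                              statements=tuple(statements),
                              extra_agents=tuple(extra_agents),
                              name=name, version=version)
    # materialize once to surface dangling endpoints / cycles / kind breaches
    try:
        document.to_graph()
    except (DanglingEndpointError, CycleError, KindConstraintError,
            EmptyAttributionError):
        raise
    return document


# ---------------------------------------------------------------------------
# alignment tables (TSV)
# ---------------------------------------------------------------------------

class Decision(str, Enum):
    """Expert verdict on the kind of an aligned pair."""

    GROUP = "GROUP"
    DISORDER = "DISORDER"
    AUTO = "AUTO"


ALIGNMENT_HEADER = ("left_source", "left_id", "right_source", "right_id",
                    "decision", "note")


@dataclass(frozen=True)
class AlignmentRow:
    left_source: str
    left_id: str
    right_source: str
    right_id: str
    decision: Decision = Decision.AUTO
    note: str = ""


@dataclass(frozen=True)
class AlignmentTable:
    """Expert cross-source equivalences; functional per source pair."""

    rows: tuple[AlignmentRow, ...] = ()

    def to_tsv(self) -> str:
        lines = ["\t".join(ALIGNMENT_HEADER)]
        for r in self.rows:
            lines.append("\t".join((r.left_source, r.left_id, r.right_source,
                                    r.right_id, r.decision.value, r.note)))
        return "\n".join(lines) + "\n"


def _check_functional(rows: Iterable[AlignmentRow]) -> None:
    directed: dict[tuple[str, str, str], tuple[str, str]] = {}
    decisions: dict[frozenset, Decision] = {}
    for row in rows:
        pair_id = frozenset([(row.left_source, row.left_id),
                             (row.right_source, row.right_id)])
        prior = decisions.get(pair_id)
        if prior is not None and prior is not row.decision:
            raise NonFunctionalAlignmentError(
                f"pair {row.left_id!r}/{row.right_id!r} aligned with two "
                f"different decisions ({prior.value} vs {row.decision.value})")
        decisions[pair_id] = row.decision
        for (src_a, id_a), (src_b, id_b) in (
            ((row.left_source, row.left_id), (row.right_source, row.right_id)),
            ((row.right_source, row.right_id), (row.left_source, row.left_id)),
        ):
            key = (src_a, id_a, src_b)
            counterpart = (src_b, id_b)
            if key in directed and directed[key] != counterpart:
                raise NonFunctionalAlignmentError(
                    f"{src_a}:{id_a} aligned to both {directed[key][1]!r} and "
                    f"{id_b!r} in source {src_b}")
            directed[key] = counterpart


def read_alignment(source: str | io.TextIOBase) -> AlignmentTable:
    """Parse an expert alignment TSV (UTF-8, literal tabs, '#' comments)."""
    text = source.read() if hasattr(source, "read") else source
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise HeaderMismatchError("alignment file is empty")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != ALIGNMENT_HEADER:
        raise HeaderMismatchError(
            f"expected header {' '.join(ALIGNMENT_HEADER)!r}, got {lines[0]!r}")
    rows: list[AlignmentRow] = []
    seen: set[AlignmentRow] = set()
    for n, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) == 5:
            fields.append("")
        if len(fields) != 6:
            raise SchemaError(f"line {n}", f"expected 6 tab-separated fields, "
                                           f"got {len(fields)}")
        token = fields[4].strip().upper()
        try:
            decision = Decision(token)
        except ValueError:
            raise UnknownDecisionError(
                f"line {n}: unknown decision {fields[4]!r}") from None
        row = AlignmentRow(fields[0], fields[1], fields[2], fields[3],
                           decision, fields[5])
        if row not in seen:
            seen.add(row)
            rows.append(row)
    _check_functional(rows)
    return AlignmentTable(rows=tuple(rows))


# ---------------------------------------------------------------------------
# Turtle dialect
# ---------------------------------------------------------------------------

PREDICATE_PROPERTY: dict[Predicate, tuple[str, str]] = {
    # predicate -> (prefixed name for writing, suffix kind)
    Predicate.MEMBER: ("skos:member", "skos"),
    Predicate.NARROWER_T: ("skos:narrowerTransitive", "skos"),
    Predicate.BROADER_T: ("skos:broaderTransitive", "skos"),
    Predicate.ASSOCIATED_GENE: ("rbdo:associated_gene", "rbdo"),
    Predicate.ASSOCIATED_PHENOTYPE: ("rbdo:associated_phenotype", "rbdo"),
    Predicate.MODE_OF_INHERITANCE: ("rbdo:mode_of_inheritance", "rbdo"),
}

_RESERVED_LOCAL = {"BoneDisorder", "BoneDisorderGroup", "Gene", "frequency",
                   "associated_gene", "associated_phenotype",
                   "mode_of_inheritance"}


def _agent_namespace(namespace: str) -> str:
    return namespace.rstrip("#/") + "/agent#"


class _Dialect:
    """IRI <-> id bookkeeping shared by the writer and the reader."""

    def __init__(self, namespace: str = DEFAULT_NAMESPACE):
        self.ns = namespace
        self.agent_ns = _agent_namespace(namespace)

    def entity_ref(self, entity_id: str) -> str:
        hp = _HP_CURIE.match(entity_id)
        if hp:
            return f"hp:{hp.group(1)}"
        if _PN_LOCAL_SAFE.match(entity_id) and not entity_id.endswith(".") \
                and entity_id not in _RESERVED_LOCAL:
            return f"rbdo:{entity_id}"
        return f"<{self.ns}{quote(entity_id, safe='')}>"

    def agent_ref(self, agent_id: str) -> str:
        if _PN_LOCAL_SAFE.match(agent_id) and not agent_id.endswith("."):
            return f"agent:{agent_id}"
        return f"<{self.agent_ns}{quote(agent_id, safe='')}>"

    def entity_iri(self, entity_id: str) -> URIRef:
        hp = _HP_CURIE.match(entity_id)
        if hp:
            return URIRef(HP_NAMESPACE + hp.group(1))
        return URIRef(self.ns + quote(entity_id, safe=""))

    def agent_iri(self, agent_id: str) -> URIRef:
        return URIRef(self.agent_ns + quote(agent_id, safe=""))

    def iri_to_entity_id(self, iri: URIRef) -> str:
        text = str(iri)
        if text.startswith(HP_NAMESPACE):
            return "HP:" + text[len(HP_NAMESPACE):]
        if text.startswith(self.ns):
            return unquote(text[len(self.ns):])
        raise DialectError(f"IRI {text} is outside the dialect namespaces")

    def iri_to_agent_id(self, iri: URIRef) -> str:
        text = str(iri)
        if text.startswith(self.agent_ns):
            return unquote(text[len(self.agent_ns):])
        raise DialectError(f"agent IRI {text} is outside the agent namespace")


_KIND_TYPES: dict[EntityKind, tuple[str, ...]] = {
    EntityKind.GROUP: ("skos:Collection", "rbdo:BoneDisorderGroup"),
    EntityKind.DISORDER: ("owl:Class", "skos:Concept", "rbdo:BoneDisorder"),
    EntityKind.GENE: ("owl:Class", "skos:Concept", "rbdo:Gene"),
    EntityKind.PHENOTYPE: ("owl:Class", "skos:Concept"),
    EntityKind.INHERITANCE_MODE: ("owl:Class", "skos:Concept"),
}

#: phenotypes sit under the phenotypic-abnormality root, inheritance modes
#: under the mode-of-inheritance root (both HPO upper-level terms)
_KIND_ROOT = {EntityKind.PHENOTYPE: "hp:0000118",
              EntityKind.INHERITANCE_MODE: "hp:0000005"}


def write_turtle(graph: KnowledgeGraph, *,
                 namespace: str = DEFAULT_NAMESPACE) -> str:
    """Serialize a valid graph to canonical Turtle.

    Layout: prefixes, ontology header, agents, entities, plain statement
    triples, then one owl:Axiom annotation node per statement — each
    section sorted lexicographically, so equal graphs produce
    byte-identical output.  Disorders (and the other concept kinds) are
    punned: the same IRI is typed owl:Class and skos:Concept.
    """
    report = validate(graph)
    if not report.ok:
        raise InvalidGraphError(report)

    d = _Dialect(namespace)
    out: list[str] = [
        f"@prefix rbdo: <{namespace}> .",
        f"@prefix agent: <{d.agent_ns}> .",
        f"@prefix hp: <{HP_NAMESPACE}> .",
        "@prefix skos: <http://www.w3.org/2004/02/skos/core#> .",
        "@prefix prov: <http://www.w3.org/ns/prov#> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "",
    ]
    if not (graph.agents or graph.entities or graph.statement_keys()):
        return "\n".join(out)

    out.append(f"<{namespace.rstrip('#')}> a owl:Ontology ;")
    out.append(f"    rdfs:label {Literal(graph.graph_id).n3()} .")
    out.append("")

    for agent_id in sorted(graph.agents):
        out.append(f"{d.agent_ref(agent_id)} a prov:Agent ;")
        out.append(f"    rdfs:label {Literal(graph.agents[agent_id]).n3()} .")
        out.append("")

    for entity_id in sorted(graph.entities):
        e = graph.entities[entity_id]
        ref = d.entity_ref(entity_id)
        lines = [f"{ref} a {', '.join(_KIND_TYPES[e.kind])}"]
        if e.kind in _KIND_ROOT:
            lines.append(f"    rdfs:subClassOf {_KIND_ROOT[e.kind]}")
        lines.append(f"    rdfs:label {Literal(e.label).n3()}")
        if e.alt_labels:
            alts = ", ".join(Literal(a).n3() for a in sorted(e.alt_labels))
            lines.append(f"    skos:altLabel {alts}")
        for ns_key in sorted(e.xrefs):
            vals = ", ".join(Literal(v).n3() for v in sorted(e.xrefs[ns_key]))
            lines.append(f"    rbdo:{ns_key} {vals}")
        agents = ", ".join(d.agent_ref(a) for a in sorted(e.attributed_to))
        lines.append(f"    prov:wasAttributedTo {agents}")
        out.append(" ;\n".join(lines) + " .")
        out.append("")

    keys = graph.statement_keys()
    plain = sorted({(s, PREDICATE_PROPERTY[p][0], o) for (s, p, o, _q) in keys})
    for s, prop, o in plain:
        out.append(f"{d.entity_ref(s)} {prop} {d.entity_ref(o)} .")
    if plain:
        out.append("")

    for (s, p, o, q) in keys:
        lines = [
            "[] a owl:Axiom",
            f"    owl:annotatedSource {d.entity_ref(s)}",
            f"    owl:annotatedProperty {PREDICATE_PROPERTY[p][0]}",
            f"    owl:annotatedTarget {d.entity_ref(o)}",
        ]
        if q is not FrequencyQualifier.UNSPECIFIED:
            lines.append(f"    rbdo:frequency {Literal(q.value).n3()}")
        agents = ", ".join(d.agent_ref(a)
                           for a in sorted(graph.statement_agents((s, p, o, q))))
        lines.append(f"    prov:wasAttributedTo {agents}")
        out.append(" ;\n".join(lines) + " .")
        out.append("")

    return "\n".join(out)


def _single(rdf_graph: rdflib.Graph, subject, predicate, what: str):
    values = list(rdf_graph.objects(subject, predicate))
    if len(values) != 1:
        raise DialectError(f"{what}: expected exactly one "
                           f"{predicate}, found {len(values)} ({subject})")
    return values[0]


def read_turtle(source: str | io.TextIOBase, *,
                namespace: str = DEFAULT_NAMESPACE) -> KnowledgeGraph:
    """Parse Turtle in the dialect emitted by :func:`write_turtle`.

    ``read_turtle(write_turtle(G)) == G`` for every valid graph G.  Triples
    outside the dialect, axiom nodes missing one of their three
    annotated-triple links, and plain statement triples lacking an axiom
    node all raise :class:`DialectError`.
    """
    text = source.read() if hasattr(source, "read") else source
    rdf = rdflib.Graph()
    try:
        rdf.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises several parser error types
        raise DialectError(f"not parseable as Turtle: {exc}") from None

    d = _Dialect(namespace)
    rbdo = rdflib.Namespace(namespace)
    hp_root_phen = URIRef(HP_NAMESPACE + "0000118")
    hp_root_moi = URIRef(HP_NAMESPACE + "0000005")
    property_to_predicate = {
        SKOS.member: Predicate.MEMBER,
        SKOS.narrowerTransitive: Predicate.NARROWER_T,
        SKOS.broaderTransitive: Predicate.BROADER_T,
        rbdo.associated_gene: Predicate.ASSOCIATED_GENE,
        rbdo.associated_phenotype: Predicate.ASSOCIATED_PHENOTYPE,
        rbdo.mode_of_inheritance: Predicate.MODE_OF_INHERITANCE,
    }

    graph_id = "graph"
    for onto in rdf.subjects(RDF.type, OWL.Ontology):
        label = rdf.value(onto, RDFS.label)
        if label is not None:
            graph_id = str(label)

    graph = KnowledgeGraph(graph_id=graph_id)

    for agent_iri in sorted(rdf.subjects(RDF.type, PROV.Agent)):
        agent_id = d.iri_to_agent_id(agent_iri)
        label = rdf.value(agent_iri, RDFS.label)
        graph.register_agent(agent_id, str(label) if label is not None else agent_id)

    # classify subjects into entity kinds from their type markers
    kinds: dict[URIRef, EntityKind] = {}
    for iri in rdf.subjects(RDF.type, rbdo.BoneDisorder):
        kinds[iri] = EntityKind.DISORDER
    for iri in rdf.subjects(RDF.type, rbdo.BoneDisorderGroup):
        kinds[iri] = EntityKind.GROUP
    for iri in rdf.subjects(RDF.type, SKOS.Collection):
        kinds.setdefault(iri, EntityKind.GROUP)
    for iri in rdf.subjects(RDF.type, rbdo.Gene):
        kinds[iri] = EntityKind.GENE
    for iri in rdf.subjects(RDFS.subClassOf, hp_root_phen):
        kinds[iri] = EntityKind.PHENOTYPE
    for iri in rdf.subjects(RDFS.subClassOf, hp_root_moi):
        kinds[iri] = EntityKind.INHERITANCE_MODE

    axiom_nodes = set(rdf.subjects(RDF.type, OWL.Axiom))

    known_props = set(property_to_predicate)
    for entity_iri in sorted(kinds):
        entity_id = d.iri_to_entity_id(entity_iri)
        label = rdf.value(entity_iri, RDFS.label)
        xrefs: dict[str, set[str]] = {}
        for pred, obj in rdf.predicate_objects(entity_iri):
            if pred in (RDF.type, RDFS.label, RDFS.subClassOf, SKOS.altLabel,
                        PROV.wasAttributedTo):
                continue
            if pred in known_props:
                continue  # statement triple, handled below
            if str(pred).startswith(namespace) and isinstance(obj, Literal):
                xrefs.setdefault(str(pred)[len(namespace):], set()).add(str(obj))
            else:
                raise DialectError(
                    f"triple outside the dialect on {entity_iri}: {pred}")
        attribution = frozenset(
            d.iri_to_agent_id(a)
            for a in rdf.objects(entity_iri, PROV.wasAttributedTo))
        graph.add_entity(EntityRecord(
            id=entity_id,
            kind=kinds[entity_iri],
            label=str(label) if label is not None else entity_id,
            alt_labels=frozenset(
                str(a) for a in rdf.objects(entity_iri, SKOS.altLabel)),
            xrefs=xrefs,
            attributed_to=attribution,
        ))

    statements: list[Statement] = []
    annotated: set[tuple[URIRef, URIRef, URIRef]] = set()
    for node in axiom_nodes:
        src = _single(rdf, node, OWL.annotatedSource, "axiom node")
        prop = _single(rdf, node, OWL.annotatedProperty, "axiom node")
        tgt = _single(rdf, node, OWL.annotatedTarget, "axiom node")
        predicate = property_to_predicate.get(prop)
        if predicate is None:
            raise DialectError(f"axiom node annotates unknown property {prop}")
        qualifier = FrequencyQualifier.UNSPECIFIED
        freq = rdf.value(node, rbdo.frequency)
        if freq is not None:
            try:
                qualifier = FrequencyQualifier(str(freq))
            except ValueError:
                raise DialectError(
                    f"unknown frequency token {str(freq)!r}") from None
        attribution = frozenset(
            d.iri_to_agent_id(a) for a in rdf.objects(node, PROV.wasAttributedTo))
        if (src, prop, tgt) not in rdf:
            raise DialectError(
                f"axiom node without its plain triple: {src} {prop} {tgt}")
        annotated.add((src, prop, tgt))
        subject_id = d.iri_to_entity_id(src)
        object_id = d.iri_to_entity_id(tgt)
        for eid in (subject_id, object_id):
            if eid not in graph.entities:
                raise DanglingEndpointError(
                    f"statement references undeclared entity {eid!r}")
        statements.append(Statement(subject_id, predicate, object_id,
                                    qualifier, attribution))

    # every plain statement triple must carry at least one axiom node
    for s, p, o in rdf:
        if p in known_props and (s, p, o) not in annotated:
            raise DialectError(f"plain triple without an axiom node: {s} {p} {o}")

    for stmt in sorted(statements, key=lambda st: (st.subject, st.predicate.value,
                                                   st.object, st.qualifier.value)):
        graph.add_statement(stmt)
    return graph


# ---------------------------------------------------------------------------
# fact sheet
# ---------------------------------------------------------------------------

RELATIONSHIPS_DEFINED = ("associated_gene", "associated_phenotype",
                         "mode_of_inheritance")


@dataclass(frozen=True)
class FactSheet:
    """Headline counts of a graph, Table-1 style."""

    n_disorders: int
    n_groups: int
    n_genes: int
    n_inheritance_modes: int
    n_total_classes: int
    n_phenotypes_reused: int
    agents: tuple[str, ...]
    relationships: tuple[str, ...] = RELATIONSHIPS_DEFINED
    namespace: str = DEFAULT_NAMESPACE

    def to_dict(self) -> dict:
        return {
            "n_disorders": self.n_disorders,
            "n_groups": self.n_groups,
            "n_genes": self.n_genes,
            "n_inheritance_modes": self.n_inheritance_modes,
            "n_total_classes": self.n_total_classes,
            "n_phenotypes_reused": self.n_phenotypes_reused,
            "agents": list(self.agents),
            "relationships": list(self.relationships),
            "namespace": self.namespace,
        }

    def to_text(self) -> str:
        rows = [
            ("Namespace", self.namespace),
            ("Provenance agents", ", ".join(self.agents) or "-"),
            ("Relationships", ", ".join(self.relationships)),
            ("Disorders", str(self.n_disorders)),
            ("Disorder groups", str(self.n_groups)),
            ("Genes", str(self.n_genes)),
            ("Inheritance modes", str(self.n_inheritance_modes)),
            ("Total classes", str(self.n_total_classes)),
            ("Phenotypes reused", str(self.n_phenotypes_reused)),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in rows)


def fact_sheet(graph: KnowledgeGraph, *,
               namespace: str = DEFAULT_NAMESPACE) -> FactSheet:
    """Tally the graph: entity counts per kind, distinct phenotypes that
    actually appear as association targets, and the agent roster."""
    report = validate(graph)
    if not report.ok:
        raise InvalidGraphError(report)
    counts = {kind: 0 for kind in EntityKind}
    for e in graph.entities.values():
        counts[e.kind] += 1
    reused = {o for (_s, p, o, _q) in graph.statement_keys()
              if p is Predicate.ASSOCIATED_PHENOTYPE}
    total = (counts[EntityKind.DISORDER] + counts[EntityKind.GROUP]
             + counts[EntityKind.GENE] + counts[EntityKind.INHERITANCE_MODE])
    return FactSheet(
        n_disorders=counts[EntityKind.DISORDER],
        n_groups=counts[EntityKind.GROUP],
        n_genes=counts[EntityKind.GENE],
        n_inheritance_modes=counts[EntityKind.INHERITANCE_MODE],
        n_total_classes=total,
        n_phenotypes_reused=len(reused),
        agents=tuple(sorted(graph.agents)),
        namespace=namespace,
    )
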