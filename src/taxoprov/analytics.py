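"""Provenance-filtered views and comparative analytics.

These are the read-side payoff of recording statement-level provenance:

* :func:`provenance_view` — re-create the classification as one source
  (or any agent set) saw it, the executable form of backwards
  compatibility;
* :func:`association_comparison` — which phenotypes/genes describing a
  disorder are common to all annotating sources, and which are unique;
* :func:`query_associations` — the endpoint-style "disorders associated
  with a given gene/phenotype" listing, provenance column included;
* :func:`coverage_report` — how much of one source's disorder census the
  other covers, plus per-disorder annotation overlap;
* :func:`grouping_divergence` — disorders whose parent containers differ
  between sources (grouped here, sub-typed there);
* :func:`taxonomy_depth` — nesting depth of the mixed group/sub-type
  hierarchy.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    EmptyAgentSetError,
    InvalidGraphError,
    UnknownAgentError,
    UnknownEntityError,
    WrongKindError,
)
from .model import (
    EntityKind,
    KnowledgeGraph,
    Predicate,
    Statement,
    hierarchy_edges,
    validate,
)


def _require_agents(graph: KnowledgeGraph, agents: Iterable[str]) -> frozenset[str]:
    agent_set = frozenset(agents)
    unknown = sorted(agent_set - graph.agents.keys())
    if unknown:
        raise UnknownAgentError(f"unregistered agent(s): {', '.join(unknown)}")
    return agent_set


def provenance_view(graph: KnowledgeGraph,
                    agents: Iterable[str]) -> KnowledgeGraph:
    """The subgraph attributed to ``agents``, with attribution restricted.

    Entities are rebuilt by replaying only the contributions made by the
    chosen agents, so labels and cross-references added by other sources
    do not leak into the view; statements whose endpoints drop out are
    dropped.  Idempotent, and monotone in the agent set.
    """
    agent_set = frozenset(agents)
    if not agent_set:
        raise EmptyAgentSetError("a provenance view needs at least one agent")
    _require_agents(graph, agent_set)

    view = KnowledgeGraph(graph_id=f"{graph.graph_id}|{'+'.join(sorted(agent_set))}")
    for agent_id in sorted(agent_set):
        view.register_agent(agent_id, graph.agents[agent_id])

    for entity_id in sorted(graph.entities):
        for contribution in graph.contributions(entity_id):
            kept = contribution.attributed_to & agent_set
            if kept:
                view.add_entity(replace(contribution, attributed_to=kept))

    for key in graph.statement_keys():
        subject, predicate, obj, qualifier = key
        kept = graph.statement_agents(key) & agent_set
        if kept and subject in view.entities and obj in view.entities:
            view.add_statement(Statement(subject, predicate, obj,
                                         qualifier, kept))
    return view


# ---------------------------------------------------------------------------
# association comparison & queries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationComparison:
    """Per-agent gene/phenotype annotation sets for one disorder.

    ``common_*`` is the intersection over the agents that annotate the
    disorder at all (an agent silent on this disorder does not force the
    intersection empty); ``unique_*`` holds what only that one agent
    asserts.  Frequency qualifiers are ignored for set membership.
    """

    disorder_id: str
    phenotypes_by_agent: Mapping[str, frozenset[str]]
    genes_by_agent: Mapping[str, frozenset[str]]
    common_phenotypes: frozenset[str]
    common_genes: frozenset[str]
    unique_phenotypes: Mapping[str, frozenset[str]]
    unique_genes: Mapping[str, frozenset[str]]


def _per_agent_objects(graph: KnowledgeGraph, disorder_id: str,
                       predicate: Predicate) -> dict[str, set[str]]:
    by_agent: dict[str, set[str]] = {}
    for key in graph.statement_keys():
        subject, pred, obj, _q = key
        if subject == disorder_id and pred is predicate:
            for agent in graph.statement_agents(key):
                by_agent.setdefault(agent, set()).add(obj)
    return by_agent


def _common_and_unique(by_agent: dict[str, set[str]]
                       ) -> tuple[frozenset[str], dict[str, frozenset[str]]]:
    if not by_agent:
        return frozenset(), {}
    common = frozenset(set.intersection(*by_agent.values()))
    unique = {}
    for agent, objects in by_agent.items():
        others: set[str] = set()
        for other, other_objects in by_agent.items():
            if other != agent:
                others |= other_objects
        unique[agent] = frozenset(objects - others - common)
    return common, unique


def association_comparison(graph: KnowledgeGraph,
                           disorder_id: str) -> AssociationComparison:
    record = graph.entities.get(disorder_id)
    if record is None:
        raise UnknownEntityError(f"unknown entity {disorder_id!r}")
    if record.kind is not EntityKind.DISORDER:
        raise WrongKindError(
            f"{disorder_id!r} has kind {record.kind.value}, expected DISORDER")
    phen = _per_agent_objects(graph, disorder_id, Predicate.ASSOCIATED_PHENOTYPE)
    gene = _per_agent_objects(graph, disorder_id, Predicate.ASSOCIATED_GENE)
    common_phen, unique_phen = _common_and_unique(phen)
    common_gene, unique_gene = _common_and_unique(gene)
    return AssociationComparison(
        disorder_id=disorder_id,
        phenotypes_by_agent={a: frozenset(v) for a, v in sorted(phen.items())},
        genes_by_agent={a: frozenset(v) for a, v in sorted(gene.items())},
        common_phenotypes=common_phen,
        common_genes=common_gene,
        unique_phenotypes=unique_phen,
        unique_genes=unique_gene,
    )


def query_associations(graph: KnowledgeGraph, target_id: str
                       ) -> list[tuple[str, Predicate, frozenset[str]]]:
    """All disorders associated with a gene or phenotype, one row per
    association statement, sorted by disorder id, provenance included."""
    record = graph.entities.get(target_id)
    if record is None:
        raise UnknownEntityError(f"unknown entity {target_id!r}")
    if record.kind not in (EntityKind.GENE, EntityKind.PHENOTYPE):
        raise WrongKindError(
            f"{target_id!r} has kind {record.kind.value}; queries target "
            "genes or phenotypes")
    wanted = (Predicate.ASSOCIATED_GENE if record.kind is EntityKind.GENE
              else Predicate.ASSOCIATED_PHENOTYPE)
    rows = [
        (subject, pred, graph.statement_agents(key))
        for key in graph.statement_keys()
        for (subject, pred, obj, _q) in [key]
        if obj == target_id and pred is wanted
    ]
    rows.sort(key=lambda row: row[0])
    return rows


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoverageReport:
    """Census comparison of two agents' disorder coverage."""

    left: str
    right: str
    left_total: int
    right_total: int
    only_left: int
    only_right: int
    shared: int
    only_left_pct: float
    only_right_pct: float
    phenotype_vocabulary: Mapping[str, int]
    #: disorder id -> (left association count, right count, common count)
    overlap: Mapping[str, tuple[int, int, int]]

    def to_dict(self) -> dict:
        return {
            "left": self.left, "right": self.right,
            "left_total": self.left_total, "right_total": self.right_total,
            "only_left": self.only_left, "only_right": self.only_right,
            "shared": self.shared,
            "only_left_pct": self.only_left_pct,
            "only_right_pct": self.only_right_pct,
            "phenotype_vocabulary": dict(self.phenotype_vocabulary),
            "overlap": {d: list(t) for d, t in self.overlap.items()},
        }


def _pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (202/524 -> 38.5)."""
    if denominator == 0:
        return 0.0
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def coverage_report(graph: KnowledgeGraph, left: str, right: str
                    ) -> CoverageReport:
    """Only-in-left / only-in-right / shared disorder counts (by entity
    attribution), distinct phenotype vocabulary per agent, and per-disorder
    annotation overlap for the disorders both agents attribute."""
    _require_agents(graph, (left, right))
    left_ids, right_ids = set(), set()
    for entity in graph.entities.values():
        if entity.kind is not EntityKind.DISORDER:
            continue
        if left in entity.attributed_to:
            left_ids.add(entity.id)
        if right in entity.attributed_to:
            right_ids.add(entity.id)
    shared_ids = left_ids & right_ids

    vocab: dict[str, set[str]] = {left: set(), right: set()}
    per_disorder: dict[str, dict[str, set[str]]] = {}
    for key in graph.statement_keys():
        subject, predicate, obj, _q = key
        if predicate is not Predicate.ASSOCIATED_PHENOTYPE:
            continue
        agents = graph.statement_agents(key)
        for agent in (left, right):
            if agent in agents:
                vocab[agent].add(obj)
                if subject in shared_ids:
                    per_disorder.setdefault(
                        subject, {left: set(), right: set()})[agent].add(obj)

    overlap = {
        disorder: (
            len(sets[left]), len(sets[right]),
            len(sets[left] & sets[right]),
        )
        for disorder, sets in sorted(per_disorder.items())
    }
    return CoverageReport(
        left=left, right=right,
        left_total=len(left_ids), right_total=len(right_ids),
        only_left=len(left_ids - right_ids),
        only_right=len(right_ids - left_ids),
        shared=len(shared_ids),
        only_left_pct=_pct(len(left_ids - right_ids), len(left_ids)),
        only_right_pct=_pct(len(right_ids - left_ids), len(right_ids)),
        phenotype_vocabulary={left: len(vocab[left]), right: len(vocab[right])},
        overlap=overlap,
    )


# ---------------------------------------------------------------------------
# grouping divergence & depth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DivergenceRecord:
    """Per-agent parent containers of one multi-source disorder.

    A parent is either a group holding the disorder via MEMBER or a
    broader disorder holding it via sub-typing; divergent means at least
    two agents disagree on the parent set.
    """

    disorder_id: str
    parents_by_agent: Mapping[str, frozenset[tuple[str, str]]]
    divergent: bool


def grouping_divergence(graph: KnowledgeGraph) -> list[DivergenceRecord]:
    """One record per disorder attributed to two or more agents."""
    records: list[DivergenceRecord] = []
    parent_edges = [
        (key, graph.statement_agents(key))
        for key in graph.statement_keys()
        if key[1] in (Predicate.MEMBER, Predicate.NARROWER_T)
    ]
    for entity_id in sorted(graph.entities):
        entity = graph.entities[entity_id]
        if entity.kind is not EntityKind.DISORDER:
            continue
        if len(entity.attributed_to) < 2:
            continue
        parents: dict[str, set[tuple[str, str]]] = {
            agent: set() for agent in entity.attributed_to}
        for (subject, predicate, obj, _q), agents in parent_edges:
            if obj != entity_id:
                continue
            for agent in agents & entity.attributed_to:
                parents[agent].add((subject, predicate.value))
        sets = list(parents.values())
        divergent = any(a != b for a in sets for b in sets)
        records.append(DivergenceRecord(
            disorder_id=entity_id,
            parents_by_agent={a: frozenset(p) for a, p in sorted(parents.items())},
            divergent=divergent,
        ))
    return records


def taxonomy_depth(graph: KnowledgeGraph, agent: str | None = None) -> int:
    """Longest root-to-leaf containment path, counted in edges, over the
    mixed group-membership / sub-typing hierarchy (0 for a flat graph)."""
    if agent is not None:
        _require_agents(graph, (agent,))
        graph = provenance_view(graph, {agent})
    report = validate(graph)
    if not report.ok:
        raise InvalidGraphError(report)
    edges = hierarchy_edges(graph)
    if not edges:
        return 0
    return int(nx.dag_longest_path_length(nx.DiGraph(edges)))
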