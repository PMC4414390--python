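"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's own graph algorithms: reachability
is an exhaustive path search over raw edge lists, longest-path enumerates
every simple path, and the merge-provenance oracle replays each source's
assertions directly.
"""
from __future__ import annotations

import random

import taxoprov as tp
from taxoprov.model import Predicate


def reachable_pairs(nodes: list[str],
                    edges: list[tuple[str, str]]) -> set[tuple[str, str]]:
    """All ordered pairs (a, b), a != b, connected by some directed path,
    found by exhaustive simple-path search."""

    def search(current: str, goal: str, seen: frozenset[str]) -> bool:
        for (u, v) in edges:
            if u != current or v in seen:
                continue
            if v == goal or search(v, goal, seen | {v}):
                return True
        return False

    return {(a, b) for a in nodes for b in nodes
            if a != b and search(a, b, frozenset({a}))}


def longest_path_edges(edges: list[tuple[str, str]]) -> int:
    """Length (in edges) of the longest simple path, by full enumeration."""
    if not edges:
        return 0
    best = 0

    def extend(current: str, length: int, seen: frozenset[str]) -> None:
        nonlocal best
        best = max(best, length)
        for (u, v) in edges:
            if u == current and v not in seen:
                extend(v, length + 1, seen | {v})

    for (u, _v) in edges:
        extend(u, 0, frozenset({u}))
    return best


def random_subtype_graph(seed: int, n: int = 12, p: float = 0.2,
                         agent: str = "SRC"):
    """A random disorder-only DAG: edges always point from a lower to a
    higher index, so no insertion is ever rejected."""
    rng = random.Random(seed)
    graph = tp.KnowledgeGraph(graph_id=f"dag-{seed}")
    graph.register_agent(agent)
    nodes = [f"d{i:02d}" for i in range(n)]
    for node in nodes:
        graph.add_entity(tp.EntityRecord(node, tp.EntityKind.DISORDER,
                                         f"Disorder {node}",
                                         attributed_to=frozenset({agent})))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_statement(tp.Statement(
                    nodes[i], Predicate.NARROWER_T, nodes[j],
                    attributed_to=frozenset({agent})))
                edges.append((nodes[i], nodes[j]))
    return graph, nodes, edges


def expected_merged_statements(sources, cmap) -> dict:
    """Replay each source's assertions (inverse sub-typing edges
    materialized) into {statement key: expected agent set}."""
    inverse = {Predicate.NARROWER_T: Predicate.BROADER_T,
               Predicate.BROADER_T: Predicate.NARROWER_T}
    expected: dict[tuple, set[str]] = {}
    for doc in sources:
        for stmt in doc.statements:
            subject = cmap[(doc.agent.id, stmt.subject)]
            obj = cmap[(doc.agent.id, stmt.object)]
            keys = [(subject, stmt.predicate, obj, stmt.qualifier)]
            if stmt.predicate in inverse:
                keys.append((obj, inverse[stmt.predicate], subject,
                             stmt.qualifier))
            for key in keys:
                expected.setdefault(key, set()).update(stmt.attributed_to)
    return expected
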