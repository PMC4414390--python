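"""Core model semantics: union-merge adds, inverse materialization,
cycle rejection, closure, the kind heuristic, and validation."""
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import taxoprov as tp
from taxoprov.errors import (
    CycleError,
    DanglingEndpointError,
    EmptyAttributionError,
    KindClashError,
    KindConstraintError,
    NotClassifiableError,
)
from taxoprov.model import EntityKind, FrequencyQualifier, Predicate

from oracles import random_subtype_graph, reachable_pairs


def _disorder(graph, entity_id, agent="SRC", label=None):
    graph.register_agent(agent)
    graph.add_entity(tp.EntityRecord(entity_id, EntityKind.DISORDER,
                                     label or entity_id,
                                     attributed_to=frozenset({agent})))
    return graph


def _graph(*disorders, agent="SRC"):
    graph = tp.KnowledgeGraph()
    for d in disorders:
        _disorder(graph, d, agent=agent)
    return graph


class TestAddEntity:
    def test_reattribution_unions_agents(self):
        graph = tp.KnowledgeGraph()
        record = tp.EntityRecord("ach", EntityKind.DISORDER, "Achondroplasia",
                                 attributed_to=frozenset({"ISDS"}))
        graph.add_entity(record)
        graph.add_entity(tp.EntityRecord(
            "ach", EntityKind.DISORDER, "Achondroplasia",
            attributed_to=frozenset({"Orphanet"})))
        assert graph.entities["ach"].attributed_to == {"ISDS", "Orphanet"}
        assert len(graph.entities) == 1

    def test_differing_label_becomes_alt_label(self):
        graph = tp.KnowledgeGraph()
        graph.add_entity(tp.EntityRecord(
            "ladd", EntityKind.DISORDER, "Lacrimo-Auriculo-Dento-Digital",
            attributed_to=frozenset({"A"})))
        graph.add_entity(tp.EntityRecord(
            "ladd", EntityKind.DISORDER, "LADD syndrome",
            xrefs={"omim_id": "149730"},
            attributed_to=frozenset({"B"})))
        entity = graph.entities["ladd"]
        assert entity.label == "Lacrimo-Auriculo-Dento-Digital"
        assert entity.alt_labels == {"LADD syndrome"}
        assert entity.xrefs == {"omim_id": frozenset({"149730"})}

    def test_identical_re_add_is_idempotent(self):
        record = tp.EntityRecord("g1", EntityKind.GROUP, "Group",
                                 attributed_to=frozenset({"A"}))
        once = tp.KnowledgeGraph().add_entity(record)
        twice = tp.KnowledgeGraph().add_entity(record).add_entity(record)
        assert once == twice

    def test_kind_clash_rejected(self):
        graph = _graph("x")
        with pytest.raises(KindClashError):
            graph.add_entity(tp.EntityRecord(
                "x", EntityKind.GROUP, "X", attributed_to=frozenset({"SRC"})))

    def test_empty_attribution_rejected(self):
        with pytest.raises(EmptyAttributionError):
            tp.KnowledgeGraph().add_entity(
                tp.EntityRecord("x", EntityKind.GENE, "X"))

    def test_random_add_sequence_matches_fold_oracle(self):
        """50 random adds over 10 ids / 2 kinds equal a brute-force fold
        of the union semantics."""
        rng = random.Random(42)
        ids = [f"e{i}" for i in range(10)]
        kind_of = {e: (EntityKind.DISORDER if i % 2 else EntityKind.GROUP)
                   for i, e in enumerate(ids)}
        graph = tp.KnowledgeGraph()
        oracle: dict[str, dict] = {}
        for step in range(50):
            entity_id = rng.choice(ids)
            label = f"label-{rng.randrange(3)}"
            agents = frozenset(rng.sample(["A", "B", "C"], rng.randint(1, 2)))
            alt = frozenset({f"alt-{rng.randrange(2)}"} if rng.random() < .5
                            else set())
            graph.add_entity(tp.EntityRecord(entity_id, kind_of[entity_id],
                                             label, alt_labels=alt,
                                             attributed_to=agents))
            state = oracle.setdefault(entity_id, {
                "label": label, "alt": set(), "agents": set()})
            state["agents"] |= agents
            state["alt"] |= alt
            if label != state["label"]:
                state["alt"].add(label)
            state["alt"].discard(state["label"])
        assert set(graph.entities) == set(oracle)
        for entity_id, state in oracle.items():
            entity = graph.entities[entity_id]
            assert entity.label == state["label"]
            assert entity.alt_labels == state["alt"]
            assert entity.attributed_to == state["agents"]


class TestAddStatement:
    def test_reassertion_unions_attribution(self):
        graph = _graph("ach")
        graph.add_entity(tp.EntityRecord("fgfr3", EntityKind.GENE, "FGFR3",
                                         attributed_to=frozenset({"SRC"})))
        for agent in ("ISDS", "Orphanet"):
            graph.add_statement(tp.Statement(
                "ach", Predicate.ASSOCIATED_GENE, "fgfr3",
                attributed_to=frozenset({agent})))
        key = ("ach", Predicate.ASSOCIATED_GENE, "fgfr3",
               FrequencyQualifier.UNSPECIFIED)
        assert graph.statement_agents(key) == {"ISDS", "Orphanet"}
        assert len(graph.statement_keys()) == 1

    def test_subtype_edge_materializes_inverse(self):
        graph = _graph("rt", "rt-sub", agent="Orphanet")
        graph.add_statement(tp.Statement(
            "rt", Predicate.NARROWER_T, "rt-sub",
            attributed_to=frozenset({"Orphanet"})))
        inverse = ("rt-sub", Predicate.BROADER_T, "rt",
                   FrequencyQualifier.UNSPECIFIED)
        assert graph.has_statement(inverse)
        assert graph.statement_agents(inverse) == {"Orphanet"}

    def test_broader_edge_materializes_narrower(self):
        graph = _graph("a", "b")
        graph.add_statement(tp.Statement(
            "a", Predicate.BROADER_T, "b", attributed_to=frozenset({"SRC"})))
        assert graph.has_statement(
            ("b", Predicate.NARROWER_T, "a", FrequencyQualifier.UNSPECIFIED))

    def test_two_cycle_rejected(self):
        graph = _graph("a", "b")
        graph.add_statement(tp.Statement("a", Predicate.NARROWER_T, "b",
                                         attributed_to=frozenset({"SRC"})))
        with pytest.raises(CycleError):
            graph.add_statement(tp.Statement(
                "b", Predicate.NARROWER_T, "a",
                attributed_to=frozenset({"SRC"})))

    def test_nested_group_cycle_rejected(self):
        graph = tp.KnowledgeGraph()
        for gid in ("g1", "g2"):
            graph.add_entity(tp.EntityRecord(gid, EntityKind.GROUP, gid,
                                             attributed_to=frozenset({"S"})))
        graph.add_statement(tp.Statement("g1", Predicate.MEMBER, "g2",
                                         attributed_to=frozenset({"S"})))
        with pytest.raises(CycleError):
            graph.add_statement(tp.Statement("g2", Predicate.MEMBER, "g1",
                                             attributed_to=frozenset({"S"})))

    @pytest.mark.parametrize("stmt, error", [
        (tp.Statement("a", Predicate.ASSOCIATED_GENE, "missing",
                      attributed_to=frozenset({"SRC"})), DanglingEndpointError),
        (tp.Statement("a", Predicate.MEMBER, "b",
                      attributed_to=frozenset({"SRC"})), KindConstraintError),
        (tp.Statement("a", Predicate.ASSOCIATED_GENE, "b",
                      attributed_to=frozenset({"SRC"})), KindConstraintError),
        (tp.Statement("a", Predicate.NARROWER_T, "b",
                      qualifier=FrequencyQualifier.FREQUENT,
                      attributed_to=frozenset({"SRC"})), KindConstraintError),
        (tp.Statement("a", Predicate.NARROWER_T, "b"), EmptyAttributionError),
    ])
    def test_invalid_statements_rejected(self, stmt, error):
        graph = _graph("a", "b")
        with pytest.raises(error):
            graph.add_statement(stmt)

    def test_qualifier_variants_are_distinct_statements(self):
        graph = _graph("d")
        graph.add_entity(tp.EntityRecord("p", EntityKind.PHENOTYPE, "P",
                                         attributed_to=frozenset({"SRC"})))
        for qualifier, agent in ((FrequencyQualifier.UNSPECIFIED, "A"),
                                 (FrequencyQualifier.VERY_FREQUENT, "B")):
            graph.add_statement(tp.Statement(
                "d", Predicate.ASSOCIATED_PHENOTYPE, "p", qualifier=qualifier,
                attributed_to=frozenset({agent})))
        assert len(graph.statement_keys()) == 2


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5),
                          st.sampled_from("ABC")), max_size=25))
def test_statement_attribution_is_monotone(operations):
    """Replaying add_statement never removes an agent from any
    attribution set, and re-application is idempotent."""
    graph = tp.KnowledgeGraph()
    for i in range(6):
        graph.add_entity(tp.EntityRecord(f"d{i}", EntityKind.DISORDER,
                                         f"d{i}",
                                         attributed_to=frozenset({"SRC"})))
    seen: dict[tuple, set[str]] = {}
    for i, j, agent in operations:
        if i == j:
            continue
        subject, obj = f"d{min(i, j)}", f"d{max(i, j)}"
        stmt = tp.Statement(subject, Predicate.NARROWER_T, obj,
                            attributed_to=frozenset({agent}))
        graph.add_statement(stmt)
        seen.setdefault(stmt.key, set()).add(agent)
        for key, agents in seen.items():
            assert agents <= graph.statement_agents(key)
        before = {k: frozenset(v) for k, v in graph._statements.items()}
        graph.add_statement(stmt)
        assert {k: frozenset(v) for k, v in graph._statements.items()} == before


class TestBroaderClosure:
    def test_three_disorder_chain(self):
        graph = _graph("polydactyly", "preaxial", "thumb")
        for broader, narrower in (("polydactyly", "preaxial"),
                                  ("preaxial", "thumb")):
            graph.add_statement(tp.Statement(
                broader, Predicate.NARROWER_T, narrower,
                attributed_to=frozenset({"SRC"})))
        closure = tp.broader_closure(graph)
        assert ("polydactyly", "thumb") in closure
        assert len(closure) == 3

    def test_empty_relation(self):
        assert tp.broader_closure(_graph("a", "b")) == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_reachability(self, seed):
        graph, nodes, edges = random_subtype_graph(seed, n=12, p=0.2)
        assert tp.broader_closure(graph) == reachable_pairs(nodes, edges)
        assert set(edges) <= tp.broader_closure(graph) or not edges


class TestClassifyNodeKind:
    def test_all_subtyped_children_mean_disorder(self):
        graph = _graph("mesomelic", "korean", "kantaputra", "savarirayan")
        for child in ("korean", "kantaputra", "savarirayan"):
            graph.add_statement(tp.Statement(
                "mesomelic", Predicate.NARROWER_T, child,
                attributed_to=frozenset({"SRC"})))
        assert tp.classify_node_kind(graph, "mesomelic") is EntityKind.DISORDER

    def test_mixed_children_mean_group(self):
        graph = tp.KnowledgeGraph()
        for gid in ("dysostosis", "craniofacial", "patellar"):
            graph.add_entity(tp.EntityRecord(gid, EntityKind.GROUP, gid,
                                             attributed_to=frozenset({"S"})))
        _disorder(graph, "clavicle", agent="S")
        for child in ("craniofacial", "patellar", "clavicle"):
            graph.add_statement(tp.Statement(
                "dysostosis", Predicate.MEMBER, child,
                attributed_to=frozenset({"S"})))
        assert tp.classify_node_kind(graph, "dysostosis") is EntityKind.GROUP

    def test_leaf_returns_declared_kind(self):
        graph = _graph("leaf")
        assert tp.classify_node_kind(graph, "leaf") is EntityKind.DISORDER

    def test_member_held_disorders_mean_group(self):
        graph = tp.KnowledgeGraph()
        graph.add_entity(tp.EntityRecord("g", EntityKind.GROUP, "g",
                                         attributed_to=frozenset({"S"})))
        _disorder(graph, "d", agent="S")
        graph.add_statement(tp.Statement("g", Predicate.MEMBER, "d",
                                         attributed_to=frozenset({"S"})))
        assert tp.classify_node_kind(graph, "g") is EntityKind.GROUP

    def test_never_group_for_purely_subtyped_children(self):
        for seed in range(5):
            graph, nodes, edges = random_subtype_graph(seed, n=8, p=0.3)
            for node in nodes:
                if any(u == node for u, _ in edges):
                    assert tp.classify_node_kind(graph, node) \
                        is EntityKind.DISORDER

    def test_unclassifiable_kinds_rejected(self):
        graph = tp.KnowledgeGraph()
        graph.add_entity(tp.EntityRecord("fgfr3", EntityKind.GENE, "FGFR3",
                                         attributed_to=frozenset({"S"})))
        with pytest.raises(NotClassifiableError):
            tp.classify_node_kind(graph, "fgfr3")


class TestValidate:
    def test_curated_merge_is_valid(self, curated_merged):
        assert tp.validate(curated_merged).ok

    def test_empty_attribution_reported(self):
        graph = _graph("a", "b")
        graph.add_statement(tp.Statement("a", Predicate.NARROWER_T, "b",
                                         attributed_to=frozenset({"SRC"})))
        key = ("a", Predicate.NARROWER_T, "b", FrequencyQualifier.UNSPECIFIED)
        graph._statements[key] = set()  # bypass add_statement on purpose
        report = tp.validate(graph)
        assert not report.ok
        assert {"EmptyAttribution", "MissingInverse"} <= {
            v.code for v in report.violations}

    def test_missing_inverse_reported(self):
        graph = _graph("a", "b")
        graph._statements[("a", Predicate.NARROWER_T, "b",
                           FrequencyQualifier.UNSPECIFIED)] = {"SRC"}
        report = tp.validate(graph)
        assert any(v.code == "MissingInverse" for v in report.violations)

    def test_missing_endpoint_reported(self):
        graph = _graph("a")
        graph._statements[("a", Predicate.ASSOCIATED_GENE, "ghost",
                           FrequencyQualifier.UNSPECIFIED)] = {"SRC"}
        report = tp.validate(graph)
        assert any(v.code == "MissingEndpoint" and "ghost" in v.subjects
                   for v in report.violations)

    def test_forced_cycle_reported(self):
        graph = _graph("a", "b")
        for s, o in (("a", "b"), ("b", "a")):
            graph._statements[(s, Predicate.NARROWER_T, o,
                               FrequencyQualifier.UNSPECIFIED)] = {"SRC"}
            graph._statements[(o, Predicate.BROADER_T, s,
                               FrequencyQualifier.UNSPECIFIED)] = {"SRC"}
        report = tp.validate(graph)
        assert any(v.code == "CycleDetected" for v in report.violations)
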