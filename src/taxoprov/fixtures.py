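"""Deterministic fixture generation.

Two kinds of fixtures are produced:

* :func:`generate_fixture` — a randomized but fully seeded pair of
  overlapping source classifications (one nosology-style source, one
  Orphanet-style source that adds frequency qualifiers) plus the expert
  alignment table and a ground-truth manifest written by direct counting
  at build time;
* :func:`curated_fixture` — a hand-written bundle encoding the classic
  rare-bone-disorder worked examples: a disorder placed in two groups with
  split attribution, a jointly asserted gene association, a
  secondary-agent phenotype annotation, a grouping-vs-sub-typing
  divergence, a three-disorder sub-typing chain, an explicit
  narrower/broader pair, and a mixed group.

The manifest is intentionally computed with plain arithmetic over the
generated lists — never via the merge or fact-sheet code — so it can serve
as an independent cross-check in tests.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InfeasibleParamsError
from .model import EntityKind, EntityRecord, FrequencyQualifier, Predicate, Statement
from .source_io import (
    AgentRef,
    AlignmentRow,
    AlignmentTable,
    Decision,
    SourceDocument,
)

_QUALIFIER_POOL = (
    FrequencyQualifier.VERY_FREQUENT,
    FrequencyQualifier.FREQUENT,
    FrequencyQualifier.OCCASIONAL,
    FrequencyQualifier.VERY_RARE,
    FrequencyQualifier.UNSPECIFIED,
)


@dataclass(frozen=True)
class FixtureParams:
    """Shape of a generated two-source fixture.

    Defaults describe a small but structurally complete pair of
    classifications: two dozen disorders per source, half of them aligned
    by the expert table, a 40-term phenotype vocabulary, 2–6 phenotype
    annotations per disorder with half of the smaller annotation set
    shared on aligned disorders, and hierarchies nested up to 4 levels.
    """

    n_disorders: int = 24
    n_groups: int = 6
    frac_aligned: float = 0.5
    n_aligned: int | None = None  # overrides frac_aligned when set
    n_phenotypes: int = 40
    assoc_min: int = 2
    assoc_max: int = 6
    overlap_frac: float = 0.5
    max_depth: int = 4
    seed: int = 0
    left_agent: tuple[str, str] = (
        "ISDS", "International Skeletal Dysplasia Society nosology")
    right_agent: tuple[str, str] = (
        "ORPHA", "Orphanet rare bone disorder classification")

    def validated(self) -> "FixtureParams":
        if not 0.0 <= self.frac_aligned <= 1.0:
            raise InfeasibleParamsError("frac_aligned must lie in [0, 1]")
        if not 0.0 <= self.overlap_frac <= 1.0:
            raise InfeasibleParamsError("overlap_frac must lie in [0, 1]")
        if min(self.n_disorders, self.n_groups, self.n_phenotypes,
               self.assoc_min, self.max_depth) < 0:
            raise InfeasibleParamsError("counts must be non-negative")
        if self.assoc_min > self.assoc_max:
            raise InfeasibleParamsError("assoc_min exceeds assoc_max")
        if self.n_aligned is not None and not (
                0 <= self.n_aligned <= self.n_disorders):
            raise InfeasibleParamsError("n_aligned outside [0, n_disorders]")
        if self.n_phenotypes < 2 * self.assoc_max:
            raise InfeasibleParamsError(
                "phenotype vocabulary too small for disjoint unique sets "
                f"({self.n_phenotypes} < 2*{self.assoc_max})")
        if self.n_disorders > 0 and self.n_groups == 0:
            raise InfeasibleParamsError("disorders need at least one group")
        return self


@dataclass(frozen=True)
class FixtureBundle:
    """Two source documents, their alignment, and a ground-truth manifest."""

    left: SourceDocument
    right: SourceDocument
    alignment: AlignmentTable
    manifest: dict = field(default_factory=dict)

    @property
    def sources(self) -> tuple[SourceDocument, SourceDocument]:
        return (self.left, self.right)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "left.json").write_text(self.left.to_json())
        (directory / "right.json").write_text(self.right.to_json())
        (directory / "alignment.tsv").write_text(self.alignment.to_tsv())
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")

    def serialize(self) -> str:
        """Canonical text form of the whole bundle (for determinism checks)."""
        return "\n---\n".join((
            self.left.to_json(), self.right.to_json(),
            self.alignment.to_tsv(),
            json.dumps(self.manifest, indent=2, sort_keys=True),
        ))


def _longest_path(edges: list[tuple[str, str]]) -> int:
    """Independent longest-path count (edges) by memoized DFS over the
    generator's own edge lists — deliberately not the analytics code."""
    children: dict[str, list[str]] = {}
    for parent, child in edges:
        children.setdefault(parent, []).append(child)
    memo: dict[str, int] = {}

    def depth(node: str) -> int:
        if node not in memo:
            memo[node] = 1 + max(
                (depth(c) for c in children.get(node, [])), default=-1)
        return memo[node]

    return max((depth(n) for n in children), default=0)


def generate_fixture(params: FixtureParams = FixtureParams()) -> FixtureBundle:
    """Build a reproducible two-source fixture.

    Identical parameters (seed included) yield byte-identical bundles.
    Hierarchy edges always point from a lower to a higher index on each
    side and aligned entities share their index, so the union of both
    hierarchies is guaranteed acyclic.
    """
    params = params.validated()
    rng = random.Random(params.seed)
    left_id, left_label = params.left_agent
    right_id, right_label = params.right_agent

    n_aligned = (params.n_aligned if params.n_aligned is not None
                 else round(params.frac_aligned * params.n_disorders))
    n_genes = max(3, params.n_disorders // 3)
    phen_vocab = [(f"HP:09{k:05d}", f"Phenotype-{k:03d}")
                  for k in range(params.n_phenotypes)]
    moi_vocab = [("HP:0000006", "Autosomal dominant inheritance"),
                 ("HP:0000007", "Autosomal recessive inheritance")]
    n_aligned_groups = max(1, params.n_groups // 2) if params.n_groups else 0

    sides: dict[str, dict] = {}
    for agent_id in (left_id, right_id):
        prefix = agent_id.lower()
        disorders = []
        for i in range(n_aligned):
            disorders.append((f"{prefix}:D{i:04d}", f"Disorder-S-{i:04d}"))
        for j in range(params.n_disorders - n_aligned):
            tag = "L" if agent_id == left_id else "R"
            disorders.append((f"{prefix}:D{tag}{j:04d}",
                              f"Disorder-{tag}-{j:04d}"))
        groups = []
        for g in range(params.n_groups):
            shared = g < n_aligned_groups
            label = (f"Group-S-{g:02d}" if shared
                     else f"Group-{agent_id}-{g:02d}")
            groups.append((f"{prefix}:G{g:02d}", label))
        sides[agent_id] = {"disorders": disorders, "groups": groups}

    rows: list[AlignmentRow] = []
    lp, rp = left_id.lower(), right_id.lower()
    for i in range(n_aligned):
        rows.append(AlignmentRow(left_id, f"{lp}:D{i:04d}",
                                 right_id, f"{rp}:D{i:04d}",
                                 Decision.DISORDER, ""))
    for g in range(n_aligned_groups):
        rows.append(AlignmentRow(left_id, f"{lp}:G{g:02d}",
                                 right_id, f"{rp}:G{g:02d}",
                                 Decision.GROUP, ""))

    # phenotype annotation plan for aligned disorders: the common subset is
    # chosen once and asserted by both sources
    overlap_plan: list[dict] = []
    aligned_assignments: list[tuple[list, list]] = []
    for i in range(n_aligned):
        k_left = rng.randint(params.assoc_min, params.assoc_max)
        k_right = rng.randint(params.assoc_min, params.assoc_max)
        n_common = round(params.overlap_frac * min(k_left, k_right))
        pool = list(phen_vocab)
        rng.shuffle(pool)
        common = pool[:n_common]
        left_only = pool[n_common:k_left]
        right_only = pool[k_left:k_left + (k_right - n_common)]
        aligned_assignments.append((common + left_only, common + right_only))
        overlap_plan.append({
            "left_id": f"{lp}:D{i:04d}", "right_id": f"{rp}:D{i:04d}",
            "left_count": k_left, "right_count": k_right,
            "common": n_common,
        })

    # gene plan: aligned disorders draw their genes once (asserted by both)
    gene_symbols = [f"Gene-{k:03d}" for k in range(n_genes)]
    aligned_genes = [sorted(rng.sample(range(n_genes),
                                       rng.randint(1, min(2, n_genes))))
                     for _ in range(n_aligned)]

    documents: dict[str, SourceDocument] = {}
    manifest_sides: dict[str, dict] = {}
    genes_used: dict[str, set[int]] = {}
    for agent_id, agent_label in ((left_id, left_label), (right_id, right_label)):
        prefix = agent_id.lower()
        is_right = agent_id == right_id
        disorders = sides[agent_id]["disorders"]
        groups = sides[agent_id]["groups"]

        entities: list[EntityRecord] = []
        statements: list[Statement] = []
        attribution = frozenset({agent_id})
        hierarchy: list[tuple[str, str]] = []

        for gid, glabel in groups:
            entities.append(EntityRecord(gid, EntityKind.GROUP, glabel,
                                         attributed_to=attribution))
        # nest groups: parent has a strictly smaller index, depth capped
        group_depth = {groups[0][0]: 0} if groups else {}
        for g in range(1, len(groups)):
            parent = groups[rng.randrange(g)][0]
            if group_depth[parent] + 1 < params.max_depth:
                statements.append(Statement(parent, Predicate.MEMBER,
                                            groups[g][0],
                                            attributed_to=attribution))
                hierarchy.append((parent, groups[g][0]))
                group_depth[groups[g][0]] = group_depth[parent] + 1
            else:
                group_depth[groups[g][0]] = 0

        for did, dlabel in disorders:
            entities.append(EntityRecord(
                did, EntityKind.DISORDER, dlabel,
                xrefs={"local": did.split(":", 1)[1]},
                attributed_to=attribution))
        for did, _ in disorders:
            gid = groups[rng.randrange(len(groups))][0]
            statements.append(Statement(gid, Predicate.MEMBER, did,
                                        attributed_to=attribution))
            hierarchy.append((gid, did))
        # sub-type chains: edges only from lower to higher disorder index
        for _ in range(max(1, params.n_disorders // 5)):
            if params.n_disorders < 2:
                break
            i, j = sorted(rng.sample(range(params.n_disorders), 2))
            statements.append(Statement(disorders[i][0], Predicate.NARROWER_T,
                                        disorders[j][0],
                                        attributed_to=attribution))
            hierarchy.append((disorders[i][0], disorders[j][0]))

        used_phen: dict[str, str] = {}
        for i, (did, _) in enumerate(disorders):
            if i < n_aligned:
                chosen = aligned_assignments[i][1 if is_right else 0]
            else:
                k = rng.randint(params.assoc_min, params.assoc_max)
                chosen = rng.sample(phen_vocab, k)
            for pid, plabel in chosen:
                used_phen[pid] = plabel
                qualifier = (rng.choice(_QUALIFIER_POOL) if is_right
                             else FrequencyQualifier.UNSPECIFIED)
                statements.append(Statement(
                    did, Predicate.ASSOCIATED_PHENOTYPE, pid,
                    qualifier=qualifier, attributed_to=attribution))

        used_genes: set[int] = set()
        for i, (did, _) in enumerate(disorders):
            if i < n_aligned:
                chosen_genes = aligned_genes[i]
            elif n_genes:
                chosen_genes = sorted(rng.sample(
                    range(n_genes), rng.randint(1, min(2, n_genes))))
            else:
                chosen_genes = []
            for k in chosen_genes:
                used_genes.add(k)
                statements.append(Statement(
                    did, Predicate.ASSOCIATED_GENE, f"{prefix}:GENE{k:03d}",
                    attributed_to=attribution))
            if rng.random() < 0.5:
                mid, _mlabel = moi_vocab[rng.randrange(len(moi_vocab))]
                statements.append(Statement(
                    did, Predicate.MODE_OF_INHERITANCE, mid,
                    attributed_to=attribution))
                used_phen.setdefault(mid, "")  # placeholder, replaced below

        for mid, mlabel in moi_vocab:
            if mid in used_phen:
                used_phen.pop(mid)
                entities.append(EntityRecord(mid, EntityKind.INHERITANCE_MODE,
                                             mlabel, attributed_to=attribution))
        for pid in sorted(used_phen):
            entities.append(EntityRecord(pid, EntityKind.PHENOTYPE,
                                         used_phen[pid],
                                         attributed_to=attribution))
        for k in sorted(used_genes):
            entities.append(EntityRecord(f"{prefix}:GENE{k:03d}",
                                         EntityKind.GENE, gene_symbols[k],
                                         attributed_to=attribution))

        genes_used[agent_id] = used_genes
        documents[agent_id] = SourceDocument(
            agent=AgentRef(agent_id, agent_label),
            entities=tuple(entities), statements=tuple(statements),
            name="synthetic classification", version=f"seed-{params.seed}")
        manifest_sides[agent_id] = {
            "n_disorders": len(disorders),
            "n_groups": len(groups),
            "n_genes": len(used_genes),
            "n_phenotypes_used": len(used_phen),
            "max_depth": _longest_path(hierarchy),
        }

    for k in sorted(genes_used[left_id] & genes_used[right_id]):
        rows.append(AlignmentRow(left_id, f"{lp}:GENE{k:03d}",
                                 right_id, f"{rp}:GENE{k:03d}",
                                 Decision.AUTO, ""))

    manifest = {
        "params": {"seed": params.seed, "n_disorders": params.n_disorders,
                   "n_groups": params.n_groups, "n_aligned": n_aligned},
        "aligned_disorders": n_aligned,
        "aligned_groups": n_aligned_groups,
        "aligned_genes": len(genes_used[left_id] & genes_used[right_id]),
        "sides": manifest_sides,
        "overlap": overlap_plan,
    }
    return FixtureBundle(left=documents[left_id], right=documents[right_id],
                         alignment=AlignmentTable(tuple(rows)),
                         manifest=manifest)


# ---------------------------------------------------------------------------
# the curated worked-examples bundle
# ---------------------------------------------------------------------------

def curated_fixture() -> FixtureBundle:
    """Hand-written two-source bundle of the classic rare-bone-disorder
    worked examples, with the exact attribution split each example calls
    for (labels kept verbatim for traceability)."""
    isds = AgentRef("ISDS", "International Skeletal Dysplasia Society")
    omim = AgentRef("OMIM", "Online Mendelian Inheritance in Man")
    orpha = AgentRef("Orphanet", "Orphanet")
    by_isds = frozenset({isds.id})
    by_omim = frozenset({omim.id})
    by_orpha = frozenset({orpha.id})

    E, S = EntityRecord, Statement
    K, P = EntityKind, Predicate

    left_entities = (
        E("isds:G-FGFR3", K.GROUP, "FGFR3 Chondrodysplasia Group",
          attributed_to=by_isds),
        E("isds:G-PST", K.GROUP, "Polydactyly-Syndactyly-Triphalangism Group",
          attributed_to=by_isds),
        E("isds:G-LIMB", K.GROUP, "Limb hypoplasia - reduction defects Group",
          attributed_to=by_isds),
        E("isds:G-TRPV4", K.GROUP, "TRPV4 Group", attributed_to=by_isds),
        E("isds:G-SEMD", K.GROUP, "Spondylo-epi(-meta)physeal dysplasias",
          attributed_to=by_isds),
        E("isds:D-ACH", K.DISORDER, "Achondroplasia",
          xrefs={"omim_id": "100800"}, attributed_to=by_isds),
        E("isds:D-LADD", K.DISORDER, "Lacrimo-Auriculo-Dento-Digital syndrome",
          alt_labels=frozenset({"LADD syndrome"}), attributed_to=by_isds),
        E("isds:D-HOS", K.DISORDER, "Holt-Oram syndrome",
          xrefs={"omim_id": "142900"}, attributed_to=by_isds),
        E("isds:D-SEMD-MT", K.DISORDER,
          "Spondyloepimetaphyseal dysplasia Maroteaux type",
          attributed_to=by_isds),
        E("isds:D-MD", K.DISORDER, "Mesomelic dysplasia", attributed_to=by_isds),
        E("isds:D-MD-KOR", K.DISORDER, "Mesomelic dysplasia, Korean type",
          attributed_to=by_isds),
        E("isds:D-MD-KAN", K.DISORDER, "Mesomelic dysplasia, Kantaputra type",
          attributed_to=by_isds),
        E("isds:D-MD-SAV", K.DISORDER, "Mesomelic dysplasia, Savarirayan type",
          attributed_to=by_isds),
        E("isds:GENE-FGFR3", K.GENE, "FGFR3",
          xrefs={"uniprot_id": "P22607"}, attributed_to=by_isds),
        E("isds:GENE-TRPV4", K.GENE, "TRPV4", attributed_to=by_isds),
        E("HP:0000256", K.PHENOTYPE, "Macrocephaly", attributed_to=by_isds),
        E("HP:0000238", K.PHENOTYPE, "Hydrocephalus", attributed_to=by_omim),
        E("HP:0002938", K.PHENOTYPE, "Lumbar hyperlordosis",
          attributed_to=by_omim),
        E("HP:0002857", K.PHENOTYPE, "Genu valgum", attributed_to=by_omim),
        E("HP:0000006", K.INHERITANCE_MODE, "Autosomal dominant inheritance",
          attributed_to=by_isds),
    )
    left_statements = (
        S("isds:G-FGFR3", P.MEMBER, "isds:D-ACH", attributed_to=by_isds),
        S("isds:G-PST", P.MEMBER, "isds:D-LADD", attributed_to=by_isds),
        S("isds:G-LIMB", P.MEMBER, "isds:D-HOS", attributed_to=by_isds),
        S("isds:G-TRPV4", P.MEMBER, "isds:D-SEMD-MT", attributed_to=by_isds),
        S("isds:G-SEMD", P.MEMBER, "isds:D-MD", attributed_to=by_isds),
        S("isds:D-MD", P.NARROWER_T, "isds:D-MD-KOR", attributed_to=by_isds),
        S("isds:D-MD", P.NARROWER_T, "isds:D-MD-KAN", attributed_to=by_isds),
        S("isds:D-MD", P.NARROWER_T, "isds:D-MD-SAV", attributed_to=by_isds),
        S("isds:D-ACH", P.ASSOCIATED_GENE, "isds:GENE-FGFR3",
          attributed_to=by_isds),
        S("isds:D-LADD", P.ASSOCIATED_GENE, "isds:GENE-FGFR3",
          attributed_to=by_isds),
        S("isds:D-SEMD-MT", P.ASSOCIATED_GENE, "isds:GENE-TRPV4",
          attributed_to=by_isds),
        S("isds:D-ACH", P.ASSOCIATED_PHENOTYPE, "HP:0000256",
          attributed_to=by_isds),
        S("isds:D-ACH", P.ASSOCIATED_PHENOTYPE, "HP:0000238",
          attributed_to=by_omim),
        S("isds:D-ACH", P.ASSOCIATED_PHENOTYPE, "HP:0002938",
          attributed_to=by_omim),
        S("isds:D-SEMD-MT", P.ASSOCIATED_PHENOTYPE, "HP:0002857",
          attributed_to=by_omim),
        S("isds:D-ACH", P.MODE_OF_INHERITANCE, "HP:0000006",
          attributed_to=by_isds),
    )
    left = SourceDocument(agent=isds, extra_agents=(omim,),
                          entities=left_entities, statements=left_statements,
                          name="nosology", version="2010")

    right_entities = (
        E("orpha:G-SEMD", K.GROUP, "Spondylo-epi(-meta)physeal dysplasias",
          attributed_to=by_orpha),
        E("orpha:364559", K.GROUP, "Dysostosis",
          xrefs={"orphanet": "364559"}, attributed_to=by_orpha),
        E("orpha:93453", K.GROUP,
          "Dysostosis with predominant craniofacial involvement",
          xrefs={"orphanet": "93453"}, attributed_to=by_orpha),
        E("orpha:93455", K.GROUP, "Patellar dysostosis",
          xrefs={"orphanet": "93455"}, attributed_to=by_orpha),
        E("orpha:G-DLA", K.GROUP,
          "Dysostosis with limb anomaly as a major feature",
          attributed_to=by_orpha),
        E("orpha:15", K.DISORDER, "Achondroplasia",
          xrefs={"orphanet": "15"}, attributed_to=by_orpha),
        E("orpha:93351", K.DISORDER,
          "Spondyloepimetaphyseal dysplasia Maroteaux type",
          xrefs={"orphanet": "93351"}, attributed_to=by_orpha),
        E("orpha:392", K.DISORDER, "Holt-Oram syndrome",
          xrefs={"orphanet": "392"}, attributed_to=by_orpha),
        E("orpha:HHS", K.DISORDER, "Heart-hand syndrome",
          attributed_to=by_orpha),
        E("orpha:66630", K.DISORDER, "Congenital pseudoarthrosis of clavicle",
          xrefs={"orphanet": "66630"}, attributed_to=by_orpha),
        E("orpha:2913", K.DISORDER, "Polydactyly",
          xrefs={"orphanet": "2913"}, attributed_to=by_orpha),
        E("orpha:294939", K.DISORDER, "Preaxial polydactyly of fingers",
          xrefs={"orphanet": "294939"}, attributed_to=by_orpha),
        E("orpha:93336", K.DISORDER, "Polydactyly of a triphalangeal thumb",
          xrefs={"orphanet": "93336"}, attributed_to=by_orpha),
        E("orpha:783", K.DISORDER, "Rubinstein-Taybi syndrome",
          xrefs={"orphanet": "783"}, attributed_to=by_orpha),
        E("orpha:353281", K.DISORDER,
          "Rubinstein-Taybi syndrome due to 16p13.3 microdeletion",
          xrefs={"orphanet": "353281"}, attributed_to=by_orpha),
        E("orpha:GENE-FGFR3", K.GENE, "FGFR3", attributed_to=by_orpha),
        E("orpha:GENE-TRPV4", K.GENE, "TRPV4", attributed_to=by_orpha),
        E("HP:0000256", K.PHENOTYPE, "Macrocephaly", attributed_to=by_orpha),
        E("HP:0000926", K.PHENOTYPE, "Platyspondyly", attributed_to=by_orpha),
    )
    right_statements = (
        S("orpha:G-SEMD", P.MEMBER, "orpha:93351", attributed_to=by_orpha),
        S("orpha:364559", P.MEMBER, "orpha:93453", attributed_to=by_orpha),
        S("orpha:364559", P.MEMBER, "orpha:93455", attributed_to=by_orpha),
        S("orpha:364559", P.MEMBER, "orpha:66630", attributed_to=by_orpha),
        S("orpha:G-DLA", P.MEMBER, "orpha:HHS", attributed_to=by_orpha),
        S("orpha:HHS", P.NARROWER_T, "orpha:392", attributed_to=by_orpha),
        S("orpha:2913", P.NARROWER_T, "orpha:294939", attributed_to=by_orpha),
        S("orpha:294939", P.NARROWER_T, "orpha:93336", attributed_to=by_orpha),
        S("orpha:783", P.NARROWER_T, "orpha:353281", attributed_to=by_orpha),
        S("orpha:15", P.ASSOCIATED_GENE, "orpha:GENE-FGFR3",
          attributed_to=by_orpha),
        S("orpha:93351", P.ASSOCIATED_GENE, "orpha:GENE-TRPV4",
          attributed_to=by_orpha),
        S("orpha:15", P.ASSOCIATED_PHENOTYPE, "HP:0000256",
          qualifier=FrequencyQualifier.VERY_FREQUENT, attributed_to=by_orpha),
        S("orpha:93351", P.ASSOCIATED_PHENOTYPE, "HP:0000926",
          qualifier=FrequencyQualifier.VERY_FREQUENT, attributed_to=by_orpha),
    )
    right = SourceDocument(agent=orpha, entities=right_entities,
                           statements=right_statements,
                           name="rare bone disorders classification",
                           version="2014-05")

    alignment = AlignmentTable((
        AlignmentRow("ISDS", "isds:D-ACH", "Orphanet", "orpha:15",
                     Decision.DISORDER, "Achondroplasia"),
        AlignmentRow("ISDS", "isds:D-SEMD-MT", "Orphanet", "orpha:93351",
                     Decision.DISORDER, "SEMD Maroteaux type"),
        AlignmentRow("ISDS", "isds:D-HOS", "Orphanet", "orpha:392",
                     Decision.DISORDER, "Holt-Oram syndrome"),
        AlignmentRow("ISDS", "isds:G-SEMD", "Orphanet", "orpha:G-SEMD",
                     Decision.GROUP, "Spondylo-epi(-meta)physeal dysplasias"),
        AlignmentRow("ISDS", "isds:GENE-FGFR3", "Orphanet", "orpha:GENE-FGFR3",
                     Decision.AUTO, "FGFR3"),
        AlignmentRow("ISDS", "isds:GENE-TRPV4", "Orphanet", "orpha:GENE-TRPV4",
                     Decision.AUTO, "TRPV4"),
    ))

    # ground-truth tallies by direct arithmetic over the lists above
    n_disorders = 8 + 10 - 3      # per-source disorders minus aligned pairs
    n_groups = 5 + 5 - 1
    n_genes = 2 + 2 - 2
    n_moi = 1
    manifest = {
        "aligned_disorders": 3,
        "aligned_groups": 1,
        "aligned_genes": 2,
        "merged": {
            "n_disorders": n_disorders,
            "n_groups": n_groups,
            "n_genes": n_genes,
            "n_inheritance_modes": n_moi,
            "n_total_classes": n_disorders + n_groups + n_genes + n_moi,
            "n_phenotypes_reused": 5,   # HP:0000256/238/2938/2857/926
            "max_depth": 2,             # e.g. group -> Heart-hand -> Holt-Oram
        },
        "labels": {
            "maroteaux": "Spondyloepimetaphyseal dysplasia Maroteaux type",
            "achondroplasia": "Achondroplasia",
            "holt_oram": "Holt-Oram syndrome",
            "polydactyly": "Polydactyly",
            "triphalangeal_thumb": "Polydactyly of a triphalangeal thumb",
            "genu_valgum": "HP:0002857",
        },
    }
    return FixtureBundle(left=left, right=right, alignment=alignment,
                         manifest=manifest)


def find_by_label(graph, label: str) -> str:
    """Id of the unique entity whose preferred label matches ``label``."""
    hits = [e.id for e in graph.entities.values() if e.label == label]
    if len(hits) != 1:
        raise KeyError(f"label {label!r} matched {len(hits)} entities")
    return hits[0]
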