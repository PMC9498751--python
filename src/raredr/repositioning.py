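"""Four candidate-generation approaches for rare-disease drug repositioning.

Given a knowledge graph and a rare disease, four complementary strategies
propose drugs already approved for other indications:

1. **Triples** — rank non-rare diseases by feature-wise Jaccard similarity
   (five feature kinds), collect drugs indicated for the top-k neighbors of
   each kind, keep drugs shared by at least ``share_min`` neighbors, and
   intersect the non-empty per-feature drug groups.
2. **Triples with associated target** — as above, but a drug only counts
   for a neighbor if the rare and the neighbor disease share a gene that
   encodes one of the drug's target proteins.
3. **Direct** — drugs targeting a protein encoded by one of the rare
   disease's own genes.
4. **Paths** — six fixed traversals from the rare disease through symptoms,
   diseases, genes, proteins and protein interactions to drugs; the final
   set is the intersection of the non-empty path sets.

Two combiners intersect the non-empty approach sets: over all four
("ALL"), and over the last three only ("TT.DDR.P" — the triples approach
being the most generalist is dropped).

Candidate drugs already indicated for the rare disease itself are known
treatments, not repositioning hypotheses; they are reported separately and
excluded from every candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .kg_model import FEATURES, KnowledgeGraph
from .similarity import rank_neighbors

__all__ = [
    "APPROACHES",
    "PATH_LABELS",
    "RepositioningParams",
    "ApproachResult",
    "triples_approach",
    "triples_target_approach",
    "direct_approach",
    "paths_approach",
    "combine",
    "run_all",
]

APPROACHES = ("triples", "triples_target", "direct", "paths")
PATH_LABELS = ("P1", "P2", "P3", "P4", "P5", "P6")


@dataclass(frozen=True)
class RepositioningParams:
    """Tunables shared by all four approaches.

    ``share_min`` quantifies "shared among the top-k neighbors": a drug
    must be linked to at least this many of the k neighbors (set it to k
    for a strict-intersection reading).  ``strict_features`` makes an empty
    per-feature drug group collapse the triples result to empty instead of
    being skipped.  ``restrict_intermediates_to_nonrare`` keeps the
    disease intermediates of paths P2-P4 non-rare.  ``exclude_known``
    removes drugs already indicated for the rare disease from all outputs.
    """

    k: int = 5
    share_min: int = 2
    strict_features: bool = False
    restrict_intermediates_to_nonrare: bool = True
    exclude_known: bool = True


@dataclass(frozen=True)
class ApproachResult:
    """Per-disease candidate drug sets, intermediates, and combined sets."""

    rare_id: str
    per_approach: Mapping[str, frozenset[str]]
    per_feature_triples: Mapping[str, frozenset[str]]
    per_path: Mapping[str, frozenset[str]]
    all_combined: frozenset[str]
    ttddrp_combined: frozenset[str]
    known_treatments: frozenset[str] = frozenset()

    @property
    def candidate_drugs(self) -> frozenset[str]:
        """Union of the four approaches' candidate sets."""
        out: frozenset[str] = frozenset()
        for s in self.per_approach.values():
            out |= s
        return out


def _known_treatments(graph: KnowledgeGraph, rare_id: str) -> frozenset[str]:
    return graph.indicated_drugs(rare_id)


def _intersect_nonempty(sets: Iterable[frozenset[str]]) -> frozenset[str]:
    nonempty = [s for s in sets if s]
    if not nonempty:
        return frozenset()
    out = set(nonempty[0])
    for s in nonempty[1:]:
        out &= s
    return frozenset(out)


def _shares_target_gene(
    graph: KnowledgeGraph, rare_id: str, neighbor_id: str, drug_id: str
) -> bool:
    """Do rare and neighbor share a gene encoding one of the drug's targets?"""
    shared = graph.feature_set(rare_id, "gene") & graph.feature_set(neighbor_id, "gene")
    if not shared:
        return False
    targets = graph.target_proteins(drug_id)
    if not targets:
        return False
    return any(graph.encoded_proteins(g) & targets for g in shared)


def _feature_drug_groups(
    graph: KnowledgeGraph,
    rare_id: str,
    params: RepositioningParams,
    require_target_gene: bool,
) -> dict[str, frozenset[str]]:
    groups: dict[str, frozenset[str]] = {}
    for feature in FEATURES:
        ranking = rank_neighbors(graph, rare_id, feature, k=params.k)
        counts: dict[str, int] = {}
        for neighbor_id in ranking.neighbor_ids:
            for drug_id in graph.indicated_drugs(neighbor_id):
                if require_target_gene and not _shares_target_gene(
                    graph, rare_id, neighbor_id, drug_id
                ):
                    continue
                counts[drug_id] = counts.get(drug_id, 0) + 1
        groups[feature] = frozenset(
            d for d, c in counts.items() if c >= params.share_min
        )
    return groups


def _strip_known(drugs: frozenset[str], known: frozenset[str],
                 params: RepositioningParams) -> frozenset[str]:
    return drugs - known if params.exclude_known else drugs


def triples_approach(
    graph: KnowledgeGraph,
    rare_id: str,
    params: RepositioningParams = RepositioningParams(),
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Per-feature drug groups from top-k similar diseases, and their
    cross-feature intersection (non-empty groups only, unless strict)."""
    known = _known_treatments(graph, rare_id)
    groups = _feature_drug_groups(graph, rare_id, params, require_target_gene=False)
    groups = {f: _strip_known(s, known, params) for f, s in groups.items()}
    if params.strict_features and any(not s for s in groups.values()):
        return groups, frozenset()
    return groups, _intersect_nonempty(groups.values())


def triples_target_approach(
    graph: KnowledgeGraph,
    rare_id: str,
    params: RepositioningParams = RepositioningParams(),
) -> frozenset[str]:
    """Triples constrained to drugs whose target is encoded by a gene the
    rare and neighbor disease share."""
    known = _known_treatments(graph, rare_id)
    groups = _feature_drug_groups(graph, rare_id, params, require_target_gene=True)
    groups = {f: _strip_known(s, known, params) for f, s in groups.items()}
    if params.strict_features and any(not s for s in groups.values()):
        return frozenset()
    return _intersect_nonempty(groups.values())


def direct_approach(
    graph: KnowledgeGraph,
    rare_id: str,
    params: RepositioningParams = RepositioningParams(),
) -> frozenset[str]:
    """Drugs targeting a protein encoded by one of the rare disease's genes."""
    known = _known_treatments(graph, rare_id)
    out: set[str] = set()
    for gene in graph.feature_set(rare_id, "gene"):
        for protein in graph.encoded_proteins(gene):
            out |= graph.drugs_targeting(protein)
    return _strip_known(frozenset(out), known, params)


def _intermediate_diseases(
    graph: KnowledgeGraph, rare_id: str, via: frozenset[str], feature: str,
    params: RepositioningParams,
) -> set[str]:
    """Diseases (other than the rare one) sharing >=1 ``feature`` item."""
    out: set[str] = set()
    for item in via:
        out |= graph.diseases_with_feature(feature, item)
    out.discard(rare_id)
    if params.restrict_intermediates_to_nonrare:
        out &= set(graph.nonrare_disease_ids)
    return out


def paths_approach(
    graph: KnowledgeGraph,
    rare_id: str,
    params: RepositioningParams = RepositioningParams(),
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """The six path traversals and the intersection of the non-empty ones.

    P1 rare→symptom→drug; P2 rare→symptom→disease→drug;
    P3 rare→symptom→disease→gene→target→drug; P4 rare→gene→disease→drug;
    P5 rare→gene→protein→target→drug;
    P6 rare→gene→protein→ppi→target→drug.
    """
    known = _known_treatments(graph, rare_id)
    symptoms = graph.feature_set(rare_id, "symptom")
    genes = graph.feature_set(rare_id, "gene")

    p1: set[str] = set()
    for s in symptoms:
        p1 |= graph.indicated_drugs(s)

    symptom_sharers = _intermediate_diseases(graph, rare_id, symptoms, "symptom", params)
    p2: set[str] = set()
    for d in symptom_sharers:
        p2 |= graph.indicated_drugs(d)

    p3: set[str] = set()
    for d in symptom_sharers:
        for gene in graph.feature_set(d, "gene"):
            for protein in graph.encoded_proteins(gene):
                p3 |= graph.drugs_targeting(protein)

    gene_sharers = _intermediate_diseases(graph, rare_id, genes, "gene", params)
    p4: set[str] = set()
    for d in gene_sharers:
        p4 |= graph.indicated_drugs(d)

    p5: set[str] = set()
    own_proteins: set[str] = set()
    for gene in genes:
        own_proteins |= graph.encoded_proteins(gene)
    for protein in own_proteins:
        p5 |= graph.drugs_targeting(protein)

    p6: set[str] = set()
    for protein in own_proteins:
        for partner in graph.ppi_partners(protein):
            p6 |= graph.drugs_targeting(partner)

    per_path = {
        label: _strip_known(frozenset(s), known, params)
        for label, s in zip(PATH_LABELS, (p1, p2, p3, p4, p5, p6))
    }
    return per_path, _intersect_nonempty(per_path.values())


def combine(
    per_approach: Mapping[str, frozenset[str]],
) -> tuple[frozenset[str], frozenset[str]]:
    """Intersect the non-empty approach sets.

    ``all_combined`` intersects over all four approaches; ``ttddrp_combined``
    drops the triples approach and intersects over triples-target, direct
    and paths only.  Both are empty when every member is empty.
    """
    all_combined = _intersect_nonempty(per_approach[a] for a in APPROACHES)
    ttddrp_combined = _intersect_nonempty(
        per_approach[a] for a in ("triples_target", "direct", "paths")
    )
    return all_combined, ttddrp_combined


def run_approaches(
    graph: KnowledgeGraph,
    rare_id: str,
    params: RepositioningParams = RepositioningParams(),
) -> ApproachResult:
    """All four approaches plus combiners for one rare disease."""
    feature_groups, triples_combined = triples_approach(graph, rare_id, params)
    tt = triples_target_approach(graph, rare_id, params)
    direct = direct_approach(graph, rare_id, params)
    per_path, paths_combined = paths_approach(graph, rare_id, params)
    per_approach = {
        "triples": triples_combined,
        "triples_target": tt,
        "direct": direct,
        "paths": paths_combined,
    }
    all_combined, ttddrp = combine(per_approach)
    return ApproachResult(
        rare_id=rare_id,
        per_approach=per_approach,
        per_feature_triples=feature_groups,
        per_path=per_path,
        all_combined=all_combined,
        ttddrp_combined=ttddrp,
        known_treatments=_known_treatments(graph, rare_id),
    )


def run_all(
    graph: KnowledgeGraph,
    rare_ids: Sequence[str],
    params: RepositioningParams = RepositioningParams(),
) -> tuple[list[ApproachResult], pd.DataFrame]:
    """One :class:`ApproachResult` per disease plus a per-approach count
    summary table (one row per disease, columns of drug-set sizes).

    The triples column reports both the cross-feature intersection count
    and, separately, the union over feature groups.
    """
    results = [run_approaches(graph, rid, params) for rid in rare_ids]
    rows = []
    for r in results:
        union_triples: frozenset[str] = frozenset()
        for s in r.per_feature_triples.values():
            union_triples |= s
        rows.append(
            {
                "disease_id": r.rare_id,
                "triples": len(r.per_approach["triples"]),
                "triples_union": len(union_triples),
                "triples_target": len(r.per_approach["triples_target"]),
                "direct": len(r.per_approach["direct"]),
                "paths": len(r.per_approach["paths"]),
                "all": len(r.all_combined),
                "ttddrp": len(r.ttddrp_combined),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "disease_id",
            "triples",
            "triples_union",
            "triples_target",
            "direct",
            "paths",
            "all",
            "ttddrp",
        ],
    )
    return results, summary
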