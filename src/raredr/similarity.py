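"""Feature-wise Jaccard similarity between rare and non-rare diseases.

For two diseases with feature sets A and B of the same kind (genes,
symptoms, proteins, pathways or variants), similarity is the Jaccard
index |A∩B| / |A∪B|.  Rankings are deterministic: scores descending,
ties broken by ascending disease id, zero-score neighbors excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .kg_model import FEATURES, KnowledgeGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityRecord",
    "Ranking",
    "jaccard",
    "rank_neighbors",
    "all_pair_similarities",
]


@dataclass(frozen=True)
class SimilarityRecord:
    rare_id: str
    nonrare_id: str
    feature: str
    score: float


@dataclass(frozen=True)
class Ranking:
    """Top-k non-rare neighbors of one rare disease for one feature kind."""

    rare_id: str
    feature: str
    entries: tuple[tuple[str, float], ...]

    @property
    def neighbor_ids(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries)


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A∩B| / |A∪B|; 0 by convention when both sets are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def _check_rare(graph: KnowledgeGraph, rare_id: str) -> None:
    if rare_id not in graph.diseases:
        raise KeyError(f"unknown disease: {rare_id!r}")


def rank_neighbors(
    graph: KnowledgeGraph, rare_id: str, feature: str, k: int = 5
) -> Ranking:
    """Rank all non-rare diseases against ``rare_id`` by ``feature`` Jaccard.

    Returns at most ``k`` entries; zero-score neighbors never appear, so
    diseases sharing nothing can never occupy a top slot.  Ties at the
    k-th rank are truncated after the id-ordered tie-break (logged when
    triggered) so the result length is deterministic.
    """
    _check_rare(graph, rare_id)
    a = graph.feature_set(rare_id, feature)
    scored = [
        (nid, jaccard(a, graph.feature_set(nid, feature)))
        for nid in graph.nonrare_disease_ids
    ]
    positive = sorted(
        ((nid, s) for nid, s in scored if s > 0.0), key=lambda t: (-t[1], t[0])
    )
    if len(positive) > k and positive[k][1] == positive[k - 1][1]:
        logger.info(
            "rank_neighbors(%s, %s): tie at rank %d truncated", rare_id, feature, k
        )
    return Ranking(rare_id=rare_id, feature=feature, entries=tuple(positive[:k]))


def all_pair_similarities(
    graph: KnowledgeGraph, rare_ids: Sequence[str], feature: str
) -> list[SimilarityRecord]:
    """One record per (rare, non-rare) pair; the background distribution
    for the downstream hypothesis tests as well as the ranking input."""
    if not rare_ids:
        raise ValueError("rare_ids must be non-empty")
    if feature not in FEATURES:
        raise KeyError(f"unknown feature kind: {feature!r}")
    records = []
    for rid in rare_ids:
        _check_rare(graph, rid)
        a = graph.feature_set(rid, feature)
        for nid in graph.nonrare_disease_ids:
            records.append(
                SimilarityRecord(
                    rare_id=rid,
                    nonrare_id=nid,
                    feature=feature,
                    score=jaccard(a, graph.feature_set(nid, feature)),
                )
            )
    return records
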