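"""Filter a disease universe down to a study set of rare diseases.

The selection workflow mirrors how a rare-disease repositioning study
narrows its scope: keep rare diseases, require them to carry association
data, drop the ones that already have a treatment, require both gene and
symptom annotations, and restrict by geographic and numeric prevalence.
Each stage's survivor count is reported as an attrition table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .kg_model import FEATURES, KnowledgeGraph

logger = logging.getLogger(__name__)

__all__ = ["SelectionCriteria", "SelectionResult", "select_diseases"]


@dataclass(frozen=True)
class SelectionCriteria:
    require_rare: bool = True
    require_in_graph: bool = True
    exclude_with_treatment: bool = True
    require_genes_and_symptoms: bool = True
    geography_whitelist: frozenset[str] | None = frozenset({"Worldwide"})
    prevalence_whitelist: frozenset[str] | None = frozenset({"<1/1000000"})
    max_genes: int | None = None
    max_symptoms: int | None = None

    def __post_init__(self) -> None:
        if not any(
            (
                self.require_rare,
                self.require_in_graph,
                self.exclude_with_treatment,
                self.require_genes_and_symptoms,
                self.geography_whitelist is not None,
                self.prevalence_whitelist is not None,
                self.max_genes is not None,
                self.max_symptoms is not None,
            )
        ):
            raise ValueError("at least one selection criterion must be enabled")


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    attrition: tuple[tuple[str, int], ...]

    def attrition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.attrition, columns=["stage", "surviving_count"])


def _stage_predicates(graph: KnowledgeGraph, criteria: SelectionCriteria):
    """(stage name, predicate) pairs in the fixed report order.

    The survivor set is order-independent (pure predicate conjunction);
    only the attrition report depends on this order.
    """
    stages = []
    if criteria.require_rare:
        stages.append(("rare", lambda d: graph.diseases[d].is_rare))
    if criteria.require_in_graph:
        stages.append(
            (
                "in_graph",
                lambda d: any(graph.feature_set(d, f) for f in FEATURES),
            )
        )
    if criteria.exclude_with_treatment:
        stages.append(("no_treatment", lambda d: not graph.indicated_drugs(d)))
    if criteria.require_genes_and_symptoms:
        stages.append(
            (
                "has_genes_and_symptoms",
                lambda d: bool(graph.feature_set(d, "gene"))
                and bool(graph.feature_set(d, "symptom")),
            )
        )
    if criteria.geography_whitelist is not None:
        allowed_geo = frozenset(criteria.geography_whitelist)
        stages.append(
            (
                "geography",
                lambda d: graph.diseases[d].prevalence_geography in allowed_geo,
            )
        )
    if criteria.prevalence_whitelist is not None:
        allowed_prev = frozenset(criteria.prevalence_whitelist)
        stages.append(
            (
                "prevalence",
                lambda d: graph.diseases[d].prevalence_class in allowed_prev,
            )
        )
    if criteria.max_genes is not None or criteria.max_symptoms is not None:

        def within_ceilings(d: str) -> bool:
            if (
                criteria.max_genes is not None
                and len(graph.feature_set(d, "gene")) > criteria.max_genes
            ):
                return False
            if (
                criteria.max_symptoms is not None
                and len(graph.feature_set(d, "symptom")) > criteria.max_symptoms
            ):
                return False
            return True

        stages.append(("ceilings", within_ceilings))
    return stages


def select_diseases(
    graph: KnowledgeGraph, criteria: SelectionCriteria = SelectionCriteria()
) -> SelectionResult:
    """Apply every enabled criterion; return survivors plus attrition report.

    Survivors are sorted by id.  An empty result is not an error (a warning
    is logged).
    """
    survivors = sorted(graph.diseases)
    attrition = [("universe", len(survivors))]
    for stage, predicate in _stage_predicates(graph, criteria):
        survivors = [d for d in survivors if predicate(d)]
        attrition.append((stage, len(survivors)))
    if not survivors:
        logger.warning("disease selection produced an empty study set")
    return SelectionResult(selected=tuple(survivors), attrition=tuple(attrition))
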