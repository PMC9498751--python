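"""Benchmark helpers: planted-signal recovery of the four approaches.

The synthetic generator plants repositioning hypotheses; these helpers
measure how often each candidate-generation approach (and the combined
sets) recovers the planted drug, aggregated over plants and seeds.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

from .repositioning import APPROACHES, RepositioningParams, run_approaches
from .synthetic_data import GeneratorConfig, PlantedTruth, generate

__all__ = ["recovery_by_approach", "recovery_over_seeds"]

_SLOTS = APPROACHES + ("all_combined", "ttddrp_combined")


def recovery_by_approach(
    graph,
    plants: Sequence[PlantedTruth],
    params: RepositioningParams = RepositioningParams(),
) -> dict[str, float]:
    """Fraction of plants whose drug each approach (and combiner) recovers."""
    hits = {slot: 0 for slot in _SLOTS}
    for plant in plants:
        result = run_approaches(graph, plant.rare_disease_id, params)
        for approach in APPROACHES:
            if plant.drug_id in result.per_approach[approach]:
                hits[approach] += 1
        if plant.drug_id in result.all_combined:
            hits["all_combined"] += 1
        if plant.drug_id in result.ttddrp_combined:
            hits["ttddrp_combined"] += 1
    n = len(plants)
    return {slot: hits[slot] / n for slot in _SLOTS} if n else dict.fromkeys(_SLOTS, 0.0)


def recovery_over_seeds(
    base_config: GeneratorConfig,
    seeds: Iterable[int],
    params: RepositioningParams = RepositioningParams(),
) -> dict[str, float]:
    """Aggregate recovery over freshly generated graphs, one per seed."""
    totals = {slot: 0.0 for slot in _SLOTS}
    n = 0
    for seed in seeds:
        graph, plants = generate(replace(base_config, seed=seed))
        rates = recovery_by_approach(graph, plants, params)
        for slot in _SLOTS:
            totals[slot] += rates[slot] * len(plants)
        n += len(plants)
    return {slot: totals[slot] / n for slot in _SLOTS} if n else dict.fromkeys(_SLOTS, 0.0)
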