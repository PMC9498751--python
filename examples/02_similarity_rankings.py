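"""Rank non-rare diseases against a rare disease by feature-wise Jaccard.

On a strong-signal graph (confederates copy all of the rare disease's
features), the top-5 neighbors of every feature are exactly the five
confederates, each with similarity 1.0.
"""

from raredr import FEATURES, GeneratorConfig, generate, rank_neighbors

config = GeneratorConfig(seed=2, planted_overlap=1.0, background_overlap=0.0)
graph, plants = generate(config)
plant = plants[0]

print(f"rare disease {plant.rare_disease_id}; "
      f"confederates {sorted(plant.confederate_disease_ids)}\n")
for feature in FEATURES:
    ranking = rank_neighbors(graph, plant.rare_disease_id, feature, k=5)
    shown = ", ".join(f"{n}={s:.2f}" for n, s in ranking.entries)
    print(f"{feature:>8}: {shown}")
# A score of 1.00 means identical feature sets; the id-sorted tie-break
# makes the ordering deterministic.
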