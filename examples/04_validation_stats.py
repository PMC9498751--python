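"""Downstream validation analytics.

1. The bundled 12-disease literature-verification table and its totals.
2. ATC 1st-level composition of a candidate drug set.
3. Phenotypic-similarity test (Welch's t) on planted hypothesis pairs.
4. GDA-strength test (Mann-Whitney U) on planted (disease, gene) pairs.
"""

from raredr import GeneratorConfig, generate, run_approaches
from raredr.casestudy import case_study_validation_summary
from raredr.downstream_stats import (
    atc_level1_composition,
    gda_pairs_from_results,
    gda_test,
    hypothesis_pairs_from_results,
    phenotypic_similarity_test,
)

summary = case_study_validation_summary()
print(summary.with_totals_row().to_string(index=False))
totals = summary.totals
print(f"\n{totals['checked']} checked drugs: {totals['therapeutic']} therapeutic, "
      f"{totals['toxic']} toxic; "
      f"{summary.fraction_with_therapeutic:.0%} of diseases have a therapeutic hit, "
      f"{summary.fraction_with_any_evidence:.0%} have any literature evidence\n")

graph, plants = generate(GeneratorConfig(seed=4, planted_overlap=1.0,
                                         background_overlap=0.0))
results = [run_approaches(graph, p.rare_disease_id) for p in plants]

candidates = sorted(set().union(*(r.candidate_drugs for r in results)))
histogram = atc_level1_composition(candidates, graph)
print("ATC level-1 composition of the candidate set:",
      {k: v for k, v in histogram.items() if v})

ps = phenotypic_similarity_test(graph, hypothesis_pairs_from_results(graph, results))
print(f"\nphenotypic similarity: hypothesis mean {ps.mean_hypothesis:.3f} vs "
      f"background mean {ps.mean_background:.3f}, p = {ps.p_value:.2e} "
      f"({ps.direction})")
# A small p with direction "expected" says the hypothesis pairs share far
# more symptoms than random rare/non-rare pairs.

for disease_id, res in gda_test(graph, gda_pairs_from_results(graph, results)).items():
    mean_hyp = sum(res.gda_scores) / len(res.gda_scores)
    print(f"GDA {disease_id}: target-gene score {mean_hyp:.2f} vs background, "
          f"p = {res.p_value:.3f} ({res.direction})")
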