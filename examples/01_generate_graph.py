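"""Generate a synthetic disease knowledge graph with planted hypotheses.

Builds a DISNET-style graph (rare + non-rare diseases, five feature
layers, drugs with indications and targets, PPI, GDA scores) in which
three repositioning hypotheses are planted, then prints its shape and the
ground truth.
"""

from raredr import GeneratorConfig, generate, feature_profile

config = GeneratorConfig(seed=1)
graph, plants = generate(config)

print(f"diseases: {len(graph.diseases)} "
      f"({len(graph.rare_disease_ids)} rare, {len(graph.nonrare_disease_ids)} non-rare)")
print(f"drugs: {len(graph.drugs)}; disease-gene edges: {len(graph.disease_gene)}; "
      f"disease-symptom edges: {len(graph.disease_symptom)}; PPI edges: {len(graph.ppi)}")

rid = plants[0].rare_disease_id
profile = feature_profile(graph, rid)
print(f"\nprofile of {rid}: {len(profile.genes)} genes, {len(profile.symptoms)} symptoms, "
      f"{len(profile.proteins)} proteins, {len(profile.pathways)} pathways, "
      f"{len(profile.variants)} variants")

print("\nplanted ground truth (rare disease, drug, shared gene, confederates):")
for p in plants:
    print(f"  {p.rare_disease_id}  {p.drug_id}  {p.shared_gene}  "
          f"{sorted(p.confederate_disease_ids)}")
# Each planted drug targets the protein encoded by the shared gene and is
# indicated for every confederate; the pipeline should recover it.
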