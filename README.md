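# raredr — feature-based drug repositioning for rare diseases

Most rare diseases have no approved treatment: their low prevalence makes
de-novo drug development commercially unattractive, so computational drug
repositioning — finding a new indication for an already-approved drug — is
one of the few tractable routes to therapy. `raredr` implements a
repositioning pipeline over a disease-centric biomedical knowledge graph
(diseases, genes, symptoms, proteins, pathways, variants, drugs and the
edges between them, in the style of the DISNET platform), from disease
selection through candidate generation to statistical validation. Because
such knowledge-base snapshots are not redistributable, the package ships a
synthetic graph generator with *planted* repositioning hypotheses, so every
stage is testable end to end with known ground truth.

## The method

**Disease similarity.** For each biological feature kind
f ∈ {genes, symptoms, proteins, pathways, variants}, a rare disease with
feature set *A* and a non-rare disease with feature set *B* are compared by
the Jaccard index

    J(A, B) = |A ∩ B| / |A ∪ B|

and, per feature kind, the top-5 most similar non-rare diseases are kept
(ties broken by disease id; zero-score neighbors excluded).

**Candidate generation.** Four approaches propose drugs for a rare disease *r*:

1. **Triples** — drugs indicated for ≥ `share_min` (default 2) of the top-5
   neighbors of each feature kind; the per-feature drug groups are then
   intersected (empty groups skipped).
2. **Triples with associated target (TT)** — as above, but a drug only
   counts for a neighbor if *r* and the neighbor share a gene encoding one
   of the drug's target proteins.
3. **Direct (DDR)** — drugs targeting a protein encoded by one of *r*'s own
   genes.
4. **Paths (P)** — six traversals
   (r→symptom→drug, r→symptom→disease→drug, r→symptom→disease→gene→target→drug,
   r→gene→disease→drug, r→gene→protein→target→drug,
   r→gene→protein→PPI→target→drug); the result is the intersection of the
   non-empty path sets.

Two combiners intersect the non-empty approach sets: **ALL** (all four) and
**TT.DDR.P** (dropping the generalist triples approach). Drugs already
indicated for the rare disease are known treatments, not hypotheses, and
are excluded.

**Validation analytics.** Candidates verified in the literature are tallied
per disease (therapeutic vs toxic); the candidate set is profiled by ATC
1st-level class (the 14 anatomical/pharmacological groups); symptom-Jaccard
of hypothesis disease pairs is compared to the rare × non-rare background
with a two-sided Welch's t-test; and the gene–disease association (GDA)
scores of candidate target genes are compared to the background GDA
distribution with a two-sided Mann–Whitney U test. Directions are reported
so "reversed" separations stay visible.

## Worked example

```sh
python examples/03_repositioning_candidates.py
```

```
disease_id  triples  triples_union  triples_target  direct  paths  all  ttddrp
    RD0000        1              1               1      20      1    1       1
    RD0004        1              1               1       4      1    1       1
    RD0005        2              2               2      19      1    1       1

RD0000: planted drug D0000 RECOVERED in the combined set (size 1)
RD0004: planted drug D0002 RECOVERED in the combined set (size 1)
RD0005: planted drug D0001 RECOVERED in the combined set (size 1)
```

Each row counts the candidate drugs per approach for one rare disease of a
strong-signal synthetic graph: the direct approach is broad (every drug
targeting a protein of the disease's genes), the others are narrow, and
intersecting the non-empty sets (`all`) pins down exactly the planted drug
for each disease. The other examples cover graph generation, similarity
rankings, the validation statistics and the full pipeline; each prints a
short interpretation of its numbers.

A command-line interface mirrors the stages:

```sh
raredr generate --out graph/ --seed 1
raredr select --graph graph/ --out selected.tsv
raredr reposition --graph graph/ --rare selected.tsv --out results/
raredr run --config pipeline.yaml
```

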