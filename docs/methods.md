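# Methods

## Data model

The pipeline operates on an immutable knowledge graph with three layers: a
biological layer (disease–gene, disease–protein, disease–pathway,
disease–variant associations, gene→protein encoding, and an undirected
protein–protein interaction set), a phenotypical layer (disease–symptom
associations), and a drugs layer (drug→indication and drug→target edges,
plus per-(gene, disease) association scores). Identifiers are opaque
strings; concept-id formatting (e.g. UMLS-style CUIs) is not enforced
beyond non-emptiness, so synthetic ids and real vocabularies interchange
freely. Symptoms share the indication-target concept space with diseases —
a drug may be indicated for either — and a node-role table disambiguates.
Disease–protein edges are stored as an independent edge set rather than
derived from gene→protein encoding, since annotation sources treat them as
first-class.

Prevalence is a closed seven-class vocabulary (six ordered classes from
`>1/1000` down to `<1/1000000`, plus `unknown`, into which the Null /
Unknown / Not-yet-documented source variants collapse).

Persistence is a set of UTF-8 tab-delimited files with headers, chosen
over a binary graph format so fixtures stay hand-editable and diffable.
Rows are written in a fixed sort with a fixed column order, and float
scores with `repr`, so save → load → save is byte-stable and lossless.
Duplicate edges in inputs are deduplicated with a warning (edge sets are
sets). `load_graph` takes the directory holding the fixed-name file set.

## Synthetic graphs and planted signal

The generator emulates the statistical shape of a disease-knowledge-base
snapshot rather than any real distribution. Defaults: 13 rare and 150
non-rare diseases, 120 drugs, and per-disease feature-set sizes drawn
uniformly from 1–44 genes and 1–237 symptoms (the spread observed across
the 13-disease case-study set this pipeline was designed around), with
smaller ranges for proteins (1–40), pathways (1–15) and variants (1–30).
Background diseases share features through a small "hub" sub-vocabulary
(the first ~5% of each vocabulary) hit with probability
`background_overlap` (default 0.1), which keeps background Jaccard scores
small but non-degenerate — necessary for the downstream Welch and
Mann–Whitney background distributions to have spread.

Each planted hypothesis wires a rare disease, a dedicated drug, and
`confederates_per_plant` (default 5) non-rare "confederates" so that the
drug is recoverable by *every* approach:

* each confederate's feature sets are rebuilt as a `planted_overlap`
  fraction of the rare disease's sets plus a `(1 − planted_overlap)`
  -thinned remnant of its own background (at overlap 1.0 the sets are
  identical, making confederate Jaccard exactly 1);
* a shared gene, present in the rare disease and every confederate,
  encodes the drug's target protein (triples-with-target and direct
  routes);
* the drug is indicated for every confederate (triples and
  disease-mediated paths), for one symptom of the rare disease (the
  symptom→drug path), and a PPI edge links the target protein to a protein
  encoded by another of the rare disease's genes (the PPI path);
* the drug is never indicated for the rare disease itself — repositioning
  means a new indication.

GDA scores are Beta-distributed: planted (shared gene, rare disease) pairs
draw from Beta(8, 2), background pairs from Beta(2, 8) (both
configurable); DSI/DPI are per-gene Uniform(0.2, 0.9). One global seed
spawns named per-component substreams in fixed order, so extending the
generator never perturbs existing components, and identical configs yield
byte-identical saved file sets.

The generator reproduces overlap *structure*, not realism: it has no
degree heterogeneity beyond the hub mechanism, no ontology structure among
symptoms, and feature kinds are sampled independently. Passing tests
therefore demonstrate correctness of the pipeline's logic and its
statistical calibration under controlled signal, not expected performance
on a real knowledge base.

A separate fixture reproduces the 13 case-study rare diseases with their
exact gene and symptom set sizes (feature identifiers synthetic, only
cardinalities faithful); protein/pathway/variant sizes for these fixtures
are generator defaults, as only gene/symptom counts are on record.

## Selection

Filters compose as a pure conjunction — survivors are order-independent,
only the attrition report is order-defined (rare → in graph → no treatment
→ has genes & symptoms → geography → prevalence → ceilings). "Has a
treatment" is operationalized as ≥ 1 indication edge pointing at the
disease; "information on genes and symptoms" as both sets non-empty;
"present in the knowledge base" as carrying ≥ 1 association edge of any
kind. Optional gene/symptom ceilings exist for cost control but have no
default, since no principled threshold presents itself. An empty survivor
set is a logged warning, not an error.

## Similarity and ranking

Jaccard of two empty sets is defined as 0, and zero-score neighbors are
excluded from rankings, so diseases sharing nothing can never occupy top-k
slots (with zero-padding, "top 5" would be arbitrary). Ties are broken by
ascending disease id and then truncated at k (logged when a tie crosses
the boundary), keeping rankings deterministic and of length ≤ k. k = 5 by
default.

## Candidate generation

"Shared among the drugs of the top-k neighbors" is read minimally: a drug
counts if linked to ≥ `share_min` (default 2) of the k neighbors;
`share_min = k` recovers a strict-intersection reading. Cross-feature and
cross-path combination intersect only the *non-empty* member sets (a
strict mode is available behind `strict_features`), mirroring the
non-empty-set intersection of the approach combiners: a single non-empty
member passes through unchanged. Path intermediates (the disease hops of
P2–P4) are restricted to non-rare diseases by default (configurable); the
rare disease itself is always excluded as an intermediate. P3's "targets"
are the proteins encoded by the intermediate diseases' genes that appear
in drug-target edges (gene → protein → target chain). P5 traverses the
same chain as the direct approach and must equal it on every graph — kept
as a structural regression test. All drug sets are id-sorted on output.

Known treatments (drugs already indicated for the rare disease) are
reported separately and excluded from candidate sets by default.

## Statistics

* **Phenotypic similarity.** Hypothesis pairs must link a rare and a
  non-rare disease sharing a gene that encodes a drug-target protein
  (checked; violating pairs are an error). Symptom-Jaccard of the
  hypothesis pairs is compared to all rare × non-rare pairs with a
  two-sided Welch's t-test (`scipy.stats.ttest_ind(equal_var=False)`);
  the direction (expected/reversed) is reported alongside p.
* **Type-I calibration.** The null simulation samples pseudo-hypothesis
  groups (n = 50) from the background score population of a *signal-free*
  graph (no planted hypotheses) and measures the rejection rate over 1000
  repetitions. With planted signal present the population contains genuine
  near-1 outlier pairs, and elevated rejection reflects real effects
  rather than miscalibration — hence the signal-free null universe.
* **GDA strength.** Per rare disease, candidate-target-gene GDA scores are
  compared to every GDA score in the graph (hypothesis records included;
  `leave_out` excludes them) with a two-sided Mann–Whitney U. Power is
  assessed by simulation from the generator's planted/background Beta
  shapes (20 hypothesis scores vs 200 background, 500 reps).
* p-values are raw; no multiple-testing correction across diseases is
  applied (a known limitation — per-disease reporting mirrors how such
  validation tables are usually presented).
* The bundled case-study verification table satisfies, per disease,
  checked = therapeutic + toxic ≤ computational, adopted as a load-time
  invariant. Its column sums give 380 computational candidates, 60
  checked, 27 therapeutic, 33 toxic; the derived per-disease success
  fractions are 8/12 (≥ 1 therapeutic drug) and 11/12 (any evidence), and
  both are reported rather than any single headline figure.

## Determinism and problem sizes

Every stochastic component is seeded; the pipeline writes its resolved
configuration, package version and SHA-256 input digests into a manifest,
and a rerun with identical config and inputs is byte-identical. The
benchmark suites run on deliberately small graphs (6 rare / 60 non-rare
diseases, 60 drugs, vocabularies of 80–300 per feature) — large enough for
non-trivial background overlap, small enough that 20-seed recovery sweeps
and 1000-rep calibration loops complete in seconds; the defaults
(13/150/120) exercise the full-size study conditions.

## Known limitations

Literature/clinical-trial verification is inherently manual and enters
only as a record table; the generator does not fit real degree
distributions; ATC codes in synthetic drugs are structurally valid but
pharmacologically meaningless; DSI/DPI are carried as input scores, never
recomputed from first principles.
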