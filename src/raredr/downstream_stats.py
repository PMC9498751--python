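"""Validation-side analytics for repositioning candidates.

Covers four post-hoc analyses:

* bookkeeping of literature/clinical-trial verification outcomes per
  candidate drug (therapeutic vs toxic vs unverified) and their totals;
* composition of a drug set by ATC 1st-level class (the 14 anatomical /
  pharmacological groups);
* a phenotypic-similarity hypothesis test — are repositioning-hypothesis
  disease pairs more symptom-similar than background rare x non-rare
  pairs? (Welch's t-test, unequal variances, two-sided);
* a gene-disease association (GDA) strength test — are the target genes
  of candidate drugs more strongly associated with their rare disease
  than background GDAs? (Mann-Whitney U, two-sided).

Sidedness note: both tests are two-sided and the observed direction is
reported separately, so hypothesis groups that separate in the *opposite*
direction from the repositioning rationale are flagged as reversed rather
than hidden.  p-values are reported raw, with no multiple-testing
correction across diseases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kg_model import ATC_LEVEL1, KnowledgeGraph
from .repositioning import ApproachResult
from .similarity import SimilarityRecord, jaccard

__all__ = [
    "VALIDATION_STATUSES",
    "ValidationRecord",
    "ValidationSummary",
    "summarize_validation",
    "summary_from_counts",
    "atc_level1_composition",
    "PhenotypicTestResult",
    "phenotypic_similarity_test",
    "welch_null_rejection_rate",
    "mannwhitney_power",
    "GDATestResult",
    "gda_test",
    "hypothesis_pairs_from_results",
    "gda_pairs_from_results",
]

VALIDATION_STATUSES = ("therapeutic", "toxic", "unverified")


@dataclass(frozen=True)
class ValidationRecord:
    """Literature/clinical-trial verdict on one (disease, drug) candidate."""

    disease_id: str
    drug_id: str
    status: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.status not in VALIDATION_STATUSES:
            raise ValueError(
                f"status {self.status!r} not in {VALIDATION_STATUSES}"
            )


@dataclass(frozen=True)
class ValidationSummary:
    """Per-disease candidate/checked/therapeutic/toxic counts plus totals.

    Invariants (enforced): per disease, checked = therapeutic + toxic and
    checked <= computational; totals are column sums.
    """

    per_disease: pd.DataFrame  # disease_id, computational, checked, therapeutic, toxic

    def __post_init__(self) -> None:
        df = self.per_disease
        required = ["disease_id", "computational", "checked", "therapeutic", "toxic"]
        if list(df.columns) != required:
            raise ValueError(f"per_disease must have columns {required}")
        bad = df[df["checked"] != df["therapeutic"] + df["toxic"]]
        if len(bad):
            raise ValueError(
                "checked != therapeutic + toxic for "
                + ", ".join(bad["disease_id"])
            )
        over = df[df["checked"] > df["computational"]]
        if len(over):
            raise ValueError(
                "checked > computational for " + ", ".join(over["disease_id"])
            )

    @property
    def totals(self) -> dict[str, int]:
        df = self.per_disease
        return {
            col: int(df[col].sum())
            for col in ("computational", "checked", "therapeutic", "toxic")
        }

    @property
    def fraction_with_therapeutic(self) -> float:
        """Fraction of diseases with at least one therapeutic checked drug."""
        df = self.per_disease
        return float((df["therapeutic"] > 0).mean())

    @property
    def fraction_with_any_evidence(self) -> float:
        """Fraction of diseases with at least one checked drug."""
        df = self.per_disease
        return float((df["checked"] > 0).mean())

    def with_totals_row(self) -> pd.DataFrame:
        df = self.per_disease.copy()
        totals = self.totals
        totals["disease_id"] = "TOTAL"
        return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)[
            df.columns
        ]


def summary_from_counts(counts: pd.DataFrame) -> ValidationSummary:
    """Build a summary from a per-disease count table (validating it)."""
    df = counts[["disease_id", "computational", "checked", "therapeutic", "toxic"]]
    df = df.reset_index(drop=True).astype(
        {"computational": int, "checked": int, "therapeutic": int, "toxic": int}
    )
    return ValidationSummary(per_disease=df)


def summarize_validation(
    records: Iterable[ValidationRecord],
    results: Sequence[ApproachResult],
) -> ValidationSummary:
    """Count verification outcomes against each disease's candidate set.

    A record referencing a drug that is not among its disease's candidates
    is a validation error.  Unverified records count as computational
    candidates that were looked up but not confirmed; they are not
    "checked".
    """
    by_disease = {r.rare_id: r for r in results}
    seen: set[tuple[str, str]] = set()
    counts = {
        r.rare_id: {"checked": 0, "therapeutic": 0, "toxic": 0} for r in results
    }
    for rec in records:
        if rec.disease_id not in by_disease:
            raise ValueError(f"record for unknown disease {rec.disease_id!r}")
        if (rec.disease_id, rec.drug_id) in seen:
            raise ValueError(
                f"duplicate record for ({rec.disease_id}, {rec.drug_id})"
            )
        seen.add((rec.disease_id, rec.drug_id))
        if rec.drug_id not in by_disease[rec.disease_id].candidate_drugs:
            raise ValueError(
                f"drug {rec.drug_id!r} is not a candidate for {rec.disease_id!r}"
            )
        if rec.status in ("therapeutic", "toxic"):
            counts[rec.disease_id]["checked"] += 1
            counts[rec.disease_id][rec.status] += 1
    rows = [
        {
            "disease_id": r.rare_id,
            "computational": len(r.candidate_drugs),
            **counts[r.rare_id],
        }
        for r in results
    ]
    return ValidationSummary(
        per_disease=pd.DataFrame(
            rows,
            columns=["disease_id", "computational", "checked", "therapeutic", "toxic"],
        )
    )


def atc_level1_composition(
    drug_ids: Iterable[str], graph: KnowledgeGraph
) -> dict[str, int]:
    """Count drugs per ATC 1st-level class.

    A drug whose codes span c distinct level-1 classes contributes 1 to
    each of the c classes; a drug without any ATC code counts under
    ``"unclassified"``.  All 14 classes are present in the output (possibly
    zero).
    """
    out = {letter: 0 for letter in sorted(ATC_LEVEL1)}
    out["unclassified"] = 0
    for drug_id in drug_ids:
        if drug_id not in graph.drugs:
            raise KeyError(f"unknown drug: {drug_id!r}")
        classes = graph.drugs[drug_id].atc_level1
        if not classes:
            out["unclassified"] += 1
        for letter in classes:
            out[letter] += 1
    return out


# ---------------------------------------------------------------------------
# Phenotypic similarity: hypothesis pairs vs background (Welch's t)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypicTestResult:
    mean_hypothesis: float
    mean_background: float
    p_value: float
    n_hypothesis: int
    n_background: int

    @property
    def direction(self) -> str:
        """"expected" if hypothesis pairs are more similar than background,
        else "reversed"."""
        return (
            "expected" if self.mean_hypothesis >= self.mean_background else "reversed"
        )


def _pair_shares_target_gene(
    graph: KnowledgeGraph, rare_id: str, nonrare_id: str
) -> bool:
    shared = graph.feature_set(rare_id, "gene") & graph.feature_set(
        nonrare_id, "gene"
    )
    targeted = {p for _, p in graph.drug_target}
    return any(graph.encoded_proteins(g) & targeted for g in shared)


def phenotypic_similarity_test(
    graph: KnowledgeGraph,
    hypothesis_pairs: Iterable[tuple[str, str]],
    background: Sequence[SimilarityRecord] | None = None,
    check_shared_gene: bool = True,
) -> PhenotypicTestResult:
    """Welch's t-test of symptom Jaccard: hypothesis pairs vs background.

    Each hypothesis pair must link a rare and a non-rare disease that share
    a gene encoding a drug-target protein (the repositioning rationale);
    violating pairs raise a validation error unless the check is disabled.
    ``background`` defaults to every rare x non-rare pair in the graph.
    """
    pairs = sorted(set(hypothesis_pairs))
    if not pairs:
        raise ValueError("hypothesis_pairs must be non-empty")
    if check_shared_gene:
        bad = [p for p in pairs if not _pair_shares_target_gene(graph, *p)]
        if bad:
            raise ValueError(
                "pairs violate the shared-target-gene condition: " + str(bad)
            )
    hyp_scores = [
        jaccard(
            graph.feature_set(r, "symptom"), graph.feature_set(n, "symptom")
        )
        for r, n in pairs
    ]
    if background is None:
        from .similarity import all_pair_similarities

        background = all_pair_similarities(
            graph, list(graph.rare_disease_ids), "symptom"
        )
    bg_scores = [rec.score for rec in background]
    t = stats.ttest_ind(hyp_scores, bg_scores, equal_var=False)
    p = float(t.pvalue) if not math.isnan(t.pvalue) else 1.0
    return PhenotypicTestResult(
        mean_hypothesis=float(np.mean(hyp_scores)),
        mean_background=float(np.mean(bg_scores)),
        p_value=p,
        n_hypothesis=len(hyp_scores),
        n_background=len(bg_scores),
    )


def welch_null_rejection_rate(
    background_scores: Sequence[float],
    n_hypothesis: int = 50,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I-error simulation for the phenotypic-similarity test.

    Each repetition samples a pseudo-hypothesis group from the background
    score population itself (a true null) and runs the same two-sided
    Welch's t-test; returns the fraction of repetitions rejecting at
    ``alpha``.  A calibrated test should land near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    scores = np.asarray(background_scores, dtype=float)
    rejections = 0
    for _ in range(n_reps):
        idx = rng.choice(scores.size, size=n_hypothesis, replace=False)
        mask = np.zeros(scores.size, dtype=bool)
        mask[idx] = True
        t = stats.ttest_ind(scores[mask], scores[~mask], equal_var=False)
        if t.pvalue < alpha:
            rejections += 1
    return rejections / n_reps


def mannwhitney_power(
    planted_beta: tuple[float, float] = (8.0, 2.0),
    background_beta: tuple[float, float] = (2.0, 8.0),
    n_hypothesis: int = 20,
    n_background: int = 200,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Power simulation for the GDA strength test.

    Draws hypothesis scores from the planted Beta distribution and
    background scores from the background Beta (the synthetic generator's
    GDA model), runs the same two-sided Mann-Whitney U each repetition,
    and returns the fraction rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        hyp = rng.beta(*planted_beta, size=n_hypothesis)
        bg = rng.beta(*background_beta, size=n_background)
        u = stats.mannwhitneyu(hyp, bg, alternative="two-sided")
        if u.pvalue < alpha:
            rejections += 1
    return rejections / n_reps


# ---------------------------------------------------------------------------
# GDA strength: candidate target genes vs background (Mann-Whitney U)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GDATestResult:
    disease_id: str
    gda_scores: tuple[float, ...]
    background_scores: tuple[float, ...]
    p_value: float

    @property
    def direction(self) -> str:
        bg = float(np.mean(self.background_scores))
        hyp = float(np.mean(self.gda_scores))
        return "expected" if hyp >= bg else "reversed"


def gda_test(
    graph: KnowledgeGraph,
    pairs: Iterable[tuple[str, str]],
    leave_out: bool = False,
) -> dict[str, GDATestResult]:
    """Per-disease Mann-Whitney U of target-gene GDA scores vs background.

    ``pairs`` are (rare disease id, gene) couples that must each carry a
    GDA record.  The background is every GDA score in the graph, including
    the hypothesis records unless ``leave_out`` is set.
    """
    pairs = sorted(set(pairs))
    scores = graph.gda_scores
    by_disease: dict[str, list[float]] = {}
    hyp_keys: set[tuple[str, str]] = set()
    for rare_id, gene in pairs:
        rec = scores.get((gene, rare_id))
        if rec is None:
            raise ValueError(f"no GDA record for gene {gene!r}, disease {rare_id!r}")
        by_disease.setdefault(rare_id, []).append(rec.gda_score)
        hyp_keys.add((gene, rare_id))
    all_records = sorted(scores.items())
    out: dict[str, GDATestResult] = {}
    for rare_id, hyp_scores in sorted(by_disease.items()):
        if leave_out:
            bg = [r.gda_score for key, r in all_records if key not in hyp_keys]
        else:
            bg = [r.gda_score for _, r in all_records]
        u = stats.mannwhitneyu(hyp_scores, bg, alternative="two-sided")
        out[rare_id] = GDATestResult(
            disease_id=rare_id,
            gda_scores=tuple(hyp_scores),
            background_scores=tuple(bg),
            p_value=float(u.pvalue),
        )
    return out


# ---------------------------------------------------------------------------
# Deriving hypothesis pairs from repositioning results
# ---------------------------------------------------------------------------


def hypothesis_pairs_from_results(
    graph: KnowledgeGraph,
    results: Sequence[ApproachResult],
    use: str = "ttddrp_combined",
) -> set[tuple[str, str]]:
    """(rare, non-rare) pairs behind the surviving repositioning hypotheses.

    For each rare disease and each drug in its combined candidate set, take
    the non-rare diseases the drug is indicated for that share with the
    rare disease a gene encoding one of the drug's targets.
    """
    pairs: set[tuple[str, str]] = set()
    nonrare = set(graph.nonrare_disease_ids)
    for r in results:
        drugs = getattr(r, use)
        rare_genes = graph.feature_set(r.rare_id, "gene")
        for drug_id in drugs:
            targets = graph.target_proteins(drug_id)
            for drug, concept in graph.drug_indication:
                if drug != drug_id or concept not in nonrare:
                    continue
                shared = rare_genes & graph.feature_set(concept, "gene")
                if any(graph.encoded_proteins(g) & targets for g in shared):
                    pairs.add((r.rare_id, concept))
    return pairs


def gda_pairs_from_results(
    graph: KnowledgeGraph,
    results: Sequence[ApproachResult],
    use: str = "ttddrp_combined",
) -> set[tuple[str, str]]:
    """(rare disease, target gene) couples for the GDA strength test.

    Genes of the rare disease that encode a target protein of one of its
    candidate drugs and that carry a GDA record.
    """
    pairs: set[tuple[str, str]] = set()
    scores = graph.gda_scores
    for r in results:
        drugs = getattr(r, use)
        targets: set[str] = set()
        for drug_id in drugs:
            targets |= graph.target_proteins(drug_id)
        for gene in graph.feature_set(r.rare_id, "gene"):
            if graph.encoded_proteins(gene) & targets and (gene, r.rare_id) in scores:
                pairs.add((r.rare_id, gene))
    return pairs
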