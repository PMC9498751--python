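import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from raredr.casestudy import case_study_validation_counts, case_study_validation_summary
from raredr.downstream_stats import (
    GDATestResult,
    ValidationRecord,
    atc_level1_composition,
    gda_pairs_from_results,
    gda_test,
    hypothesis_pairs_from_results,
    mannwhitney_power,
    phenotypic_similarity_test,
    summarize_validation,
    summary_from_counts,
    welch_null_rejection_rate,
)
from raredr.kg_model import Disease, Drug, GDARecord, KnowledgeGraph
from raredr.repositioning import run_approaches
from raredr.similarity import all_pair_similarities


# ---------------------------------------------------------------------------
# validation bookkeeping
# ---------------------------------------------------------------------------


def test_case_study_validation_totals():
    summary = case_study_validation_summary()
    totals = summary.totals
    assert totals["checked"] == 60
    assert totals["toxic"] == 33
    assert totals["therapeutic"] == 27


def test_case_study_success_fractions():
    summary = case_study_validation_summary()
    assert summary.fraction_with_therapeutic == pytest.approx(8 / 12)
    assert summary.fraction_with_any_evidence == pytest.approx(11 / 12)


def test_totals_row_is_column_sum():
    df = case_study_validation_summary().with_totals_row()
    body, total = df.iloc[:-1], df.iloc[-1]
    for col in ("computational", "checked", "therapeutic", "toxic"):
        assert total[col] == body[col].sum()


def test_checked_identity_enforced():
    counts = case_study_validation_counts()
    counts.loc[0, "toxic"] += 1  # breaks checked = therapeutic + toxic
    with pytest.raises(ValueError, match="checked"):
        summary_from_counts(counts)


def test_checked_cannot_exceed_computational():
    counts = case_study_validation_counts()
    counts.loc[0, "computational"] = 0
    with pytest.raises(ValueError, match="computational"):
        summary_from_counts(counts)


def test_summarize_validation_from_records(planted_graph):
    graph, plants = planted_graph
    results = [run_approaches(graph, p.rare_disease_id) for p in plants]
    records = [
        ValidationRecord(
            disease_id=p.rare_disease_id,
            drug_id=p.drug_id,
            status="therapeutic" if i % 2 == 0 else "toxic",
        )
        for i, p in enumerate(plants)
    ]
    summary = summarize_validation(records, results)
    totals = summary.totals
    assert totals["checked"] == len(plants)
    assert totals["therapeutic"] + totals["toxic"] == totals["checked"]
    # unverified records are not "checked"
    records2 = records[:-1] + [
        ValidationRecord(
            disease_id=plants[-1].rare_disease_id,
            drug_id=plants[-1].drug_id,
            status="unverified",
        )
    ]
    assert summarize_validation(records2, results).totals["checked"] == len(plants) - 1


def test_record_for_non_candidate_drug_rejected(planted_graph):
    graph, plants = planted_graph
    results = [run_approaches(graph, plants[0].rare_disease_id)]
    with pytest.raises(ValueError, match="not a candidate"):
        summarize_validation(
            [
                ValidationRecord(
                    disease_id=plants[0].rare_disease_id,
                    drug_id="NOT_A_DRUG",
                    status="therapeutic",
                )
            ],
            results,
        )
    with pytest.raises(ValueError, match="status"):
        ValidationRecord(disease_id="x", drug_id="y", status="maybe")


# ---------------------------------------------------------------------------
# ATC composition
# ---------------------------------------------------------------------------


def _atc_graph():
    return KnowledgeGraph(
        drugs={
            "D1": Drug(id="D1", atc_codes=frozenset({"C07AG02"})),
            "D2": Drug(id="D2", atc_codes=frozenset({"L01XE05", "N02BA01"})),
            "D3": Drug(id="D3"),
        }
    )


def test_atc_single_and_multi_class_counting():
    graph = _atc_graph()
    comp = atc_level1_composition(["D1"], graph)
    assert comp["C"] == 1 and sum(comp.values()) == 1
    comp = atc_level1_composition(["D1", "D2", "D3"], graph)
    assert comp["C"] == 1 and comp["L"] == 1 and comp["N"] == 1
    assert comp["unclassified"] == 1
    # one multi-class drug makes the histogram total exceed the drug count
    assert sum(comp.values()) == 4 > 3


def test_atc_composition_matches_generator_labels(default_graph):
    graph, _ = default_graph
    drugs = sorted(graph.drugs)[:60]
    comp = atc_level1_composition(drugs, graph)
    expected: dict[str, int] = {}
    for d in drugs:
        letters = {c[0] for c in graph.drugs[d].atc_codes}
        for letter in letters:
            expected[letter] = expected.get(letter, 0) + 1
    for letter, count in expected.items():
        assert comp[letter] == count
    assert sum(comp.values()) >= len(drugs)
    with pytest.raises(KeyError):
        atc_level1_composition(["nope"], graph)


# ---------------------------------------------------------------------------
# Welch / Mann-Whitney against independent textbook computation
# ---------------------------------------------------------------------------

WELCH_SAMPLES = [
    ([0.1, 0.2, 0.15, 0.3, 0.25], [0.5, 0.6, 0.55, 0.45]),
    ([1.0, 1.1, 0.9, 1.05], [1.0, 1.2, 0.8, 1.1, 0.95]),
    ([0.0, 0.0, 0.1], [0.9, 1.0, 0.8]),
]


@pytest.mark.parametrize("a, b", WELCH_SAMPLES)
def test_welch_matches_textbook_formula(a, b):
    """Welch's statistic and Satterthwaite df computed from first principles."""
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    t = (ma - mb) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2 * sps.t.sf(abs(t), df)
    res = sps.ttest_ind(a, b, equal_var=False)
    assert res.statistic == pytest.approx(t)
    assert res.pvalue == pytest.approx(p)


def test_mannwhitney_matches_exhaustive_enumeration():
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    a, b = [0.9, 0.8, 0.7], [0.1, 0.2, 0.3, 0.4]
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    pooled = a + b
    n_a = len(a)
    count = total = 0
    mean_u = n_a * len(b) / 2
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        if abs(u - mean_u) >= abs(u_obs - mean_u):
            count += 1
        total += 1
    p_exact = count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    assert res.pvalue == pytest.approx(p_exact)


# ---------------------------------------------------------------------------
# phenotypic similarity test
# ---------------------------------------------------------------------------


def test_phenotypic_test_on_planted_signal(planted_graph):
    graph, plants = planted_graph
    pairs = {
        (p.rare_disease_id, c)
        for p in plants
        for c in p.confederate_disease_ids
    }
    res = phenotypic_similarity_test(graph, pairs)
    assert res.mean_hypothesis > res.mean_background
    assert res.p_value < 0.05
    assert res.direction == "expected"


def test_identical_diseases_score_one(planted_graph):
    graph, plants = planted_graph
    # at planted_overlap=1 the confederates' symptom sets equal the rare
    # disease's, so every hypothesis pair scores exactly 1
    plant = plants[0]
    pairs = {(plant.rare_disease_id, c) for c in plant.confederate_disease_ids}
    res = phenotypic_similarity_test(graph, pairs)
    assert res.mean_hypothesis == 1.0


def test_pairs_violating_shared_gene_condition_rejected(planted_graph):
    graph, plants = planted_graph
    plant = plants[0]
    # a non-confederate shares no target-encoding gene with the rare disease
    outsider = next(
        n
        for n in graph.nonrare_disease_ids
        if n not in plant.confederate_disease_ids
        and not graph.feature_set(plant.rare_disease_id, "gene")
        & graph.feature_set(n, "gene")
    )
    with pytest.raises(ValueError, match="shared-target-gene"):
        phenotypic_similarity_test(graph, {(plant.rare_disease_id, outsider)})
    with pytest.raises(ValueError, match="non-empty"):
        phenotypic_similarity_test(graph, set())


def test_welch_null_rejection_rate_is_calibrated_quick():
    """Light calibration check on a signal-free graph (a true null
    population); the full 1000-rep run lives in the acceptance suite."""
    from raredr.synthetic_data import GeneratorConfig, generate

    graph, _ = generate(GeneratorConfig(seed=5, n_planted=0))
    bg = [r.score for r in all_pair_similarities(
        graph, list(graph.rare_disease_ids), "symptom")]
    rate = welch_null_rejection_rate(bg, n_reps=200, seed=1)
    assert 0.01 <= rate <= 0.10


# ---------------------------------------------------------------------------
# GDA test
# ---------------------------------------------------------------------------


def _gda_graph(hyp_scores, bg_scores):
    n = len(hyp_scores) + len(bg_scores)
    diseases = {"R": Disease(id="R", is_rare=True)}
    diseases.update({f"N{i}": Disease(id=f"N{i}") for i in range(len(bg_scores))})
    genes = [f"g{i}" for i in range(n)]
    records = []
    edges = set()
    for i, s in enumerate(hyp_scores):
        records.append(GDARecord(gene=genes[i], disease_id="R", gda_score=s,
                                 dsi=0.5, dpi=0.5))
        edges.add(("R", genes[i]))
    for j, s in enumerate(bg_scores):
        g = genes[len(hyp_scores) + j]
        records.append(GDARecord(gene=g, disease_id=f"N{j}", gda_score=s,
                                 dsi=0.5, dpi=0.5))
        edges.add((f"N{j}", g))
    return KnowledgeGraph(
        diseases=diseases,
        node_roles={g: "gene" for g in genes},
        disease_gene=frozenset(edges),
        gda=frozenset(records),
    )


def test_gda_test_separates_planted_scores():
    rng = np.random.default_rng(0)
    graph = _gda_graph(
        hyp_scores=list(rng.beta(8, 2, size=20)),
        bg_scores=list(rng.beta(2, 8, size=60)),
    )
    pairs = {("R", g) for g in sorted(graph.feature_set("R", "gene"))}
    res = gda_test(graph, pairs)["R"]
    assert res.p_value < 0.05
    assert res.direction == "expected"


def test_gda_test_flags_reversed_direction():
    rng = np.random.default_rng(1)
    graph = _gda_graph(
        hyp_scores=list(rng.beta(2, 8, size=20)),
        bg_scores=list(rng.beta(8, 2, size=60)),
    )
    pairs = {("R", g) for g in sorted(graph.feature_set("R", "gene"))}
    res = gda_test(graph, pairs)["R"]
    assert res.p_value < 0.05
    assert res.direction == "reversed"


def test_gda_test_no_separation_under_constant_scores():
    graph = _gda_graph(hyp_scores=[0.5] * 5, bg_scores=[0.5] * 20)
    pairs = {("R", g) for g in sorted(graph.feature_set("R", "gene"))}
    res = gda_test(graph, pairs)["R"]
    assert res.p_value == pytest.approx(1.0)


def test_gda_test_missing_record_rejected(default_graph):
    graph, _ = default_graph
    with pytest.raises(ValueError, match="no GDA record"):
        gda_test(graph, {(graph.rare_disease_ids[0], "NOT_A_GENE")})


def test_gda_leave_out_shrinks_background():
    graph = _gda_graph(hyp_scores=[0.9, 0.8], bg_scores=[0.1] * 10)
    pairs = {("R", g) for g in sorted(graph.feature_set("R", "gene"))}
    with_hyp = gda_test(graph, pairs)["R"]
    without = gda_test(graph, pairs, leave_out=True)["R"]
    assert len(with_hyp.background_scores) == len(without.background_scores) + 2


def test_mannwhitney_power_strong_separation():
    assert mannwhitney_power(n_reps=100, seed=3) > 0.9


# ---------------------------------------------------------------------------
# hypothesis-pair derivation
# ---------------------------------------------------------------------------


def test_hypothesis_pairs_derive_from_planted_results(planted_graph):
    graph, plants = planted_graph
    results = [run_approaches(graph, p.rare_disease_id) for p in plants]
    ps_pairs = hypothesis_pairs_from_results(graph, results)
    gda_pairs = gda_pairs_from_results(graph, results)
    for p in plants:
        assert {(p.rare_disease_id, c) for c in p.confederate_disease_ids} <= ps_pairs
        assert (p.rare_disease_id, p.shared_gene) in gda_pairs
    # derived pairs satisfy the shared-target-gene precondition
    phenotypic_similarity_test(graph, ps_pairs)
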