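import dataclasses

import pytest

from raredr.kg_model import Disease, Drug, KnowledgeGraph
from raredr.repositioning import (
    APPROACHES,
    RepositioningParams,
    combine,
    direct_approach,
    paths_approach,
    run_all,
    run_approaches,
    triples_approach,
    triples_target_approach,
)
from raredr.evaluation import recovery_by_approach

from conftest import SIX_PATH_EXPECTED, make_random_small_graph, strong_signal_config
from oracles import brute_direct, brute_paths, brute_paths_combined, brute_triples


def test_six_path_fixture_matches_hand_enumeration(six_path_graph):
    per_path, combined = paths_approach(six_path_graph, "R")
    assert {k: set(v) for k, v in per_path.items()} == SIX_PATH_EXPECTED
    # the six non-empty sets are disjoint, so their intersection is empty
    assert combined == frozenset()


def test_direct_toy_chain():
    graph = KnowledgeGraph(
        diseases={"R": Disease(id="R", is_rare=True), "N": Disease(id="N")},
        drugs={"D1": Drug(id="D1")},
        node_roles={"G1": "gene", "P1": "protein"},
        disease_gene=frozenset({("R", "G1")}),
        gene_protein=frozenset({("G1", "P1")}),
        drug_target=frozenset({("D1", "P1")}),
    )
    assert direct_approach(graph, "R") == {"D1"}
    per_path, _ = paths_approach(graph, "R")
    assert per_path["P5"] == {"D1"}
    # a rare disease with no genes yields nothing
    graph2 = KnowledgeGraph(
        diseases={"R": Disease(id="R", is_rare=True)},
        drugs={"D1": Drug(id="D1")},
        node_roles={"P1": "protein"},
        drug_target=frozenset({("D1", "P1")}),
    )
    assert direct_approach(graph2, "R") == frozenset()


def test_no_drug_layer_yields_empty_results(six_path_graph):
    graph = dataclasses.replace(
        six_path_graph,
        drugs={},
        drug_indication=frozenset(),
        drug_target=frozenset(),
    )
    result = run_approaches(graph, "R")
    assert all(not s for s in result.per_approach.values())
    assert result.all_combined == frozenset()


def test_empty_gene_protein_map_empties_target_approaches(six_path_graph):
    graph = dataclasses.replace(six_path_graph, gene_protein=frozenset())
    assert triples_target_approach(graph, "R") == frozenset()
    assert direct_approach(graph, "R") == frozenset()


@pytest.mark.parametrize(
    "per_approach, expected_all, expected_ttddrp",
    [
        # a single non-empty set passes through both combiners untouched
        (
            {"triples": set(), "triples_target": set(), "direct": set(),
             "paths": {f"d{i}" for i in range(965)}},
            {f"d{i}" for i in range(965)},
            {f"d{i}" for i in range(965)},
        ),
        (
            {"triples": {"a", "b"}, "triples_target": set(),
             "direct": {"b", "c"}, "paths": {"b"}},
            {"b"},
            {"b"},
        ),
        # disjoint non-empty sets kill ALL but not the triples-free combiner
        (
            {"triples": {"a"}, "triples_target": {"b"}, "direct": set(),
             "paths": set()},
            set(),
            {"b"},
        ),
        (
            {"triples": set(), "triples_target": set(), "direct": set(),
             "paths": set()},
            set(),
            set(),
        ),
    ],
)
def test_combiner_semantics(per_approach, expected_all, expected_ttddrp):
    per_approach = {k: frozenset(v) for k, v in per_approach.items()}
    all_combined, ttddrp = combine(per_approach)
    assert all_combined == expected_all
    assert ttddrp == expected_ttddrp


@pytest.mark.parametrize("seed", range(15))
def test_approaches_match_brute_force_enumeration(seed):
    graph = make_random_small_graph(seed)
    params = RepositioningParams()
    for rare in (d for d, v in graph.diseases.items() if v.is_rare):
        result = run_approaches(graph, rare, params)
        assert result.per_approach["direct"] == brute_direct(graph, rare)
        assert result.per_approach["triples"] == brute_triples(graph, rare)
        assert result.per_approach["triples_target"] == brute_triples(
            graph, rare, with_target=True
        )
        assert {k: set(v) for k, v in result.per_path.items()} == brute_paths(
            graph, rare
        )
        assert result.per_approach["paths"] == brute_paths_combined(graph, rare)


@pytest.mark.parametrize("seed", range(10))
def test_p5_equals_direct_approach(seed):
    """P5 traverses the identical rare->gene->protein->target chain."""
    graph = make_random_small_graph(seed + 100)
    for rare in (d for d, v in graph.diseases.items() if v.is_rare):
        per_path, _ = paths_approach(graph, rare)
        assert per_path["P5"] == direct_approach(graph, rare)


@pytest.mark.parametrize("seed", range(10))
def test_combined_sets_are_subsets_of_nonempty_members(seed):
    graph = make_random_small_graph(seed + 200)
    for rare in (d for d, v in graph.diseases.items() if v.is_rare):
        r = run_approaches(graph, rare)
        for a in APPROACHES:
            if r.per_approach[a]:
                assert r.all_combined <= r.per_approach[a]
        for a in ("triples_target", "direct", "paths"):
            if r.per_approach[a]:
                assert r.ttddrp_combined <= r.per_approach[a]
        nonempty = [r.per_approach[a] for a in APPROACHES if r.per_approach[a]]
        if len(nonempty) == 1:
            assert r.all_combined == nonempty[0]


def test_planted_drugs_recovered_by_every_approach(planted_graph):
    graph, plants = planted_graph
    rates = recovery_by_approach(graph, plants)
    assert rates == {slot: 1.0 for slot in rates}


def test_removing_shared_gene_defeats_target_constraint(planted_graph):
    graph, plants = planted_graph
    plant = plants[0]
    assert plant.drug_id in triples_target_approach(graph, plant.rare_disease_id)
    stripped = dataclasses.replace(
        graph,
        disease_gene=frozenset(
            e for e in graph.disease_gene
            if e != (plant.rare_disease_id, plant.shared_gene)
        ),
        gda=frozenset(
            r for r in graph.gda
            if (r.gene, r.disease_id) != (plant.shared_gene, plant.rare_disease_id)
        ),
    )
    assert plant.drug_id not in triples_target_approach(stripped, plant.rare_disease_id)


def test_known_treatments_excluded_from_candidates(planted_graph):
    graph, plants = planted_graph
    plant = plants[0]
    # wire the planted drug as an existing treatment of the rare disease
    treated = dataclasses.replace(
        graph,
        drug_indication=graph.drug_indication
        | {(plant.drug_id, plant.rare_disease_id)},
    )
    result = run_approaches(treated, plant.rare_disease_id)
    assert plant.drug_id in result.known_treatments
    assert plant.drug_id not in result.candidate_drugs
    # with exclusion disabled the drug reappears
    keep = run_approaches(
        treated, plant.rare_disease_id, RepositioningParams(exclude_known=False)
    )
    assert plant.drug_id in keep.per_approach["direct"]


def test_run_all_summary_counts_are_consistent(planted_graph):
    graph, plants = planted_graph
    rare_ids = sorted({p.rare_disease_id for p in plants})
    results, summary = run_all(graph, rare_ids)
    assert list(summary["disease_id"]) == rare_ids
    for r, row in zip(results, summary.itertuples(index=False)):
        assert row.triples == len(r.per_approach["triples"])
        assert row.triples_target == len(r.per_approach["triples_target"])
        assert row.direct == len(r.per_approach["direct"])
        assert row.paths == len(r.per_approach["paths"])
        assert row.all == len(r.all_combined)
        assert row.ttddrp == len(r.ttddrp_combined)


def test_recovery_does_not_improve_as_overlap_weakens():
    seeds = range(4)
    rates = []
    for overlap in (1.0, 0.6):
        from raredr.evaluation import recovery_over_seeds

        rates.append(
            recovery_over_seeds(
                strong_signal_config(0, planted_overlap=overlap), seeds
            )["all_combined"]
        )
    assert rates[0] >= rates[1]
    assert rates[0] == 1.0
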