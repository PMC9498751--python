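from __future__ import annotations

import numpy as np
import pytest

from raredr.kg_model import Disease, Drug, GDARecord, KnowledgeGraph
from raredr.synthetic_data import GeneratorConfig, generate


def make_six_path_graph() -> KnowledgeGraph:
    """Hand-built small graph exercising all six drug-discovery paths.

    Expected per-path sets (manual traversal, frozen):
      P1={DD}, P2={DA}, P3={DB}, P4={DB}, P5={DA}, P6={DC};
    their non-empty intersection is empty, and Direct == P5 == {DA}.
    """
    return KnowledgeGraph(
        diseases={
            "R": Disease(id="R", is_rare=True),
            "N1": Disease(id="N1"),
            "N2": Disease(id="N2"),
        },
        drugs={d: Drug(id=d) for d in ("DA", "DB", "DC", "DD")},
        node_roles={
            "S1": "symptom",
            "S2": "symptom",
            "G1": "gene",
            "G2": "gene",
            "P1": "protein",
            "P2": "protein",
            "P3": "protein",
        },
        disease_symptom=frozenset({("R", "S1"), ("N1", "S1"), ("N2", "S2")}),
        disease_gene=frozenset({("R", "G1"), ("N1", "G2"), ("N2", "G1")}),
        gene_protein=frozenset({("G1", "P1"), ("G2", "P2")}),
        ppi=frozenset({("P1", "P3")}),
        drug_target=frozenset({("DA", "P1"), ("DB", "P2"), ("DC", "P3")}),
        drug_indication=frozenset({("DD", "S1"), ("DA", "N1"), ("DB", "N2")}),
    )


SIX_PATH_EXPECTED = {
    "P1": {"DD"},
    "P2": {"DA"},
    "P3": {"DB"},
    "P4": {"DB"},
    "P5": {"DA"},
    "P6": {"DC"},
}


def make_random_small_graph(seed: int) -> KnowledgeGraph:
    """A random valid graph with <= 30 nodes for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    n_rare, n_nonrare = 2, int(rng.integers(3, 6))
    diseases = {f"R{i}": Disease(id=f"R{i}", is_rare=True) for i in range(n_rare)}
    diseases.update({f"N{i}": Disease(id=f"N{i}") for i in range(n_nonrare)})
    genes = [f"g{i}" for i in range(4)]
    symptoms = [f"s{i}" for i in range(4)]
    proteins = [f"p{i}" for i in range(4)]
    pathways = [f"w{i}" for i in range(2)]
    variants = [f"v{i}" for i in range(2)]
    node_roles = {}
    for pool, role in (
        (genes, "gene"),
        (symptoms, "symptom"),
        (proteins, "protein"),
        (pathways, "pathway"),
        (variants, "variant"),
    ):
        node_roles.update({x: role for x in pool})
    drugs = {f"d{i}": Drug(id=f"d{i}") for i in range(int(rng.integers(2, 5)))}

    def random_edges(lefts, rights, p):
        return frozenset(
            (a, b) for a in lefts for b in rights if rng.random() < p
        )

    dids = list(diseases)
    gda = frozenset(
        GDARecord(gene=g, disease_id=d, gda_score=float(rng.uniform()),
                  dsi=float(rng.uniform()), dpi=float(rng.uniform()))
        for d, g in random_edges(dids, genes, 0.3)
    )
    ppi = frozenset(
        tuple(sorted((a, b)))
        for a in proteins
        for b in proteins
        if a < b and rng.random() < 0.3
    )
    indication_targets = dids + symptoms
    return KnowledgeGraph(
        diseases=diseases,
        drugs=drugs,
        node_roles=node_roles,
        disease_gene=random_edges(dids, genes, 0.4),
        disease_symptom=random_edges(dids, symptoms, 0.4),
        disease_protein=random_edges(dids, proteins, 0.3),
        disease_pathway=random_edges(dids, pathways, 0.3),
        disease_variant=random_edges(dids, variants, 0.3),
        drug_indication=random_edges(list(drugs), indication_targets, 0.25),
        drug_target=random_edges(list(drugs), proteins, 0.3),
        gene_protein=random_edges(genes, proteins, 0.4),
        ppi=ppi,
        gda=gda,
    )


SMALL_GENERATOR_KWARGS = dict(
    n_rare=6,
    n_nonrare=60,
    n_drugs=60,
    vocab_sizes={
        "gene": 200,
        "symptom": 300,
        "protein": 250,
        "pathway": 80,
        "variant": 150,
    },
    profile_size_ranges={
        "gene": (1, 20),
        "symptom": (2, 40),
        "protein": (1, 15),
        "pathway": (1, 8),
        "variant": (1, 10),
    },
)


def strong_signal_config(seed: int, planted_overlap: float = 1.0) -> GeneratorConfig:
    return GeneratorConfig(
        planted_overlap=planted_overlap,
        background_overlap=0.0,
        confederates_per_plant=5,
        n_planted=3,
        seed=seed,
        **SMALL_GENERATOR_KWARGS,
    )


@pytest.fixture(scope="session")
def six_path_graph():
    return make_six_path_graph()


@pytest.fixture(scope="session")
def planted_graph():
    """Strong-signal planted graph plus its ground truth."""
    return generate(strong_signal_config(seed=11))


@pytest.fixture(scope="session")
def default_graph():
    """A graph generated under the default study conditions."""
    return generate(GeneratorConfig(seed=5))
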