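"""Synthetic disease-centric knowledge graphs with planted repositioning signal.

The generator emulates the statistical shape of a DISNET-style snapshot:
rare and non-rare diseases carrying per-feature association sets (genes,
symptoms, proteins, pathways, variants), a drugs layer with indication and
target edges, gene->protein encoding, a protein-protein interaction layer,
and per-(gene, disease) association scores.

A configurable number of repositioning hypotheses are *planted*: for each
one, a rare disease, a drug, and a set of "confederate" non-rare diseases
are wired so the drug is recoverable by every candidate-generation
approach — the confederates copy a fraction ``planted_overlap`` of the rare
disease's features (so they dominate feature-wise similarity rankings), all
share a gene whose encoded protein the drug targets, and the drug is
indicated for every confederate.  Background diseases share features only
through a small hub sub-vocabulary hit with probability
``background_overlap``, so background similarity is nonzero but small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kg_model import (
    Disease,
    Drug,
    GDARecord,
    KnowledgeGraph,
    PREVALENCE_CLASSES,
)

__all__ = ["GeneratorConfig", "PlantedTruth", "generate", "table1_fixture"]

_FEATURE_PREFIX = {
    "gene": "G",
    "symptom": "S",
    "protein": "P",
    "pathway": "W",
    "variant": "V",
}

_ATC_LETTERS = "ABCDGHJLMNPRSV"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic graph generator.

    Defaults mirror the study conditions this pipeline is meant for:
    13 rare diseases against a non-rare background, per-disease gene counts
    in 1-44 and symptom counts in 1-237 (the observed spread of the 13-case
    study set), and a weak background overlap against which a planted
    overlap of 0.8 is clearly detectable.
    """

    n_rare: int = 13
    n_nonrare: int = 150
    vocab_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "gene": 500,
            "symptom": 1000,
            "protein": 600,
            "pathway": 150,
            "variant": 400,
        }
    )
    n_drugs: int = 120
    profile_size_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "gene": (1, 44),
            "symptom": (1, 237),
            "protein": (1, 40),
            "pathway": (1, 15),
            "variant": (1, 30),
        }
    )
    background_overlap: float = 0.1
    n_planted: int = 3
    planted_overlap: float = 0.8
    confederates_per_plant: int = 5
    gda_planted_beta: tuple[float, float] = (8.0, 2.0)
    gda_background_beta: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.planted_overlap > self.background_overlap:
            raise ValueError(
                "planted_overlap must exceed background_overlap "
                f"({self.planted_overlap} <= {self.background_overlap}); "
                "otherwise the planted signal is undetectable"
            )
        if not 0.0 < self.planted_overlap <= 1.0:
            raise ValueError("planted_overlap must lie in (0, 1]")
        if not 0.0 <= self.background_overlap <= 1.0:
            raise ValueError("background_overlap must lie in [0, 1]")
        for name in ("n_rare", "n_nonrare", "n_drugs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted < 0 or self.confederates_per_plant <= 0:
            raise ValueError("plant counts must be non-negative / positive")
        if self.n_planted > self.n_rare:
            raise ValueError("n_planted cannot exceed n_rare")
        if self.n_planted * self.confederates_per_plant > self.n_nonrare:
            raise ValueError("not enough non-rare diseases for the requested plants")
        for feature, (lo, hi) in self.profile_size_ranges.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"degenerate profile size range for {feature}")
            if hi > self.vocab_sizes[feature]:
                raise ValueError(f"profile size range for {feature} exceeds vocabulary")


@dataclass(frozen=True)
class PlantedTruth:
    """One planted repositioning hypothesis the pipeline should recover."""

    rare_disease_id: str
    drug_id: str
    confederate_disease_ids: frozenset[str]
    shared_gene: str


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Independent named substreams off one global seed.

    Components are spawned in a fixed order, so adding a new stream at the
    end never perturbs existing ones.
    """
    names = ("diseases", "profiles", "drugs", "plants", "gda")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _sample_profile(
    rng: np.random.Generator,
    size_range: tuple[int, int],
    vocab: list[str],
    hub: list[str],
    background_overlap: float,
) -> set[str]:
    lo, hi = size_range
    size = int(rng.integers(lo, hi + 1))
    out: set[str] = set()
    for _ in range(size):
        pool = hub if (hub and rng.random() < background_overlap) else vocab
        out.add(pool[int(rng.integers(len(pool)))])
    return out


def _random_atc_code(rng: np.random.Generator) -> str:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    return (
        _ATC_LETTERS[int(rng.integers(len(_ATC_LETTERS)))]
        + f"{int(rng.integers(1, 17)):02d}"
        + letters[int(rng.integers(26))]
        + letters[int(rng.integers(26))]
        + f"{int(rng.integers(1, 100)):02d}"
    )


_RARE_PREVALENCE = ("<1/1000000", "1-9/1000000", "1-9/100000", "unknown")
_RARE_PREVALENCE_W = (0.55, 0.2, 0.15, 0.1)
_GEOGRAPHIES = ("Worldwide", "Europe", "United States")
_GEOGRAPHY_W = (0.7, 0.2, 0.1)


def generate(config: GeneratorConfig) -> tuple[KnowledgeGraph, list[PlantedTruth]]:
    """Generate a validated knowledge graph plus its planted ground truth.

    Deterministic given ``config`` (including ``config.seed``).
    """
    rngs = _streams(config.seed)

    vocab = {
        feat: [f"{_FEATURE_PREFIX[feat]}{i:05d}" for i in range(n)]
        for feat, n in config.vocab_sizes.items()
    }
    hub = {
        feat: words[: max(3, len(words) // 20)] for feat, words in vocab.items()
    }
    node_roles = {w: feat for feat, words in vocab.items() for w in words}

    # -- disease nodes -------------------------------------------------
    rng = rngs["diseases"]
    diseases: dict[str, Disease] = {}
    rare_ids = [f"RD{i:04d}" for i in range(config.n_rare)]
    nonrare_ids = [f"ND{i:04d}" for i in range(config.n_nonrare)]
    for did in rare_ids:
        diseases[did] = Disease(
            id=did,
            name=f"rare disease {did}",
            is_rare=True,
            prevalence_class=str(
                rng.choice(_RARE_PREVALENCE, p=_RARE_PREVALENCE_W)
            ),
            prevalence_geography=str(rng.choice(_GEOGRAPHIES, p=_GEOGRAPHY_W)),
        )
    for did in nonrare_ids:
        diseases[did] = Disease(
            id=did,
            name=f"common disease {did}",
            is_rare=False,
            prevalence_class=str(rng.choice(PREVALENCE_CLASSES[:3])),
            prevalence_geography="Worldwide",
        )

    # -- background feature profiles ------------------------------------
    rng = rngs["profiles"]
    profiles: dict[str, dict[str, set[str]]] = {
        did: {
            feat: _sample_profile(
                rng,
                config.profile_size_ranges[feat],
                vocab[feat],
                hub[feat],
                config.background_overlap,
            )
            for feat in vocab
        }
        for did in rare_ids + nonrare_ids
    }

    # one encoded protein per gene (uniformly random, fixed for the graph)
    gene_protein = {
        g: vocab["protein"][int(rng.integers(len(vocab["protein"])))]
        for g in vocab["gene"]
    }

    # -- drugs layer ----------------------------------------------------
    rng = rngs["drugs"]
    drugs: dict[str, Drug] = {}
    drug_indication: set[tuple[str, str]] = set()
    drug_target: set[tuple[str, str]] = set()
    for i in range(config.n_drugs):
        drug_id = f"D{i:04d}"
        n_codes = int(rng.integers(1, 3))
        drugs[drug_id] = Drug(
            id=drug_id,
            name=f"drug {drug_id}",
            atc_codes=frozenset(_random_atc_code(rng) for _ in range(n_codes)),
        )
        for _ in range(int(rng.integers(1, 4))):
            protein = vocab["protein"][int(rng.integers(len(vocab["protein"])))]
            drug_target.add((drug_id, protein))
        # indications: a few non-rare diseases plus, sometimes, symptoms
        for _ in range(int(rng.integers(1, 5))):
            target = nonrare_ids[int(rng.integers(len(nonrare_ids)))]
            drug_indication.add((drug_id, target))
        for _ in range(int(rng.integers(0, 3))):
            symptom = vocab["symptom"][int(rng.integers(len(vocab["symptom"])))]
            drug_indication.add((drug_id, symptom))

    # -- plants ----------------------------------------------------------
    rng = rngs["plants"]
    plants: list[PlantedTruth] = []
    planted_rare = [
        str(x) for x in rng.choice(rare_ids, size=config.n_planted, replace=False)
    ]
    free_confederates = list(nonrare_ids)
    planted_drug_ids = [f"D{i:04d}" for i in range(config.n_planted)]
    planted_pairs: set[tuple[str, str]] = set()

    for rare_id, drug_id in zip(planted_rare, planted_drug_ids):
        rare_profile = profiles[rare_id]
        if len(rare_profile["gene"]) < 2:
            extra = vocab["gene"][int(rng.integers(len(vocab["gene"])))]
            rare_profile["gene"].add(extra)
        genes_sorted = sorted(rare_profile["gene"])
        shared_gene = genes_sorted[int(rng.integers(len(genes_sorted)))]
        target_protein = gene_protein[shared_gene]

        # re-wire the reserved drug: it targets the shared gene's protein
        drug_target.add((drug_id, target_protein))
        # the drug must not already treat the rare disease (repositioning
        # means a new indication)
        drug_indication.discard((drug_id, rare_id))

        idx = rng.choice(len(free_confederates), size=config.confederates_per_plant,
                         replace=False)
        confederates = [free_confederates[int(i)] for i in sorted(idx, reverse=True)]
        for i in sorted(idx, reverse=True):
            del free_confederates[int(i)]

        for conf_id in confederates:
            conf_profile = profiles[conf_id]
            for feat, rare_set in rare_profile.items():
                pool = sorted(rare_set)
                n_copy = math.ceil(config.planted_overlap * len(pool))
                if n_copy:
                    take = rng.choice(len(pool), size=n_copy, replace=False)
                    copied = {pool[int(i)] for i in take}
                else:
                    copied = set()
                # confederate keeps a thinned-down background of its own
                keep = {
                    f for f in conf_profile[feat]
                    if rng.random() < (1.0 - config.planted_overlap)
                }
                conf_profile[feat] = copied | keep
            conf_profile["gene"].add(shared_gene)
            drug_indication.add((drug_id, conf_id))

        # P1 route: the planted drug is also indicated for one of the rare
        # disease's symptoms
        symptoms_sorted = sorted(rare_profile["symptom"])
        if not symptoms_sorted:
            rare_profile["symptom"].add(vocab["symptom"][0])
            symptoms_sorted = sorted(rare_profile["symptom"])
        drug_indication.add(
            (drug_id, symptoms_sorted[int(rng.integers(len(symptoms_sorted)))])
        )

        plants.append(
            PlantedTruth(
                rare_disease_id=rare_id,
                drug_id=drug_id,
                confederate_disease_ids=frozenset(confederates),
                shared_gene=shared_gene,
            )
        )
        planted_pairs.add((shared_gene, rare_id))

    # PPI layer: random background pairs, plus — for each plant — an edge
    # between the target protein and a protein encoded by another of the
    # rare disease's genes, so the drug is reachable through the PPI route
    ppi: set[tuple[str, str]] = set()
    n_ppi = 2 * len(vocab["protein"])
    for _ in range(n_ppi):
        p = vocab["protein"][int(rng.integers(len(vocab["protein"])))]
        q = vocab["protein"][int(rng.integers(len(vocab["protein"])))]
        if p != q:
            ppi.add(tuple(sorted((p, q))))
    for plant in plants:
        target_protein = gene_protein[plant.shared_gene]
        other_genes = sorted(profiles[plant.rare_disease_id]["gene"] - {plant.shared_gene})
        partner = gene_protein[other_genes[0]]
        if partner != target_protein:
            ppi.add(tuple(sorted((partner, target_protein))))
        else:
            alt = vocab["protein"][0] if vocab["protein"][0] != target_protein \
                else vocab["protein"][1]
            ppi.add(tuple(sorted((alt, target_protein))))

    # -- GDA scores ------------------------------------------------------
    rng = rngs["gda"]
    gene_dsi = {g: float(rng.uniform(0.2, 0.9)) for g in vocab["gene"]}
    gene_dpi = {g: float(rng.uniform(0.2, 0.9)) for g in vocab["gene"]}
    gda = set()
    for did, prof in sorted(profiles.items()):
        for gene in sorted(prof["gene"]):
            if (gene, did) in planted_pairs:
                score = float(rng.beta(*config.gda_planted_beta))
            else:
                score = float(rng.beta(*config.gda_background_beta))
            gda.add(
                GDARecord(
                    gene=gene,
                    disease_id=did,
                    gda_score=score,
                    dsi=gene_dsi[gene],
                    dpi=gene_dpi[gene],
                )
            )

    edges = {
        feat: frozenset(
            (did, f) for did, prof in profiles.items() for f in prof[feat]
        )
        for feat in vocab
    }
    graph = KnowledgeGraph(
        diseases=diseases,
        drugs=drugs,
        node_roles=node_roles,
        disease_gene=edges["gene"],
        disease_symptom=edges["symptom"],
        disease_protein=edges["protein"],
        disease_pathway=edges["pathway"],
        disease_variant=edges["variant"],
        drug_indication=frozenset(drug_indication),
        drug_target=frozenset(drug_target),
        gene_protein=frozenset(gene_protein.items()),
        ppi=frozenset(ppi),
        gda=frozenset(gda),
    )
    return graph, plants


# ---------------------------------------------------------------------------
# The 13-disease case-study fixture
# ---------------------------------------------------------------------------

#: (CUI, name, n_genes, n_symptoms) for the 13 rare diseases of the
#: case-study set this pipeline was designed around.
CASE_STUDY_DISEASES: tuple[tuple[str, str, int, int], ...] = (
    ("C0011195", "Dejerine-Sottas syndrome", 31, 10),
    ("C0023944", "Locked-In Syndrome", 1, 17),
    ("C0024054", "Lown-Ganong-Levine syndrome", 1, 6),
    ("C0024901", "Diffuse cutaneous mastocytosis", 1, 237),
    ("C0027877", "Congenital neuronal ceroid lipofuscinosis", 38, 52),
    ("C0036391", "Schwartz-Jampel syndrome", 23, 5),
    ("C0265202", "Seckel syndrome", 15, 4),
    ("C0268059", "Neonatal hemochromatosis", 1, 43),
    ("C0549463", "X-Linked Lymphoproliferative Disorder", 11, 1),
    ("C0751337", "X-Linked Emery-Dreifuss Muscular Dystrophy", 44, 32),
    ("C0869083", "Dahlberg-Borer-Newcomer syndrome", 12, 2),
    ("C1852146", "Vibratory urticaria", 1, 11),
    ("C0796280", "Acromegaloid facial appearance syndrome", 1, 90),
)


def table1_fixture(n_nonrare: int = 50, seed: int = 0) -> KnowledgeGraph:
    """The 13 case-study rare diseases with their exact gene/symptom counts.

    Feature identifiers are synthetic; only the set sizes are faithful.
    A configurable non-rare background is generated around them so
    selection and similarity stages have something to rank against.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    max_genes = max(n for _, _, n, _ in CASE_STUDY_DISEASES)
    max_symptoms = max(n for _, _, _, n in CASE_STUDY_DISEASES)
    genes = [f"G{i:05d}" for i in range(max(2 * max_genes, 120))]
    symptoms = [f"S{i:05d}" for i in range(max(2 * max_symptoms, 600))]
    node_roles = {g: "gene" for g in genes}
    node_roles.update({s: "symptom" for s in symptoms})

    diseases: dict[str, Disease] = {}
    disease_gene: set[tuple[str, str]] = set()
    disease_symptom: set[tuple[str, str]] = set()
    for cui, name, n_genes, n_symptoms in CASE_STUDY_DISEASES:
        diseases[cui] = Disease(
            id=cui,
            name=name,
            is_rare=True,
            prevalence_class="<1/1000000",
            prevalence_geography="Worldwide",
        )
        for g in rng.choice(genes, size=n_genes, replace=False):
            disease_gene.add((cui, str(g)))
        for s in rng.choice(symptoms, size=n_symptoms, replace=False):
            disease_symptom.add((cui, str(s)))

    for i in range(n_nonrare):
        did = f"ND{i:04d}"
        diseases[did] = Disease(
            id=did,
            name=f"common disease {did}",
            is_rare=False,
            prevalence_class=">1/1000",
            prevalence_geography="Worldwide",
        )
        for g in rng.choice(genes, size=int(rng.integers(1, 20)), replace=False):
            disease_gene.add((did, str(g)))
        for s in rng.choice(symptoms, size=int(rng.integers(1, 40)), replace=False):
            disease_symptom.add((did, str(s)))

    return KnowledgeGraph(
        diseases=diseases,
        node_roles=node_roles,
        disease_gene=frozenset(disease_gene),
        disease_symptom=frozenset(disease_symptom),
    )
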