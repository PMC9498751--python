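"""Independent brute-force oracles for the candidate-generation approaches.

These deliberately avoid the package's graph indexes and set algebra:
everything is enumerated with explicit loops over raw edge tuples, so a
bug in the implementation's adjacency caching or intersection logic
cannot hide in the oracle.
"""

from __future__ import annotations

from raredr.kg_model import FEATURES, KnowledgeGraph

EDGE_OF_FEATURE = {
    "gene": "disease_gene",
    "symptom": "disease_symptom",
    "protein": "disease_protein",
    "pathway": "disease_pathway",
    "variant": "disease_variant",
}


def brute_feature_set(graph: KnowledgeGraph, disease: str, feature: str) -> set[str]:
    edges = getattr(graph, EDGE_OF_FEATURE[feature])
    return {f for d, f in edges if d == disease}


def brute_jaccard(a: set, b: set) -> float:
    inter = sum(1 for x in a if x in b)
    union = len(a) + len(b) - inter
    return inter / union if union else 0.0


def brute_known_treatments(graph: KnowledgeGraph, rare: str) -> set[str]:
    return {d for d, c in graph.drug_indication if c == rare}


def brute_top_k(graph: KnowledgeGraph, rare: str, feature: str, k: int) -> list[str]:
    a = brute_feature_set(graph, rare, feature)
    nonrare = [d for d, v in graph.diseases.items() if not v.is_rare]
    scored = []
    for n in nonrare:
        s = brute_jaccard(a, brute_feature_set(graph, n, feature))
        if s > 0:
            scored.append((n, s))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return [n for n, _ in scored[:k]]


def brute_indicated(graph: KnowledgeGraph, concept: str) -> set[str]:
    return {d for d, c in graph.drug_indication if c == concept}


def brute_drug_targets(graph: KnowledgeGraph, drug: str) -> set[str]:
    return {p for d, p in graph.drug_target if d == drug}


def brute_encoded(graph: KnowledgeGraph, gene: str) -> set[str]:
    return {p for g, p in graph.gene_protein if g == gene}


def _strip(drugs: set[str], graph: KnowledgeGraph, rare: str) -> set[str]:
    return drugs - brute_known_treatments(graph, rare)


def brute_triples(
    graph: KnowledgeGraph,
    rare: str,
    k: int = 5,
    share_min: int = 2,
    with_target: bool = False,
) -> set[str]:
    groups = []
    rare_genes = brute_feature_set(graph, rare, "gene")
    for feature in FEATURES:
        top = brute_top_k(graph, rare, feature, k)
        counts: dict[str, int] = {}
        for n in top:
            n_genes = brute_feature_set(graph, n, "gene")
            for drug in brute_indicated(graph, n):
                if with_target:
                    ok = False
                    for g in rare_genes & n_genes:
                        for p in brute_encoded(graph, g):
                            if p in brute_drug_targets(graph, drug):
                                ok = True
                    if not ok:
                        continue
                counts[drug] = counts.get(drug, 0) + 1
        groups.append(
            _strip({d for d, c in counts.items() if c >= share_min}, graph, rare)
        )
    nonempty = [g for g in groups if g]
    if not nonempty:
        return set()
    out = set(nonempty[0])
    for g in nonempty[1:]:
        out &= g
    return out


def brute_direct(graph: KnowledgeGraph, rare: str) -> set[str]:
    out = set()
    for g, d in graph.disease_gene:
        if g != rare:
            continue
        for gene, protein in graph.gene_protein:
            if gene != d:
                continue
            for drug, target in graph.drug_target:
                if target == protein:
                    out.add(drug)
    return _strip(out, graph, rare)


def brute_paths(graph: KnowledgeGraph, rare: str) -> dict[str, set[str]]:
    symptoms = brute_feature_set(graph, rare, "symptom")
    genes = brute_feature_set(graph, rare, "gene")
    nonrare = {d for d, v in graph.diseases.items() if not v.is_rare}

    p1 = set()
    for s in symptoms:
        p1 |= brute_indicated(graph, s)

    symptom_sharers = set()
    for d, s in graph.disease_symptom:
        if s in symptoms and d != rare and d in nonrare:
            symptom_sharers.add(d)
    p2 = set()
    for d in symptom_sharers:
        p2 |= brute_indicated(graph, d)

    p3 = set()
    for d in symptom_sharers:
        for gene in brute_feature_set(graph, d, "gene"):
            for protein in brute_encoded(graph, gene):
                for drug, target in graph.drug_target:
                    if target == protein:
                        p3.add(drug)

    gene_sharers = set()
    for d, g in graph.disease_gene:
        if g in genes and d != rare and d in nonrare:
            gene_sharers.add(d)
    p4 = set()
    for d in gene_sharers:
        p4 |= brute_indicated(graph, d)

    p5 = set()
    own_proteins = set()
    for gene in genes:
        own_proteins |= brute_encoded(graph, gene)
    for protein in own_proteins:
        for drug, target in graph.drug_target:
            if target == protein:
                p5.add(drug)

    partners = set()
    for a, b in graph.ppi:
        if a in own_proteins:
            partners.add(b)
        if b in own_proteins:
            partners.add(a)
    p6 = set()
    for protein in partners:
        for drug, target in graph.drug_target:
            if target == protein:
                p6.add(drug)

    return {
        label: _strip(s, graph, rare)
        for label, s in zip(
            ("P1", "P2", "P3", "P4", "P5", "P6"), (p1, p2, p3, p4, p5, p6)
        )
    }


def brute_paths_combined(graph: KnowledgeGraph, rare: str) -> set[str]:
    per_path = brute_paths(graph, rare)
    nonempty = [s for s in per_path.values() if s]
    if not nonempty:
        return set()
    out = set(nonempty[0])
    for s in nonempty[1:]:
        out &= s
    return out
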