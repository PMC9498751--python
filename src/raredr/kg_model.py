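"""Disease-centric knowledge-graph data model and edge-list TSV readers/writers.

The graph has three layers: a biological layer (disease-gene, disease-protein,
disease-pathway, disease-variant associations, gene->protein encoding, and
protein-protein interactions), a phenotypical layer (disease-symptom
associations), and a drugs layer (drug->indication and drug->target edges,
plus per-(gene, disease) association scores).

Everything is stored as plain sets of identifier tuples inside an immutable
:class:`KnowledgeGraph`; per-disease feature sets (:class:`FeatureProfile`)
are derived views, never free-standing state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of prevalence classes, ordered from highest to lowest
#: prevalence.  The three "unknown" source variants (Null / Unknown /
#: Not yet documented) collapse into a single ``"unknown"`` class.
PREVALENCE_CLASSES = (
    ">1/1000",
    "6-9/10000",
    "1-5/10000",
    "1-9/100000",
    "1-9/1000000",
    "<1/1000000",
    "unknown",
)

_UNKNOWN_PREVALENCE_ALIASES = {"null", "unknown", "not yet documented", ""}

#: The 14 anatomical/pharmacological groups of the ATC 1st level.
ATC_LEVEL1 = frozenset("ABCDGHJLMNPRSV")

#: Biological feature kinds over which disease similarity is computed.
FEATURES = ("gene", "symptom", "protein", "pathway", "variant")

#: Node roles allowed in the feature vocabulary table.
NODE_ROLES = ("gene", "symptom", "protein", "pathway", "variant")


class GraphValidationError(ValueError):
    """Referential-integrity or vocabulary violation in a graph."""


class GraphConfigurationError(ValueError):
    """Missing or unreadable input file set."""


def normalize_prevalence_class(value: str) -> str:
    """Map a raw prevalence label onto the closed vocabulary.

    Unknown variants collapse to ``"unknown"``; anything else must already
    be one of :data:`PREVALENCE_CLASSES`.
    """
    value = str(value).strip()
    if value.lower() in _UNKNOWN_PREVALENCE_ALIASES:
        return "unknown"
    # tolerate the unicode en-dash and thousands separators seen in the wild
    canon = value.replace("–", "-").replace(",", "").replace(" ", "")
    if canon in PREVALENCE_CLASSES:
        return canon
    raise GraphValidationError(f"malformed prevalence class: {value!r}")


@dataclass(frozen=True)
class Disease:
    id: str
    name: str = ""
    is_rare: bool = False
    prevalence_class: str = "unknown"
    prevalence_geography: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("disease id must be non-empty")
        object.__setattr__(
            self, "prevalence_class", normalize_prevalence_class(self.prevalence_class)
        )


@dataclass(frozen=True)
class Drug:
    id: str
    name: str = ""
    atc_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("drug id must be non-empty")
        codes = frozenset(self.atc_codes)
        for code in codes:
            if not code or code[0] not in ATC_LEVEL1:
                raise GraphValidationError(
                    f"drug {self.id}: ATC code {code!r} has no valid level-1 letter"
                )
        object.__setattr__(self, "atc_codes", codes)

    @property
    def atc_level1(self) -> frozenset[str]:
        """The distinct level-1 letters of this drug's ATC codes."""
        return frozenset(code[0] for code in self.atc_codes)


@dataclass(frozen=True)
class GDARecord:
    """A gene-disease association with its strength and gene-level indexes.

    ``gda_score`` measures how well established the association is;
    ``dsi`` (disease specificity index) is inversely related to how many
    diseases the gene touches; ``dpi`` (disease pleiotropy index) grows with
    the number of distinct disease classes the gene touches.  All three live
    in [0, 1].
    """

    gene: str
    disease_id: str
    gda_score: float
    dsi: float
    dpi: float

    def __post_init__(self) -> None:
        for label in ("gda_score", "dsi", "dpi"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise GraphValidationError(
                    f"GDA record ({self.gene}, {self.disease_id}): "
                    f"{label}={v} outside [0, 1]"
                )


@dataclass(frozen=True)
class FeatureProfile:
    """Per-disease feature sets: the A and B of the Jaccard comparison."""

    disease_id: str
    genes: frozenset[str] = frozenset()
    symptoms: frozenset[str] = frozenset()
    proteins: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    variants: frozenset[str] = frozenset()

    def feature_set(self, feature: str) -> frozenset[str]:
        if feature not in FEATURES:
            raise KeyError(f"unknown feature kind: {feature!r}")
        return getattr(self, feature + "s")


def _dedupe(name: str, rows: Iterable[tuple]) -> frozenset:
    rows = list(rows)
    out = frozenset(rows)
    if len(out) < len(rows):
        logger.warning("%s: %d duplicate edges dropped", name, len(rows) - len(out))
    return out


@dataclass(frozen=True)
class KnowledgeGraph:
    """Immutable container of typed node sets and association edge sets.

    Edge sets are sets of identifier tuples.  ``ppi`` pairs are stored
    order-independently (canonicalized at construction).  ``drug_indication``
    targets may be disease ids or symptom ids: symptoms are concepts in
    their own right and share the indication target space with diseases.
    """

    diseases: Mapping[str, Disease] = field(default_factory=dict)
    drugs: Mapping[str, Drug] = field(default_factory=dict)
    node_roles: Mapping[str, str] = field(default_factory=dict)
    disease_gene: frozenset[tuple[str, str]] = frozenset()
    disease_symptom: frozenset[tuple[str, str]] = frozenset()
    disease_protein: frozenset[tuple[str, str]] = frozenset()
    disease_pathway: frozenset[tuple[str, str]] = frozenset()
    disease_variant: frozenset[tuple[str, str]] = frozenset()
    drug_indication: frozenset[tuple[str, str]] = frozenset()
    drug_target: frozenset[tuple[str, str]] = frozenset()
    gene_protein: frozenset[tuple[str, str]] = frozenset()
    ppi: frozenset[tuple[str, str]] = frozenset()
    gda: frozenset[GDARecord] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "diseases", dict(self.diseases))
        object.__setattr__(self, "drugs", dict(self.drugs))
        object.__setattr__(self, "node_roles", dict(self.node_roles))
        for name in (
            "disease_gene",
            "disease_symptom",
            "disease_protein",
            "disease_pathway",
            "disease_variant",
            "drug_indication",
            "drug_target",
            "gene_protein",
        ):
            object.__setattr__(self, name, _dedupe(name, getattr(self, name)))
        # canonical order inside each PPI pair, so (p, q) == (q, p)
        object.__setattr__(
            self, "ppi", _dedupe("ppi", (tuple(sorted(p)) for p in self.ppi))
        )
        object.__setattr__(self, "gda", frozenset(self.gda))
        self._validate()

    # -- validation ----------------------------------------------------

    def _nodes_of_role(self, role: str) -> set[str]:
        return {n for n, r in self.node_roles.items() if r == role}

    def _validate(self) -> None:
        for node, role in self.node_roles.items():
            if role not in NODE_ROLES:
                raise GraphValidationError(f"node {node}: unknown role {role!r}")
        by_role = {role: self._nodes_of_role(role) for role in NODE_ROLES}
        disease_ids = set(self.diseases)

        def check(edge_name: str, pairs, left_ok, right_ok, right_label: str):
            for a, b in pairs:
                if a not in left_ok:
                    raise GraphValidationError(
                        f"{edge_name}: undeclared endpoint {a!r}"
                    )
                if b not in right_ok:
                    raise GraphValidationError(
                        f"{edge_name}: undeclared {right_label} {b!r}"
                    )

        check("disease_gene", self.disease_gene, disease_ids, by_role["gene"], "gene")
        check(
            "disease_symptom",
            self.disease_symptom,
            disease_ids,
            by_role["symptom"],
            "symptom",
        )
        check(
            "disease_protein",
            self.disease_protein,
            disease_ids,
            by_role["protein"],
            "protein",
        )
        check(
            "disease_pathway",
            self.disease_pathway,
            disease_ids,
            by_role["pathway"],
            "pathway",
        )
        check(
            "disease_variant",
            self.disease_variant,
            disease_ids,
            by_role["variant"],
            "variant",
        )
        concepts = disease_ids | by_role["symptom"]
        check(
            "drug_indication",
            self.drug_indication,
            set(self.drugs),
            concepts,
            "disease-or-symptom concept",
        )
        check(
            "drug_target", self.drug_target, set(self.drugs), by_role["protein"], "protein"
        )
        check(
            "gene_protein",
            self.gene_protein,
            by_role["gene"],
            by_role["protein"],
            "protein",
        )
        check("ppi", self.ppi, by_role["protein"], by_role["protein"], "protein")
        for rec in self.gda:
            if rec.disease_id not in disease_ids:
                raise GraphValidationError(f"gda: undeclared disease {rec.disease_id!r}")
            if rec.gene not in by_role["gene"]:
                raise GraphValidationError(f"gda: undeclared gene {rec.gene!r}")

    # -- derived indexes (built lazily, cached) ------------------------

    @cached_property
    def rare_disease_ids(self) -> tuple[str, ...]:
        return tuple(sorted(d for d, v in self.diseases.items() if v.is_rare))

    @cached_property
    def nonrare_disease_ids(self) -> tuple[str, ...]:
        return tuple(sorted(d for d, v in self.diseases.items() if not v.is_rare))

    @cached_property
    def _feature_adjacency(self) -> dict[str, dict[str, frozenset[str]]]:
        out: dict[str, dict[str, frozenset[str]]] = {}
        for feature, edges in (
            ("gene", self.disease_gene),
            ("symptom", self.disease_symptom),
            ("protein", self.disease_protein),
            ("pathway", self.disease_pathway),
            ("variant", self.disease_variant),
        ):
            adj: dict[str, set[str]] = {}
            for d, f in edges:
                adj.setdefault(d, set()).add(f)
            out[feature] = {d: frozenset(s) for d, s in adj.items()}
        return out

    @cached_property
    def _indications_by_concept(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for drug, concept in self.drug_indication:
            adj.setdefault(concept, set()).add(drug)
        return {c: frozenset(s) for c, s in adj.items()}

    @cached_property
    def _drugs_by_target(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for drug, protein in self.drug_target:
            adj.setdefault(protein, set()).add(drug)
        return {p: frozenset(s) for p, s in adj.items()}

    @cached_property
    def _proteins_by_gene(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for gene, protein in self.gene_protein:
            adj.setdefault(gene, set()).add(protein)
        return {g: frozenset(s) for g, s in adj.items()}

    @cached_property
    def _ppi_neighbors(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {}
        for p, q in self.ppi:
            adj.setdefault(p, set()).add(q)
            adj.setdefault(q, set()).add(p)
        return {p: frozenset(s) for p, s in adj.items()}

    @cached_property
    def _diseases_by_feature(self) -> dict[str, dict[str, frozenset[str]]]:
        out: dict[str, dict[str, frozenset[str]]] = {}
        for feature, adjacency in self._feature_adjacency.items():
            rev: dict[str, set[str]] = {}
            for d, feats in adjacency.items():
                for f in feats:
                    rev.setdefault(f, set()).add(d)
            out[feature] = {f: frozenset(s) for f, s in rev.items()}
        return out

    @cached_property
    def gda_scores(self) -> dict[tuple[str, str], GDARecord]:
        return {(r.gene, r.disease_id): r for r in self.gda}

    # -- query surface --------------------------------------------------

    def feature_set(self, disease_id: str, feature: str) -> frozenset[str]:
        """The ``feature``-neighbors of a disease (empty if none)."""
        if disease_id not in self.diseases:
            raise KeyError(f"unknown disease: {disease_id!r}")
        if feature not in FEATURES:
            raise KeyError(f"unknown feature kind: {feature!r}")
        return self._feature_adjacency[feature].get(disease_id, frozenset())

    def diseases_with_feature(self, feature: str, feature_id: str) -> frozenset[str]:
        return self._diseases_by_feature[feature].get(feature_id, frozenset())

    def indicated_drugs(self, concept_id: str) -> frozenset[str]:
        """Drugs with an indication edge to a disease or symptom concept."""
        return self._indications_by_concept.get(concept_id, frozenset())

    def drugs_targeting(self, protein_id: str) -> frozenset[str]:
        return self._drugs_by_target.get(protein_id, frozenset())

    def encoded_proteins(self, gene_id: str) -> frozenset[str]:
        return self._proteins_by_gene.get(gene_id, frozenset())

    def ppi_partners(self, protein_id: str) -> frozenset[str]:
        return self._ppi_neighbors.get(protein_id, frozenset())

    def target_proteins(self, drug_id: str) -> frozenset[str]:
        return frozenset(p for d, p in self.drug_target if d == drug_id)


def feature_profile(graph: KnowledgeGraph, disease_id: str) -> FeatureProfile:
    """Derive the five feature sets of one disease from the graph's edges."""
    return FeatureProfile(
        disease_id=disease_id,
        genes=graph.feature_set(disease_id, "gene"),
        symptoms=graph.feature_set(disease_id, "symptom"),
        proteins=graph.feature_set(disease_id, "protein"),
        pathways=graph.feature_set(disease_id, "pathway"),
        variants=graph.feature_set(disease_id, "variant"),
    )


# ---------------------------------------------------------------------------
# Edge-list file IO: ten UTF-8 tab-delimited files with headers.
# ---------------------------------------------------------------------------

FILE_SET = (
    "diseases.tsv",
    "drugs.tsv",
    "nodes.tsv",
    "disease_gene.tsv",
    "disease_symptom.tsv",
    "disease_protein.tsv",
    "disease_pathway.tsv",
    "disease_variant.tsv",
    "drug_edges.tsv",
    "gene_protein.tsv",
    "ppi.tsv",
    "gda.tsv",
)


def _read_tsv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.is_file():
        raise GraphConfigurationError(f"missing input file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise GraphConfigurationError(f"{path}: missing columns {missing}")
    return df


def load_graph(directory: str | Path) -> KnowledgeGraph:
    """Load a knowledge graph from its edge-list file-set directory.

    Raises :class:`GraphConfigurationError` for missing files and
    :class:`GraphValidationError` for dangling edge endpoints, malformed
    prevalence classes or out-of-range scores.
    """
    directory = Path(directory)
    ddf = _read_tsv(
        directory / "diseases.tsv",
        ("id", "name", "is_rare", "prevalence_class", "prevalence_geography"),
    )
    diseases: dict[str, Disease] = {}
    for row in ddf.itertuples(index=False):
        if row.id in diseases:
            raise GraphValidationError(f"duplicate disease id: {row.id!r}")
        diseases[row.id] = Disease(
            id=row.id,
            name=row.name,
            is_rare=str(row.is_rare).strip().lower() in {"true", "1", "yes"},
            prevalence_class=row.prevalence_class,
            prevalence_geography=row.prevalence_geography,
        )

    rdf = _read_tsv(directory / "drugs.tsv", ("id", "name", "atc_codes"))
    drugs: dict[str, Drug] = {}
    for row in rdf.itertuples(index=False):
        if row.id in drugs:
            raise GraphValidationError(f"duplicate drug id: {row.id!r}")
        codes = frozenset(c for c in str(row.atc_codes).split(";") if c)
        drugs[row.id] = Drug(id=row.id, name=row.name, atc_codes=codes)

    ndf = _read_tsv(directory / "nodes.tsv", ("id", "role"))
    node_roles = dict(zip(ndf["id"], ndf["role"]))

    def pairs(fname: str, cols: tuple[str, str]):
        df = _read_tsv(directory / fname, cols)
        return [(a, b) for a, b in zip(df[cols[0]], df[cols[1]])]

    edf = _read_tsv(directory / "drug_edges.tsv", ("drug_id", "kind", "node_id"))
    indication, target = [], []
    for row in edf.itertuples(index=False):
        if row.kind == "indication":
            indication.append((row.drug_id, row.node_id))
        elif row.kind == "target":
            target.append((row.drug_id, row.node_id))
        else:
            raise GraphValidationError(
                f"drug_edges.tsv: unknown edge kind {row.kind!r}"
            )

    gdf = _read_tsv(
        directory / "gda.tsv", ("gene_id", "disease_id", "gda_score", "dsi", "dpi")
    )
    gda = frozenset(
        GDARecord(
            gene=row.gene_id,
            disease_id=row.disease_id,
            gda_score=float(row.gda_score),
            dsi=float(row.dsi),
            dpi=float(row.dpi),
        )
        for row in gdf.itertuples(index=False)
    )

    return KnowledgeGraph(
        diseases=diseases,
        drugs=drugs,
        node_roles=node_roles,
        disease_gene=frozenset(pairs("disease_gene.tsv", ("disease_id", "feature_id"))),
        disease_symptom=frozenset(
            pairs("disease_symptom.tsv", ("disease_id", "feature_id"))
        ),
        disease_protein=frozenset(
            pairs("disease_protein.tsv", ("disease_id", "feature_id"))
        ),
        disease_pathway=frozenset(
            pairs("disease_pathway.tsv", ("disease_id", "feature_id"))
        ),
        disease_variant=frozenset(
            pairs("disease_variant.tsv", ("disease_id", "feature_id"))
        ),
        drug_indication=frozenset(indication),
        drug_target=frozenset(target),
        gene_protein=frozenset(pairs("gene_protein.tsv", ("gene_id", "protein_id"))),
        ppi=frozenset(pairs("ppi.tsv", ("protein_a", "protein_b"))),
        gda=gda,
    )


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def save_graph(graph: KnowledgeGraph, directory: str | Path) -> list[Path]:
    """Write the edge-list file set; byte-stable under a fixed sort.

    ``load_graph(save_graph(g))`` reproduces ``g`` field-for-field.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        probe = directory / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"directory not writable: {directory}") from exc

    written: list[Path] = []

    def emit(fname: str, df: pd.DataFrame, sort_cols: list[str]) -> None:
        path = directory / fname
        _write_tsv(path, df.sort_values(sort_cols).reset_index(drop=True))
        written.append(path)

    emit(
        "diseases.tsv",
        pd.DataFrame(
            [
                {
                    "id": d.id,
                    "name": d.name,
                    "is_rare": str(d.is_rare).lower(),
                    "prevalence_class": d.prevalence_class,
                    "prevalence_geography": d.prevalence_geography,
                }
                for d in graph.diseases.values()
            ],
            columns=["id", "name", "is_rare", "prevalence_class", "prevalence_geography"],
        ),
        ["id"],
    )
    emit(
        "drugs.tsv",
        pd.DataFrame(
            [
                {"id": d.id, "name": d.name, "atc_codes": ";".join(sorted(d.atc_codes))}
                for d in graph.drugs.values()
            ],
            columns=["id", "name", "atc_codes"],
        ),
        ["id"],
    )
    emit(
        "nodes.tsv",
        pd.DataFrame(
            [{"id": n, "role": r} for n, r in graph.node_roles.items()],
            columns=["id", "role"],
        ),
        ["role", "id"],
    )
    for fname, edges in (
        ("disease_gene.tsv", graph.disease_gene),
        ("disease_symptom.tsv", graph.disease_symptom),
        ("disease_protein.tsv", graph.disease_protein),
        ("disease_pathway.tsv", graph.disease_pathway),
        ("disease_variant.tsv", graph.disease_variant),
    ):
        emit(
            fname,
            pd.DataFrame(sorted(edges), columns=["disease_id", "feature_id"]),
            ["disease_id", "feature_id"],
        )
    drug_rows = [
        {"drug_id": d, "kind": "indication", "node_id": n}
        for d, n in graph.drug_indication
    ] + [{"drug_id": d, "kind": "target", "node_id": n} for d, n in graph.drug_target]
    emit(
        "drug_edges.tsv",
        pd.DataFrame(drug_rows, columns=["drug_id", "kind", "node_id"]),
        ["drug_id", "kind", "node_id"],
    )
    emit(
        "gene_protein.tsv",
        pd.DataFrame(sorted(graph.gene_protein), columns=["gene_id", "protein_id"]),
        ["gene_id", "protein_id"],
    )
    emit(
        "ppi.tsv",
        pd.DataFrame(sorted(graph.ppi), columns=["protein_a", "protein_b"]),
        ["protein_a", "protein_b"],
    )
    emit(
        "gda.tsv",
        pd.DataFrame(
            [
                {
                    "gene_id": r.gene,
                    "disease_id": r.disease_id,
                    "gda_score": repr(r.gda_score),
                    "dsi": repr(r.dsi),
                    "dpi": repr(r.dpi),
                }
                for r in graph.gda
            ],
            columns=["gene_id", "disease_id", "gda_score", "dsi", "dpi"],
        ),
        ["gene_id", "disease_id"],
    )
    return written
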