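"""End-to-end orchestration: select → similarity → reposition → stats.

:func:`run_pipeline` runs every stage on a graph directory and writes a
report bundle of TSV tables (candidate summary, per-feature similarity
rankings, validation summary, phenotypic-similarity test, GDA test, ATC
histogram) plus a YAML manifest carrying the resolved configuration, the
seed and SHA-256 digests of the inputs.  The bundle is byte-identical
across runs with the same config and inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .disease_selection import SelectionCriteria, select_diseases
from .downstream_stats import (
    ValidationRecord,
    atc_level1_composition,
    gda_pairs_from_results,
    gda_test,
    hypothesis_pairs_from_results,
    phenotypic_similarity_test,
    summarize_validation,
)
from .kg_model import FEATURES, KnowledgeGraph, load_graph
from .repositioning import RepositioningParams, run_all
from .similarity import rank_neighbors

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    graph_dir: str = ""
    out_dir: str = "pipeline_out"
    validation_file: str | None = None
    # selection
    require_rare: bool = True
    require_in_graph: bool = True
    exclude_with_treatment: bool = False
    require_genes_and_symptoms: bool = True
    geography_whitelist: list[str] | None = None
    prevalence_whitelist: list[str] | None = None
    # similarity / repositioning
    k: int = 5
    share_min: int = 2
    strict_features: bool = False
    restrict_intermediates_to_nonrare: bool = True
    exclude_known: bool = True
    # stats
    alpha: float = 0.05
    gda_leave_out: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def selection_criteria(self) -> SelectionCriteria:
        return SelectionCriteria(
            require_rare=self.require_rare,
            require_in_graph=self.require_in_graph,
            exclude_with_treatment=self.exclude_with_treatment,
            require_genes_and_symptoms=self.require_genes_and_symptoms,
            geography_whitelist=(
                frozenset(self.geography_whitelist)
                if self.geography_whitelist is not None
                else None
            ),
            prevalence_whitelist=(
                frozenset(self.prevalence_whitelist)
                if self.prevalence_whitelist is not None
                else None
            ),
        )

    def repositioning_params(self) -> RepositioningParams:
        return RepositioningParams(
            k=self.k,
            share_min=self.share_min,
            strict_features=self.strict_features,
            restrict_intermediates_to_nonrare=self.restrict_intermediates_to_nonrare,
            exclude_known=self.exclude_known,
        )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def load_validation_records(path: str | Path) -> list[ValidationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        ValidationRecord(
            disease_id=row.disease_id,
            drug_id=row.drug_id,
            status=row.status,
            evidence=getattr(row, "evidence", ""),
        )
        for row in df.itertuples(index=False)
    ]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns written paths."""
    out: dict[str, Path] = {}
    graph_dir = Path(config.graph_dir)
    if not graph_dir.is_dir():
        raise PipelineError("config", f"graph directory not found: {graph_dir}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        graph = load_graph(graph_dir)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    # -- selection ------------------------------------------------------
    try:
        selection = select_diseases(graph, config.selection_criteria())
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc
    _write_tsv(
        out_dir / "selected.tsv",
        pd.DataFrame({"disease_id": list(selection.selected)}),
    )
    _write_tsv(out_dir / "attrition.tsv", selection.attrition_frame())
    out["selected"] = out_dir / "selected.tsv"
    out["attrition"] = out_dir / "attrition.tsv"
    rare_ids = list(selection.selected)

    # -- similarity rankings ---------------------------------------------
    try:
        sim_dir = out_dir / "similarity"
        sim_dir.mkdir(exist_ok=True)
        for feature in FEATURES:
            rows = []
            for rid in rare_ids:
                ranking = rank_neighbors(graph, rid, feature, k=config.k)
                for rank, (nid, score) in enumerate(ranking.entries, start=1):
                    rows.append(
                        {
                            "rare_id": rid,
                            "nonrare_id": nid,
                            "score": repr(score),
                            "rank": rank,
                        }
                    )
            _write_tsv(
                sim_dir / f"{feature}.tsv",
                pd.DataFrame(rows, columns=["rare_id", "nonrare_id", "score", "rank"]),
            )
            out[f"similarity_{feature}"] = sim_dir / f"{feature}.tsv"
    except Exception as exc:
        raise PipelineError("similarity", str(exc)) from exc

    # -- repositioning ----------------------------------------------------
    try:
        results, summary = run_all(graph, rare_ids, config.repositioning_params())
    except Exception as exc:
        raise PipelineError("reposition", str(exc)) from exc
    _write_tsv(out_dir / "summary.tsv", summary)
    out["summary"] = out_dir / "summary.tsv"
    cand_rows = []
    for r in results:
        for drug_id in sorted(r.candidate_drugs):
            cand_rows.append(
                {
                    "disease_id": r.rare_id,
                    "drug_id": drug_id,
                    "approaches": ";".join(
                        a for a in sorted(r.per_approach) if drug_id in r.per_approach[a]
                    ),
                    "in_all": drug_id in r.all_combined,
                    "in_ttddrp": drug_id in r.ttddrp_combined,
                }
            )
    _write_tsv(
        out_dir / "candidates.tsv",
        pd.DataFrame(
            cand_rows,
            columns=["disease_id", "drug_id", "approaches", "in_all", "in_ttddrp"],
        ),
    )
    out["candidates"] = out_dir / "candidates.tsv"

    # -- downstream stats --------------------------------------------------
    try:
        if config.validation_file:
            records = load_validation_records(config.validation_file)
            vsummary = summarize_validation(records, results)
            _write_tsv(out_dir / "validation_summary.tsv", vsummary.with_totals_row())
            out["validation_summary"] = out_dir / "validation_summary.tsv"

        all_candidates: set[str] = set()
        for r in results:
            all_candidates |= r.candidate_drugs
        histogram = atc_level1_composition(sorted(all_candidates), graph)
        _write_tsv(
            out_dir / "atc_histogram.tsv",
            pd.DataFrame(
                [{"atc_level1": k, "count": v} for k, v in histogram.items()],
                columns=["atc_level1", "count"],
            ),
        )
        out["atc_histogram"] = out_dir / "atc_histogram.tsv"

        ps_pairs = hypothesis_pairs_from_results(graph, results)
        ps_rows = []
        if ps_pairs:
            ps = phenotypic_similarity_test(graph, ps_pairs)
            ps_rows.append(
                {
                    "mean_background": repr(ps.mean_background),
                    "mean_hypothesis": repr(ps.mean_hypothesis),
                    "p_value": repr(ps.p_value),
                    "direction": ps.direction,
                    "n_hypothesis": ps.n_hypothesis,
                    "n_background": ps.n_background,
                }
            )
        _write_tsv(
            out_dir / "ps_test.tsv",
            pd.DataFrame(
                ps_rows,
                columns=[
                    "mean_background",
                    "mean_hypothesis",
                    "p_value",
                    "direction",
                    "n_hypothesis",
                    "n_background",
                ],
            ),
        )
        out["ps_test"] = out_dir / "ps_test.tsv"

        gda_pairs = gda_pairs_from_results(graph, results)
        gda_rows = []
        if gda_pairs:
            for disease_id, res in gda_test(
                graph, gda_pairs, leave_out=config.gda_leave_out
            ).items():
                gda_rows.append(
                    {
                        "disease_id": disease_id,
                        "n_genes": len(res.gda_scores),
                        "mean_gda": repr(float(pd.Series(res.gda_scores).mean())),
                        "mean_background": repr(
                            float(pd.Series(res.background_scores).mean())
                        ),
                        "p_value": repr(res.p_value),
                        "direction": res.direction,
                    }
                )
        _write_tsv(
            out_dir / "gda_test.tsv",
            pd.DataFrame(
                gda_rows,
                columns=[
                    "disease_id",
                    "n_genes",
                    "mean_gda",
                    "mean_background",
                    "p_value",
                    "direction",
                ],
            ),
        )
        out["gda_test"] = out_dir / "gda_test.tsv"
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    # -- manifest ----------------------------------------------------------
    manifest = {
        "raredr_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "input_digests": {
            p.name: _digest(p) for p in sorted(graph_dir.glob("*.tsv"))
        },
    }
    with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    out["manifest"] = out_dir / "manifest.yaml"
    config.to_yaml(out_dir / "config.yaml")
    out["config"] = out_dir / "config.yaml"
    return out
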