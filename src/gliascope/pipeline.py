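"""End-to-end orchestration: simulate -> normalize -> DEGs -> reference ->
classify -> cross-reference -> enrichment, as one configured, logged,
reproducible run.

Given a seed and a :class:`RunConfig`, every stage is deterministic; all
outputs carry the config hash and seed in their metadata, and a final
``report.json`` scores recovery against the planted truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .celltypes import build_reference, annotate_deg_list
from .deg import (GroupDesign, comparison_degs, intersect_comparisons,
                  collapse_to_genes)
from .ectopic import build_fc_table, celltype_fold_changes, scan_ectopic
from .enrichment import overrepresentation_test
from .mas5 import Mas5Params, normalize_dataset
from .synthetic_data import (make_category_map, simulate_deg_study,
                             simulate_ectopic_study, simulate_reference_study,
                             NoiseParams)

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "analyze_deg_study", "recovery_metrics"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Every knob of a full demonstration run."""

    seed: int = 0
    # simulation
    n_genes: int = 2000
    n_deg: int = 60
    min_fc: float = 2.5
    max_fc: float = 6.0
    n_comparisons: int = 3
    n_replicates: int = 3
    cv: float = 0.15
    background: float = 50.0
    probes_per_set: int = 11
    enriched_fraction: float = 0.2
    enrichment_factor: float = 5.0
    # DEG thresholds
    fc_threshold: float = 2.0
    fdr: float = 0.05
    require_fdr: bool = False
    direction_consistency: bool = True
    min_pm: int = 3
    # classification / cross-reference
    class_factor: float = 4.0
    contamination_fraction: float = 0.1
    ectopic_fold: float = 50.0
    ectopic_k: float = 3.0
    ectopic_floor: float = 10.0
    n_pure: int = 200
    ectopic_n_genes: int = 1200
    # MAS5 constants
    mas5: Mas5Params = field(default_factory=Mas5Params)

    def __post_init__(self) -> None:
        if isinstance(self.mas5, dict):
            self.mas5 = Mas5Params(**self.mas5)
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_deg < 0 or self.n_genes < 10:
            raise ValueError("invalid simulation sizes")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**io.read_config_yaml(path))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def analyze_deg_study(study, fc_threshold: float = 2.0, fdr: float = 0.05,
                      require_fdr: bool = False,
                      direction_consistency: bool = True, min_pm: int = 3,
                      mas5: Mas5Params | None = None):
    """Normalize, test and intersect a simulated multi-comparison study.

    Returns ``(recovered_genes, entities, tables)`` where recovered_genes
    is the deduplicated gene set common to all comparisons.
    """
    tables = []
    for comp in study.comparisons:
        intensities = comp.mutant.intensities.join(comp.control.intensities)
        expr = normalize_dataset(intensities, study.layout, mas5)
        design = GroupDesign(comp.comparison_id,
                             mutant=tuple(comp.mutant.intensities.columns),
                             control=tuple(comp.control.intensities.columns))
        tables.append(comparison_degs(expr, design, fc_threshold, fdr,
                                      require_fdr, min_pm))
    entities = intersect_comparisons(tables, direction_consistency)
    collapsed = collapse_to_genes(entities, study.annotation, tables)
    return set(collapsed.genes["gene_id"]), entities, tables


def recovery_metrics(recovered: set, planted: set) -> dict:
    """Sensitivity and false-discovery proportion of a recovered gene set
    against the planted truth."""
    tp = len(recovered & planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "false_discovery_proportion":
            (len(recovered) - tp) / len(recovered) if recovered else 0.0,
        "n_recovered": len(recovered),
        "n_planted": len(planted),
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full chain and return the report dict.

    Writes every stage's tables under ``out_dir`` and a ``report.json``
    with DEG-recovery metrics, the per-class DEG counts, ectopic calls
    and the top enrichment rows.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.config_hash(), "seed": config.seed}
    io.write_config_yaml(config.to_dict(), out / "config.yaml")
    noise = NoiseParams(cv=config.cv, background=config.background)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2 ** 31) for s in ss.spawn(3)]

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-tagged and re-raised
            raise PipelineError(f"[{name}] {exc}") from exc

    # -- simulate ----------------------------------------------------------
    def _simulate():
        study = simulate_deg_study(
            n_genes=config.n_genes, n_deg=config.n_deg, min_fc=config.min_fc,
            max_fc=config.max_fc, n_comparisons=config.n_comparisons,
            n_replicates=config.n_replicates, noise=noise,
            probes_per_set=config.probes_per_set,
            enriched_fraction=config.enriched_fraction,
            enrichment_factor=config.enrichment_factor, seed=seeds[0])
        io.write_layout(study.layout, out / "sim" / "layout.tsv", meta)
        io.write_annotation(study.annotation, out / "sim" / "annotation.tsv", meta)
        io.write_truth(study.truth, out / "sim" / "truth.json")
        for comp in study.comparisons:
            for role, ds in (("mutant", comp.mutant), ("control", comp.control)):
                io.write_matrix(ds.intensities,
                                out / "sim" / f"{comp.comparison_id}_{role}.tsv",
                                meta)
        return study

    study = stage("simulate", _simulate)
    logger.info("simulated %d comparisons over %d genes",
                len(study.comparisons), config.n_genes)

    # -- normalize + per-comparison DEGs -----------------------------------
    def _normalize_and_test():
        tables = []
        for comp in study.comparisons:
            intensities = comp.mutant.intensities.join(comp.control.intensities)
            expr = normalize_dataset(intensities, study.layout, config.mas5)
            logger.info("%s scale factors: %s", comp.comparison_id,
                        dict(expr.scale_factors.round(4)))
            io.write_expression(expr, out / "expr" / comp.comparison_id, meta)
            design = GroupDesign(comp.comparison_id,
                                 mutant=tuple(comp.mutant.intensities.columns),
                                 control=tuple(comp.control.intensities.columns))
            table = comparison_degs(expr, design, config.fc_threshold,
                                    config.fdr, config.require_fdr,
                                    config.min_pm)
            io.write_table(table.rename_axis("probeset_id").reset_index(),
                           out / "degs" / f"{comp.comparison_id}.tsv", meta)
            tables.append(table)
        return tables

    tables = stage("degs", _normalize_and_test)

    def _intersect():
        entities = intersect_comparisons(tables, config.direction_consistency)
        collapsed = collapse_to_genes(entities, study.annotation, tables)
        io.write_table(collapsed.genes, out / "degs" / "degs.tsv", meta)
        return entities, collapsed

    entities, collapsed = stage("intersect", _intersect)
    recovered = set(collapsed.genes["gene_id"])
    planted = set(study.truth.planted_deg_genes)
    tp = len(recovered & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdp = (len(recovered) - tp) / len(recovered) if recovered else 0.0

    # -- reference + classification ----------------------------------------
    def _reference():
        ref_study = simulate_reference_study(
            n_replicates=config.n_replicates,
            noise=NoiseParams(cv=min(config.cv, 0.1), background=0.0),
            probes_per_set=config.probes_per_set, profiles=study.profiles,
            layout=study.layout, annotation=study.annotation, seed=seeds[1])
        datasets = {t: normalize_dataset(ds.intensities, study.layout,
                                         config.mas5)
                    for t, ds in ref_study.datasets.items()}
        reference = build_reference(datasets, study.annotation,
                                    config.class_factor)
        ref_out = reference.values.copy()
        ref_out["class"] = reference.classes
        io.write_matrix(ref_out, out / "reference" / "reference.tsv", meta)
        classified, counts = annotate_deg_list(sorted(recovered), reference)
        io.write_table(classified, out / "reference" / "classified.tsv", meta)
        io.write_table(counts.rename_axis("class").reset_index(),
                       out / "reference" / "class_counts.tsv", meta)
        return reference, classified, counts

    reference, classified, counts = stage("reference", _reference)

    # -- disease cross-reference (ectopic detection) ------------------------
    def _crossref():
        ect = simulate_ectopic_study(
            n_genes=config.ectopic_n_genes, n_pure=config.n_pure,
            ectopic_fold=config.ectopic_fold,
            contamination_fraction=config.contamination_fraction,
            noise=noise, probes_per_set=config.probes_per_set, seed=seeds[2])
        dis = normalize_dataset(ect.disease.intensities, ect.layout, config.mas5)
        ctl = normalize_dataset(ect.control.intensities, ect.layout, config.mas5)
        label = f"{ect.host}_disease"
        fc = celltype_fold_changes(dis, ctl, ect.annotation)
        fc_table = build_fc_table({label: fc})
        io.write_matrix(fc_table, out / "crossref" / "fc_table.tsv", meta)
        from .celltypes import reference_from_values
        ect_reference = reference_from_values(ect.profiles.expression,
                                              config.class_factor)
        calls = scan_ectopic(fc_table, label, ect.host, ect_reference,
                             {ect.home: ect.marker_genes},
                             k=config.ectopic_k, floor=config.ectopic_floor)
        io.write_table(calls, out / "crossref" / "ectopic.tsv", meta)
        return ect, calls

    ect_study, ectopic_calls = stage("crossref", _crossref)
    flagged = set(ectopic_calls.loc[ectopic_calls["flag"], "gene"])

    # -- enrichment ---------------------------------------------------------
    def _enrich():
        categories = make_category_map(study.profiles.planted_class,
                                       seed=config.seed)
        table = overrepresentation_test(sorted(recovered), categories,
                                        reference_size=config.n_genes)
        io.write_table(table, out / "enrichment" / "enrichment.tsv", meta)
        return table

    enrich_table = stage("enrichment", _enrich) if recovered else None

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "deg": {
            "n_entities": len(entities),
            "n_genes": len(recovered),
            "n_planted": len(planted),
            "sensitivity": round(sensitivity, 6),
            "false_discovery_proportion": round(fdp, 6),
        },
        "class_counts": {str(k): int(v) for k, v in counts.items()},
        "ectopic": {
            "planted": [ect_study.ectopic_gene],
            "flagged": sorted(flagged),
            "planted_recovered": ect_study.ectopic_gene in flagged,
            "false_positives": sorted(flagged - {ect_study.ectopic_gene}),
        },
        "enrichment_top": (
            enrich_table.head(3)[["category", "fold_enrichment", "p_raw",
                                  "q_value"]].to_dict("records")
            if enrich_table is not None else []),
    }
    io.write_json(report, out / "report.json")
    return report
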