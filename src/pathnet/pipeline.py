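"""End-to-end orchestration of the integrative pathway analysis.

Stage order: genotype QC → genotypic association → SNP selection →
SNP→gene collapse → (per layer) active-subnetwork search + pathway
enrichment over several seeded iterations → Fisher merge of the two layers
→ overlap-index clustering with representative selection.  The proteomic
layer enters directly at the subnetwork stage with its differential-
expression p-values.  A run manifest records every effective parameter and
per-stage count so a run is fully reproducible and inspectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .enrichment import iterate_and_aggregate
from .gene_scores import (
    assign_snps_to_genes,
    gene_level_scores,
    snps_per_gene,
    validate_protein_scores,
)
from .genome_assoc import genotypic_test, run_qc, threshold_snps
from .integration_merge import merge_layers
from .io_formats import (
    GenotypeDataset,
    GeneScoreTable,
    PathwayCollection,
    PPINetwork,
    SnpGeneMap,
    write_results,
)
from .pathway_clustering import cluster_enriched_pathways

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, with its conventional default."""

    alpha: float = 0.05            # SNP selection and enrichment significance
    sample_call: float = 0.98
    min_call: float = 0.95
    min_maf: float = 0.01
    r2_max: float = 0.5
    ld_window: int = 50
    ld_step: int = 5
    n_iter: int = 10
    n_seeds: int = 20
    max_depth: int | None = None
    max_overlap: float = 0.5
    cut: float = 0.55
    calibration_samples: int = 1000
    collapse_strategy: str = "min"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "sample_call", "min_call", "min_maf",
                     "r2_max", "max_overlap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    merged: list
    clusters: object
    genomic_layer: list
    proteomic_layer: list
    qc_report: object
    association: list
    manifest: dict


def run_all(
    genotypes: GenotypeDataset,
    snp_gene_map: SnpGeneMap,
    protein_scores: GeneScoreTable,
    ppi: PPINetwork,
    pathways: PathwayCollection,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute every stage on in-memory inputs; any failure names its stage."""
    cfg = config or PipelineConfig()
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "counts": {},
    }
    counts = manifest["counts"]
    ss = np.random.SeedSequence(cfg.seed)
    seed_genomic, seed_proteomic = ss.spawn(2)

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return deco

    @stage("qc")
    def qc():
        ds, report = run_qc(
            genotypes, sample_call=cfg.sample_call, min_call=cfg.min_call,
            min_maf=cfg.min_maf, r2_max=cfg.r2_max,
            window=cfg.ld_window, step=cfg.ld_step,
        )
        counts["snps_in"] = genotypes.n_snps
        counts["samples_in"] = genotypes.n_samples
        counts["samples_retained"] = ds.n_samples
        counts["snps_retained"] = ds.n_snps
        for reason in report.VALID_SNP_REASONS:
            counts[f"snps_excluded_{reason.lower()}"] = sum(
                r == reason for r in report.excluded_snps.values()
            )
        return ds, report

    dataset, qc_report = qc

    @stage("assoc")
    def assoc():
        results = genotypic_test(dataset)
        selected = threshold_snps(results, alpha=cfg.alpha)
        counts["snps_selected"] = len(selected)
        return results, selected

    association, selected_snps = assoc

    @stage("map-genes")
    def map_genes():
        pmap = {r.snp_id: r.p_value for r in association}
        assignments = assign_snps_to_genes(
            {s: pmap[s] for s in selected_snps}, snp_gene_map
        )
        table = gene_level_scores(assignments, strategy=cfg.collapse_strategy)
        counts["genes_scored_genomic"] = len(table)
        return table, snps_per_gene(assignments)

    genomic_scores, gene_snps = map_genes

    @stage("proteomic-scores")
    def prot():
        table = validate_protein_scores(protein_scores, alpha=cfg.alpha)
        counts["genes_scored_proteomic"] = len(table)
        return table

    proteomic_scores = prot

    @stage("enrich")
    def enrich():
        if len(pathways) == 0:
            raise ValueError("empty pathway collection")
        genomic = iterate_and_aggregate(
            genomic_scores, ppi, pathways, n_iter=cfg.n_iter,
            seed=seed_genomic, gene_snps=gene_snps, alpha=cfg.alpha,
            n_seeds=cfg.n_seeds, max_depth=cfg.max_depth,
            max_overlap=cfg.max_overlap,
            calibration_samples=cfg.calibration_samples,
        )
        proteomic = iterate_and_aggregate(
            proteomic_scores, ppi, pathways, n_iter=cfg.n_iter,
            seed=seed_proteomic, alpha=cfg.alpha,
            n_seeds=cfg.n_seeds, max_depth=cfg.max_depth,
            max_overlap=cfg.max_overlap,
            calibration_samples=cfg.calibration_samples,
        )
        counts["pathways_enriched_genomic"] = len(genomic)
        counts["pathways_enriched_proteomic"] = len(proteomic)
        return genomic, proteomic

    genomic_layer, proteomic_layer = enrich

    @stage("merge")
    def merge():
        merged = merge_layers(genomic_layer, proteomic_layer, pathways)
        counts["pathways_merged"] = len(merged)
        return merged

    merged = merge

    @stage("cluster")
    def cluster():
        assignment = cluster_enriched_pathways(merged, pathways, cut=cfg.cut)
        counts["clusters"] = assignment.n_clusters if assignment else len(merged)
        return assignment

    clusters = cluster

    logger.info("pipeline complete: %s", counts)
    return PipelineResult(
        merged=merged, clusters=clusters,
        genomic_layer=genomic_layer, proteomic_layer=proteomic_layer,
        qc_report=qc_report, association=association, manifest=manifest,
    )


def write_bundle(result: PipelineResult, out_dir) -> None:
    """Write the results TSV and the JSON run manifest to *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(result.merged, result.clusters, out / "merged_pathways.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
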