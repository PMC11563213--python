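"""Collapse SNP-level association p-values to gene-level scores.

Each selected SNP is assigned to the single candidate gene with the highest
functional-priority score in the user-supplied SNP→gene map (the map stands
in for functional-annotation services that rank a SNP's possible target
genes).  Gene-level p-values are then the minimum over the gene's assigned
SNPs by default; a Fisher-combination alternative is available.  The
proteomic layer enters as a ready-made (gene, p) table and is only
validated and thresholded here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .io_formats import GeneScoreTable, SnpGeneMap

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class GeneAssignment:
    snp_id: str
    gene_id: str
    priority_score: float
    p_value: float


def assign_snps_to_genes(
    selected_snps: dict[str, float], snp_gene_map: SnpGeneMap
) -> list[GeneAssignment]:
    """Assign each SNP to its maximum-priority candidate gene.

    *selected_snps* maps snp_id → association p-value.  Priority ties break
    to the lexicographically smallest gene id; SNPs with no candidate in the
    map are dropped (count logged).
    """
    rows = snp_gene_map.rows
    candidates = rows[rows["snp_id"].isin(selected_snps)]
    assignments: list[GeneAssignment] = []
    for snp_id, group in candidates.groupby("snp_id", sort=True):
        best = None
        for gene_id, priority in zip(group["gene_id"], group["priority_score"]):
            if (
                best is None
                or priority > best[1]
                or (priority == best[1] and gene_id < best[0])
            ):
                best = (gene_id, float(priority))
        assignments.append(
            GeneAssignment(str(snp_id), best[0], best[1], selected_snps[snp_id])
        )
    n_dropped = len(selected_snps) - len(assignments)
    if n_dropped:
        logger.info("%d SNP(s) had no candidate gene in the map; dropped", n_dropped)
    return assignments


def _fisher_within_gene(pvals: list[float]) -> float:
    x2 = -2.0 * sum(math.log(max(p, P_FLOOR)) for p in pvals)
    return float(stats.chi2.sf(x2, 2 * len(pvals)))


def gene_level_scores(
    assignments: list[GeneAssignment], strategy: str = "min"
) -> GeneScoreTable:
    """Collapse SNP assignments to one p-value per gene (genomic layer).

    ``strategy="min"`` (default) takes the minimum assigned SNP p per gene;
    ``"fisher"`` combines them with Fisher's method (df = 2·n_snps).
    """
    if not assignments:
        raise ValueError("no gene assignments to collapse")
    if strategy not in ("min", "fisher"):
        raise ValueError(f"unknown collapse strategy: {strategy}")
    by_gene: dict[str, list[float]] = {}
    for a in assignments:
        by_gene.setdefault(a.gene_id, []).append(a.p_value)
    entries = {}
    for gene in sorted(by_gene):
        pvals = by_gene[gene]
        p = min(pvals) if strategy == "min" else _fisher_within_gene(pvals)
        entries[gene] = max(p, P_FLOOR)
    return GeneScoreTable(entries=entries, layer_label="genomic")


def snps_per_gene(assignments: list[GeneAssignment]) -> dict[str, list[str]]:
    """Gene → sorted list of assigned SNP ids (for result reporting)."""
    out: dict[str, list[str]] = {}
    for a in assignments:
        out.setdefault(a.gene_id, []).append(a.snp_id)
    return {g: sorted(s) for g, s in out.items()}


def validate_protein_scores(
    raw, alpha: float = 0.05
) -> GeneScoreTable:
    """Validate the proteomic differential-expression table.

    Rows with p ≥ *alpha* are excluded (only significantly differentially
    expressed proteins enter the network analysis), duplicates collapse by
    minimum, and p-values are floored at 1e-300.  Raises if nothing remains.
    """
    if isinstance(raw, GeneScoreTable):
        pairs = list(raw.entries.items())
    elif isinstance(raw, dict):
        pairs = list(raw.items())
    else:  # iterable of (gene, p) rows, possibly with duplicate genes
        pairs = [(str(g), float(p)) for g, p in raw]
    out: dict[str, float] = {}
    for gene, p in pairs:
        if p >= alpha:
            continue
        p = max(float(p), P_FLOOR)
        out[gene] = min(p, out.get(gene, 1.0))
    if not out:
        raise ValueError(f"no proteins with p < {alpha}: empty proteomic layer")
    return GeneScoreTable(entries=dict(sorted(out.items())), layer_label="proteomic")
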