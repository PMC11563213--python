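"""Pathway over-representation testing of active subnetworks.

Each subnetwork is tested against every pathway it intersects with an exact
two-sided hypergeometric test (minimal-tail doubling), Bonferroni-corrected
over the pathways tested for that subnetwork.  Per pathway the best
(smallest) corrected p across subnetworks is kept, filtered at p < 0.05,
and the whole subnetwork+enrichment stage is repeated over several seeded
iterations with the per-pathway minimum across iterations reported.

The background universe is the set of genes present in both the PPI
network and the layer's score table: the hypergeometric draw models
subnetwork membership, which is only possible for scored network genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .active_subnetworks import Subnetwork, find_subnetworks
from .io_formats import GeneScoreTable, PathwayCollection, PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentTest:
    pathway_id: str
    N: int            # background gene count
    K: int            # pathway genes in background
    n: int            # subnetwork genes in background
    x: int            # overlap count
    p_raw: float
    p_bonferroni: float
    overlap_genes: frozenset = frozenset()


@dataclass
class LayerPathwayResult:
    pathway_id: str
    p_value: float                     # best Bonferroni-corrected p
    genes: frozenset = frozenset()     # contributing (overlap) genes
    snps: frozenset = frozenset()      # contributing SNP ids (genomic layer)


def hypergeom_two_sided(N: int, K: int, n: int, x: int, two_sided: bool = True) -> float:
    """Exact hypergeometric tail p-value for overlap *x*.

    X ~ Hypergeometric(N, K, n).  Two-sided (default) doubles the smaller of
    the two tails, capped at 1: p = min(1, 2·min(P[X ≥ x], P[X ≤ x])).
    One-sided returns the over-representation tail P[X ≥ x].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (max(0, n + K - N) <= x <= min(K, n)):
        raise ValueError(f"overlap x={x} outside support for N={N}, K={K}, n={n}")
    dist = stats.hypergeom(N, K, n)
    upper = float(dist.sf(x - 1))   # P[X >= x]
    if not two_sided:
        return min(upper, 1.0)
    lower = float(dist.cdf(x))      # P[X <= x]
    return min(1.0, 2.0 * min(upper, lower))


def enrich_subnetwork(
    subnetwork: Subnetwork | frozenset,
    pathways: PathwayCollection,
    background: set[str],
    two_sided: bool = True,
    bonferroni_scope: str = "tested",
) -> list[EnrichmentTest]:
    """Hypergeometric tests of one subnetwork against all overlapping pathways.

    Pathways with zero overlap are skipped.  Bonferroni m is the number of
    pathways actually tested for this subnetwork (``bonferroni_scope=
    "tested"``, default) or the full collection size (``"collection"``).
    """
    members = subnetwork.members if isinstance(subnetwork, Subnetwork) else frozenset(subnetwork)
    sub_bg = members & background
    N, n = len(background), len(sub_bg)
    raw: list[tuple[str, int, int, int, float, frozenset]] = []
    for rec in pathways:
        path_bg = rec.genes & background
        overlap = sub_bg & path_bg
        if not overlap:
            continue
        K, x = len(path_bg), len(overlap)
        p = hypergeom_two_sided(N, K, n, x, two_sided=two_sided)
        raw.append((rec.pathway_id, K, n, x, p, frozenset(overlap)))
    m = len(raw) if bonferroni_scope == "tested" else len(pathways)
    return [
        EnrichmentTest(pid, N, K, n, x, p, min(1.0, p * m), genes)
        for pid, K, n, x, p, genes in raw
    ]


def best_per_pathway(
    tests: list[EnrichmentTest], alpha: float = 0.05
) -> list[LayerPathwayResult]:
    """Per pathway, minimum corrected p over subnetworks; keep p < *alpha*.

    When several subnetworks tie at the minimum, their overlap gene sets are
    unioned.
    """
    best_p: dict[str, float] = {}
    genes: dict[str, frozenset] = {}
    for t in tests:
        prev = best_p.get(t.pathway_id)
        if prev is None or t.p_bonferroni < prev:
            best_p[t.pathway_id] = t.p_bonferroni
            genes[t.pathway_id] = t.overlap_genes
        elif t.p_bonferroni == prev:
            genes[t.pathway_id] = genes[t.pathway_id] | t.overlap_genes
    return [
        LayerPathwayResult(pid, p, genes[pid])
        for pid, p in sorted(best_p.items())
        if p < alpha
    ]


def _aggregate(results_by_iter: list[list[LayerPathwayResult]]) -> list[LayerPathwayResult]:
    best: dict[str, LayerPathwayResult] = {}
    for results in results_by_iter:
        for r in results:
            prev = best.get(r.pathway_id)
            if prev is None or r.p_value < prev.p_value:
                best[r.pathway_id] = LayerPathwayResult(
                    r.pathway_id, r.p_value, r.genes, r.snps
                )
            elif r.p_value == prev.p_value:
                best[r.pathway_id] = LayerPathwayResult(
                    r.pathway_id, prev.p_value,
                    prev.genes | r.genes, prev.snps | r.snps,
                )
    return sorted(best.values(), key=lambda r: (r.p_value, r.pathway_id))


def iterate_and_aggregate(
    score_table: GeneScoreTable,
    ppi: PPINetwork,
    pathways: PathwayCollection,
    n_iter: int = 10,
    seed: int | np.random.SeedSequence = 0,
    gene_snps: dict[str, list[str]] | None = None,
    alpha: float = 0.05,
    two_sided: bool = True,
    n_seeds: int = 20,
    max_depth: int | None = None,
    max_overlap: float = 0.5,
    calibration_samples: int = 1000,
) -> list[LayerPathwayResult]:
    """Run subnetwork search + enrichment *n_iter* times; report per-pathway minima.

    Iterations differ only through the Monte-Carlo calibration randomness
    (distinct child seeds of *seed*); the per-pathway p is the minimum across
    iterations and contributing genes/SNPs are unioned across tying minima.
    *gene_snps* (genomic layer) maps gene → SNP ids used for reporting.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    background = set(score_table.entries) & ppi.nodes
    if not background:
        raise ValueError("no scored genes present in the PPI network")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    per_iter: list[list[LayerPathwayResult]] = []
    for child in ss.spawn(n_iter):
        rng = np.random.default_rng(child)
        modules = find_subnetworks(
            score_table, ppi, n_seeds=n_seeds, max_depth=max_depth,
            max_overlap=max_overlap, calibration_samples=calibration_samples,
            rng=rng,
        )
        tests: list[EnrichmentTest] = []
        for sub in modules:
            tests.extend(
                enrich_subnetwork(sub, pathways, background, two_sided=two_sided)
            )
        results = best_per_pathway(tests, alpha=alpha)
        if gene_snps:
            results = [
                LayerPathwayResult(
                    r.pathway_id, r.p_value, r.genes,
                    frozenset(s for g in r.genes for s in gene_snps.get(g, ())),
                )
                for r in results
            ]
        per_iter.append(results)
        logger.info(
            "iteration: %d subnetworks, %d enriched pathways",
            len(modules), len(results),
        )
    return _aggregate(per_iter)
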