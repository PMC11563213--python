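"""Seeded generators for every input the pipeline consumes, with ground truth.

The generator emulates the study design the pipeline targets: a small
case/control genotyping cohort (11 cases vs 60 controls by default), a
scale-free protein–protein interaction network, a KEGG-style pathway
collection, a SNP→gene functional-priority map, and a proteomic
differential-expression table.  Signal is *planted*: SNPs mapping to genes
of designated "genomic" pathways get a case/control allele-frequency shift,
genes of designated "proteomic" pathways get Beta(a, 1) p-values, and the
planted pathways are seeded inside connected PPI neighbourhoods so that
active-subnetwork search can recover them.  The returned
:class:`GroundTruth` records what was planted so downstream stages can be
scored against a known answer.

Null SNPs draw genotypes Binomial(2, f) with f ~ Uniform(0.05, 0.5)
identically in cases and controls; associated SNPs shift the case allele
frequency by ``effect_delta`` (clamped to [0.01, 0.99]).  Linkage
disequilibrium is not modelled beyond duplicating a few SNP columns
(``ld_dup_fraction``) so that the r²-pruning stage has something to do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import (
    GenotypeDataset,
    GeneScoreTable,
    PathwayCollection,
    PathwayRecord,
    PPINetwork,
    SnpGeneMap,
)

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-design defaults."""

    n_cases: int = 11
    n_controls: int = 60
    n_snps: int = 2000
    n_genes: int = 300
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 30)
    ppi_mean_degree: float = 4.0
    planted_pathways_genomic: tuple[str, ...] = ()
    planted_pathways_proteomic: tuple[str, ...] = ()
    signal_beta_shape: float = 0.1     # signal p ~ Beta(a, 1); a=1 is null
    effect_delta: float = 0.2          # case/control allele-frequency shift
    missing_rate: float = 0.01
    y_chrom_fraction: float = 0.02     # SNPs labelled chromosome Y
    low_call_fraction: float = 0.02    # SNPs forced below the 95% call rate
    ld_dup_fraction: float = 0.01      # SNP columns duplicated (r2 = 1 pairs)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps, self.n_genes,
               self.n_pathways) <= 0:
            raise ValueError("all counts must be positive")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid pathway size range ({lo}, {hi})")
        if hi > self.n_genes:
            raise ValueError("pathway sizes cannot exceed n_genes")
        if not (0.0 < self.signal_beta_shape <= 1.0):
            raise ValueError("signal_beta_shape must be in (0, 1]")
        if not (0.0 <= self.effect_delta <= 0.5):
            raise ValueError("effect_delta must be in [0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.ppi_mean_degree >= self.n_genes:
            raise ValueError("ppi_mean_degree must be < n_genes")
        known = {f"P{i:04d}" for i in range(1, self.n_pathways + 1)}
        for pid in (*self.planted_pathways_genomic, *self.planted_pathways_proteomic):
            if pid not in known:
                raise ValueError(f"planted pathway {pid} outside P0001..P{self.n_pathways:04d}")


@dataclass
class GroundTruth:
    associated_snp_ids: frozenset
    active_module_genes: dict[str, frozenset]   # planted pathway -> its genes
    enriched_pathways_genomic: frozenset
    enriched_pathways_proteomic: frozenset

    @property
    def shared_pathway_ids(self) -> frozenset:
        return self.enriched_pathways_genomic & self.enriched_pathways_proteomic


def _gene_id(i: int) -> str:
    return f"G{i + 1:06d}"


def simulate_ppi(config: SimulationConfig, rng: np.random.Generator) -> PPINetwork:
    """Connected scale-free PPI stand-in via preferential attachment.

    Mean degree ≈ ``ppi_mean_degree`` (Barabási–Albert with m ≈ mean/2);
    node ids are "G000001"… and the edge set is a deterministic function of
    the rng state.
    """
    m = max(1, round(config.ppi_mean_degree / 2))
    seed_int = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(config.n_genes, m, seed=seed_int)
    g = nx.relabel_nodes(g, {i: _gene_id(i) for i in g.nodes()})
    return PPINetwork.from_networkx(g)


def _connected_sample(
    g: nx.Graph,
    size: int,
    rng: np.random.Generator,
    start: str | None = None,
    allowed: set[str] | None = None,
) -> list[str]:
    """Random connected node set grown by frontier expansion from *start*.

    When *allowed* is given, growth is confined to that node set (the walk
    may terminate short of *size* if the allowed region is exhausted).
    """
    pool = sorted(g.nodes()) if allowed is None else sorted(allowed)
    if not pool:
        return []
    if start is None:
        start = pool[rng.integers(len(pool))]
    ok = (lambda n: True) if allowed is None else (lambda n: n in allowed)
    members = [start]
    frontier = sorted(n for n in g.neighbors(start) if ok(n))
    while len(members) < size and frontier:
        nxt = frontier.pop(rng.integers(len(frontier)))
        members.append(nxt)
        for nb in sorted(g.neighbors(nxt)):
            if ok(nb) and nb not in members and nb not in frontier:
                frontier.append(nb)
    return members


def simulate_pathways(
    config: SimulationConfig, ppi: PPINetwork, rng: np.random.Generator
) -> PathwayCollection:
    """Pathway collection with planted pathways seeded in PPI neighbourhoods.

    Planted pathways (ids named in the config) draw 85% of their genes from
    one connected neighbourhood of the network (so their induced subgraph
    has a dominant connected component) and the rest uniformly; non-planted
    pathways are uniform random gene sets.  Planted neighbourhoods are
    pairwise disjoint and avoid the highest-degree hubs, keeping distinct
    modules separated in the graph rather than chained through hubs.
    """
    lo, hi = config.pathway_size_range
    g = ppi.to_networkx()
    all_genes = sorted(ppi.nodes)
    degrees = dict(g.degree())
    degree_cap = float(np.quantile(sorted(degrees.values()), 0.90))
    non_hub = {n for n, d in degrees.items() if d <= degree_cap}
    planted = set(config.planted_pathways_genomic) | set(config.planted_pathways_proteomic)
    taken: set[str] = set()
    records = []
    for i in range(1, config.n_pathways + 1):
        pid = f"P{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if pid in planted:
            target = max(1, round(0.85 * size))
            core: list[str] = []
            for _attempt in range(5):  # a start can land in a small pocket
                cand = _connected_sample(g, target, rng, allowed=non_hub - taken)
                if len(cand) > len(core):
                    core = cand
                if len(core) >= target:
                    break
            taken.update(core)
            rest_pool = [x for x in all_genes if x not in core and x not in taken]
            n_extra = min(size - len(core), len(rest_pool))
            extra = list(
                rng.choice(rest_pool, size=n_extra, replace=False)
            ) if n_extra > 0 else []
            taken.update(str(x) for x in extra)
            genes = frozenset(core) | frozenset(str(x) for x in extra)
        else:
            genes = frozenset(
                str(x) for x in rng.choice(all_genes, size=size, replace=False)
            )
        records.append(PathwayRecord(pid, f"synthetic pathway {i}", genes))
    return PathwayCollection(records)


def densify_planted_neighbourhoods(
    ppi: PPINetwork,
    pathways: PathwayCollection,
    planted_ids,
    rng: np.random.Generator,
    target_degree: float = 4.0,
) -> PPINetwork:
    """Add edges inside planted pathways until their induced subgraphs reach
    *target_degree* mean internal degree.

    Frontier-grown neighbourhoods on a preferential-attachment graph are
    tree-like and shatter when a fraction of their genes is unscored;
    genuine disease modules are densely interconnected (the premise of
    module-based analysis), so planted modules are reinforced to survive
    partial observation.
    """
    g = ppi.to_networkx()
    for pid in sorted(set(planted_ids)):
        genes = sorted(pathways[pid].genes)
        sub = g.subgraph(genes)
        need = int(target_degree * len(genes) / 2) - sub.number_of_edges()
        non_edges = [
            (a, b)
            for i, a in enumerate(genes) for b in genes[i + 1:]
            if not g.has_edge(a, b)
        ]
        if need > 0 and non_edges:
            chosen = rng.choice(len(non_edges), size=min(need, len(non_edges)),
                                replace=False)
            g.add_edges_from(non_edges[i] for i in chosen)
    return PPINetwork.from_networkx(g)


def simulate_snp_gene_map(
    config: SimulationConfig, rng: np.random.Generator
) -> SnpGeneMap:
    """SNP→gene candidate map with functional-priority scores.

    Each SNP gets 1–3 candidate genes with priorities ~ Uniform(0, 1); the
    maximum-priority candidate is the SNP's "true" target gene used when
    planting association signal.
    """
    rows = []
    for j in range(config.n_snps):
        snp = f"rs{j + 1:07d}"
        n_cand = int(rng.integers(1, 4))
        genes = rng.choice(config.n_genes, size=n_cand, replace=False)
        priorities = rng.uniform(0.0, 1.0, size=n_cand)
        for gi, pr in zip(genes, priorities):
            rows.append((snp, _gene_id(int(gi)), float(pr)))
    return SnpGeneMap(
        rows=pd.DataFrame(rows, columns=["snp_id", "gene_id", "priority_score"])
    )


def _top_gene_per_snp(snp_map: SnpGeneMap) -> dict[str, str]:
    best: dict[str, tuple[float, str]] = {}
    for snp, gene, pr in snp_map.rows.itertuples(index=False):
        cur = best.get(snp)
        if cur is None or pr > cur[0] or (pr == cur[0] and gene < cur[1]):
            best[snp] = (pr, gene)
    return {s: g for s, (_, g) in best.items()}


def simulate_genotypes(
    config: SimulationConfig,
    snp_map: SnpGeneMap,
    pathways: PathwayCollection,
    rng: np.random.Generator,
) -> tuple[GenotypeDataset, GroundTruth]:
    """Genotype matrix with planted case/control allele-frequency shifts.

    SNPs whose top-priority gene belongs to a planted genomic pathway are
    "associated": controls keep base allele frequency f ~ Uniform(0.05, 0.5),
    cases get f + effect_delta (clamped).  A configured fraction of SNPs is
    labelled chromosome Y, another is degraded below the 95% call-rate
    threshold, and a third duplicates its left neighbour's genotypes to
    create r² = 1 pairs for the pruning stage to remove.
    """
    n = config.n_cases + config.n_controls
    n_snps = config.n_snps
    planted_genes: set[str] = set()
    module_genes: dict[str, frozenset] = {}
    for pid in config.planted_pathways_genomic:
        module_genes[pid] = pathways[pid].genes
        planted_genes |= set(pathways[pid].genes)

    top_gene = _top_gene_per_snp(snp_map)
    snp_ids = [f"rs{j + 1:07d}" for j in range(n_snps)]
    associated = np.array(
        [top_gene.get(s, "") in planted_genes for s in snp_ids]
    )
    if config.effect_delta == 0.0:
        associated[:] = False

    f_ctrl = rng.uniform(0.05, 0.5, size=n_snps)
    f_case = np.where(
        associated, np.clip(f_ctrl + config.effect_delta, 0.01, 0.99), f_ctrl
    )
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True
    freqs = np.where(is_case[:, None], f_case[None, :], f_ctrl[None, :])
    genotypes = rng.binomial(2, freqs).astype(float)

    # duplicated columns: perfect LD with the previous SNP
    n_dup = int(round(config.ld_dup_fraction * n_snps))
    dup_idx = rng.choice(np.arange(1, n_snps), size=n_dup, replace=False) if n_dup else []
    for j in dup_idx:
        genotypes[:, j] = genotypes[:, j - 1]

    # missingness: uniform background plus forced low-call SNPs
    if config.missing_rate > 0:
        genotypes[rng.random((n, n_snps)) < config.missing_rate] = np.nan
    n_low = int(round(config.low_call_fraction * n_snps))
    low_idx = rng.choice(n_snps, size=n_low, replace=False) if n_low else []
    for j in low_idx:
        drop = rng.random(n) < 0.10   # ~90% call rate, below the 95% filter
        genotypes[drop, j] = np.nan

    # chromosome labels: contiguous blocks over 1..22 (keeps duplicated
    # neighbours on the same chromosome for the pruning stage), plus Y
    chrom = np.array(
        [str(1 + (j * 22) // n_snps) for j in range(n_snps)], dtype=object
    )
    n_y = int(round(config.y_chrom_fraction * n_snps))
    y_idx = rng.choice(n_snps, size=n_y, replace=False) if n_y else []
    chrom[list(y_idx)] = "Y"
    # positions: increasing within chromosome; duplicated SNPs stay adjacent
    pos = np.zeros(n_snps, dtype=np.int64)
    counters: dict[str, int] = {}
    for j in range(n_snps):
        counters[chrom[j]] = counters.get(chrom[j], 0) + 1
        pos[j] = counters[chrom[j]] * 1000

    dataset = GenotypeDataset(
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        phenotypes=np.where(is_case, "case", "control").astype(object),
        snp_ids=snp_ids,
        chrom=chrom,
        pos=pos,
        genotypes=genotypes,
    )
    truth = GroundTruth(
        associated_snp_ids=frozenset(np.array(snp_ids)[associated]),
        active_module_genes=module_genes,
        enriched_pathways_genomic=frozenset(config.planted_pathways_genomic),
        enriched_pathways_proteomic=frozenset(config.planted_pathways_proteomic),
    )
    return dataset, truth


def simulate_protein_scores(
    config: SimulationConfig,
    pathways: PathwayCollection,
    rng: np.random.Generator,
) -> GeneScoreTable:
    """Proteomic p-value table: Beta(a, 1) on planted genes, uniform elsewhere."""
    signal_genes: set[str] = set()
    for pid in config.planted_pathways_proteomic:
        signal_genes |= set(pathways[pid].genes)
    entries = {}
    for i in range(config.n_genes):
        gene = _gene_id(i)
        if gene in signal_genes:
            p = rng.beta(config.signal_beta_shape, 1.0)
        else:
            p = rng.uniform(0.0, 1.0)
        entries[gene] = float(max(p, 1e-300))
    return GeneScoreTable(entries=entries, layer_label="proteomic")


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    ppi: PPINetwork
    pathways: PathwayCollection
    snp_gene_map: SnpGeneMap
    genotypes: GenotypeDataset
    protein_scores: GeneScoreTable
    truth: GroundTruth


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every pipeline input from one seeded config."""
    rng = np.random.default_rng(config.seed)
    ppi = simulate_ppi(config, rng)
    pathways = simulate_pathways(config, ppi, rng)
    planted = set(config.planted_pathways_genomic) | set(config.planted_pathways_proteomic)
    if planted:
        ppi = densify_planted_neighbourhoods(ppi, pathways, planted, rng)
    snp_map = simulate_snp_gene_map(config, rng)
    genotypes, truth = simulate_genotypes(config, snp_map, pathways, rng)
    proteins = simulate_protein_scores(config, pathways, rng)
    return SyntheticStudy(config, ppi, pathways, snp_map, genotypes, proteins, truth)
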