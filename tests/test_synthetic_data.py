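"""Generator determinism, planted-signal structure and null calibration."""

import networkx as nx
import numpy as np
import pytest

from pathnet.genome_assoc import genotypic_test
from pathnet.synthetic_data import (
    SimulationConfig,
    densify_planted_neighbourhoods,
    simulate_genotypes,
    simulate_pathways,
    simulate_ppi,
    simulate_protein_scores,
    simulate_snp_gene_map,
    simulate_study,
)


def small_config(**kw):
    defaults = dict(
        n_cases=20, n_controls=20, n_snps=300, n_genes=120, n_pathways=8,
        pathway_size_range=(8, 15),
        planted_pathways_genomic=("P0001",),
        planted_pathways_proteomic=("P0002",),
        effect_delta=0.3, signal_beta_shape=0.1, seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_snps=0),
            dict(signal_beta_shape=1.5),
            dict(effect_delta=0.7),
            dict(missing_rate=1.0),
            dict(pathway_size_range=(0, 5)),
            dict(pathway_size_range=(10, 500)),
            dict(ppi_mean_degree=400.0),
            dict(planted_pathways_genomic=("P9999",)),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestPpi:
    def test_seeded_determinism(self):
        cfg = small_config()
        a = simulate_ppi(cfg, np.random.default_rng(4))
        b = simulate_ppi(cfg, np.random.default_rng(4))
        assert a.edges == b.edges

    def test_connected_with_target_mean_degree(self):
        cfg = small_config(n_genes=200, ppi_mean_degree=4.0)
        ppi = simulate_ppi(cfg, np.random.default_rng(0))
        g = ppi.to_networkx()
        assert nx.is_connected(g)
        mean_deg = 2 * g.number_of_edges() / g.number_of_nodes()
        assert mean_deg == pytest.approx(4.0, abs=0.5)

    def test_two_genes_single_edge(self):
        cfg = small_config(n_genes=2, ppi_mean_degree=1.0,
                           pathway_size_range=(1, 2))
        ppi = simulate_ppi(cfg, np.random.default_rng(0))
        assert len(ppi.edges) == 1


class TestPathways:
    def test_sizes_within_range(self):
        cfg = small_config()
        rng = np.random.default_rng(2)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        lo, hi = cfg.pathway_size_range
        assert len(coll) == cfg.n_pathways
        for rec in coll:
            assert lo <= len(rec.genes) <= hi

    def test_planted_pathway_has_dominant_connected_component(self):
        """>=70% of a planted pathway's genes sit in one connected component
        of its induced PPI subgraph (checked by graph traversal)."""
        cfg = small_config()
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ppi = simulate_ppi(cfg, rng)
            coll = simulate_pathways(cfg, ppi, rng)
            g = ppi.to_networkx()
            for pid in ("P0001", "P0002"):
                genes = coll[pid].genes
                sub = g.subgraph(genes)
                largest = max(nx.connected_components(sub), key=len)
                assert len(largest) / len(genes) >= 0.7

    def test_seeded_determinism(self):
        cfg = small_config()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            ppi = simulate_ppi(cfg, rng)
            out.append(simulate_pathways(cfg, ppi, rng))
        assert [(r.pathway_id, r.genes) for r in out[0]] == [
            (r.pathway_id, r.genes) for r in out[1]
        ]

    def test_densification_preserves_nodes_and_adds_internal_edges(self):
        cfg = small_config()
        rng = np.random.default_rng(3)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        dense = densify_planted_neighbourhoods(ppi, coll, ["P0001"], rng)
        assert dense.nodes == ppi.nodes
        assert ppi.edges <= dense.edges
        genes = coll["P0001"].genes
        before = ppi.to_networkx().subgraph(genes).number_of_edges()
        after = dense.to_networkx().subgraph(genes).number_of_edges()
        assert after >= before


class TestGenotypes:
    def test_null_delta_zero_flags_no_snps(self):
        cfg = small_config(effect_delta=0.0)
        rng = np.random.default_rng(5)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        snp_map = simulate_snp_gene_map(cfg, rng)
        ds, truth = simulate_genotypes(cfg, snp_map, coll, rng)
        assert truth.associated_snp_ids == frozenset()
        # empirical case/control allele-frequency difference ~0 on average
        case = ds.genotypes[ds.is_case]
        ctrl = ds.genotypes[~ds.is_case]
        diff = np.nanmean(case, axis=0) / 2 - np.nanmean(ctrl, axis=0) / 2
        assert abs(np.nanmean(diff)) < 0.02

    def test_no_missing_when_rate_zero(self):
        cfg = small_config(missing_rate=0.0, low_call_fraction=0.0)
        rng = np.random.default_rng(6)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        snp_map = simulate_snp_gene_map(cfg, rng)
        ds, _ = simulate_genotypes(cfg, snp_map, coll, rng)
        assert not np.isnan(ds.genotypes).any()

    def test_planted_snps_detectable_at_large_n(self):
        """With delta=0.3 and 500 per group, planted SNPs have median p < 1e-4."""
        cfg = small_config(
            n_cases=500, n_controls=500, n_snps=400, effect_delta=0.3,
            missing_rate=0.0, low_call_fraction=0.0, y_chrom_fraction=0.0,
        )
        rng = np.random.default_rng(7)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        snp_map = simulate_snp_gene_map(cfg, rng)
        ds, truth = simulate_genotypes(cfg, snp_map, coll, rng)
        assert truth.associated_snp_ids
        pmap = {r.snp_id: r.p_value for r in genotypic_test(ds)}
        planted_p = [pmap[s] for s in truth.associated_snp_ids]
        assert np.median(planted_p) < 1e-4

    def test_structure_fractions(self):
        cfg = small_config()
        rng = np.random.default_rng(8)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        snp_map = simulate_snp_gene_map(cfg, rng)
        ds, _ = simulate_genotypes(cfg, snp_map, coll, rng)
        y_frac = ds.is_y_chrom().mean()
        assert y_frac == pytest.approx(cfg.y_chrom_fraction, abs=0.01)
        call = 1 - np.isnan(ds.genotypes).mean(axis=0)
        assert (call < 0.95).mean() >= cfg.low_call_fraction * 0.5


class TestProteinScores:
    def test_degenerate_shape_one_is_uniform(self):
        cfg = small_config(signal_beta_shape=1.0)
        rng = np.random.default_rng(9)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        table = simulate_protein_scores(cfg, coll, rng)
        signal = [table.entries[g] for g in coll["P0002"].genes]
        # Beta(1,1) == Uniform: mean of signal p's near 0.5
        assert np.mean(signal) == pytest.approx(0.5, abs=0.25)

    def test_signal_mean_matches_beta_expectation(self):
        """Beta(0.1, 1) has mean a/(a+1) ~ 0.0909; signal mean p < 0.2."""
        cfg = small_config(signal_beta_shape=0.1, n_genes=300,
                           pathway_size_range=(30, 40), n_pathways=4,
                           planted_pathways_proteomic=("P0002",),
                           planted_pathways_genomic=())
        rng = np.random.default_rng(10)
        ppi = simulate_ppi(cfg, rng)
        coll = simulate_pathways(cfg, ppi, rng)
        table = simulate_protein_scores(cfg, coll, rng)
        signal = [table.entries[g] for g in coll["P0002"].genes]
        assert np.mean(signal) < 0.2

    def test_seeded_determinism(self):
        cfg = small_config()
        tables = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            ppi = simulate_ppi(cfg, rng)
            coll = simulate_pathways(cfg, ppi, rng)
            tables.append(simulate_protein_scores(cfg, coll, rng))
        assert tables[0].entries == tables[1].entries


class TestStudy:
    def test_end_to_end_determinism(self):
        cfg = small_config()
        a, b = simulate_study(cfg), simulate_study(cfg)
        assert a.ppi.edges == b.ppi.edges
        np.testing.assert_array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        assert a.protein_scores.entries == b.protein_scores.entries
        assert a.truth.associated_snp_ids == b.truth.associated_snp_ids

    def test_null_genotypic_pvalues_uniform(self):
        """No planted signal: association p-values are ~Uniform(0,1) (KS)."""
        from scipy import stats

        cfg = small_config(
            n_cases=250, n_controls=250, n_snps=2000, effect_delta=0.0,
            missing_rate=0.0, low_call_fraction=0.0, y_chrom_fraction=0.0,
            ld_dup_fraction=0.0,
        )
        study = simulate_study(cfg)
        pvals = [r.p_value for r in genotypic_test(study.genotypes)]
        # 250 per group keeps the chi-square approximation accurate enough
        # for a literal uniformity test (small groups leave visible
        # discreteness in the 2x3 tables)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_ground_truth_shared_is_intersection(self):
        cfg = small_config(
            planted_pathways_genomic=("P0001", "P0003"),
            planted_pathways_proteomic=("P0003", "P0004"),
        )
        study = simulate_study(cfg)
        assert study.truth.shared_pathway_ids == frozenset({"P0003"})
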