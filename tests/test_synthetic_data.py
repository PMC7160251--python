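"""Forward-model generators: structure, LD, architectures, expression."""

import numpy as np
import pandas as pd
import pytest

from acidarch import phenotype_stats as phs
from acidarch.datatypes import ConfigurationError
from acidarch.population_structure import kinship_matrix
from acidarch.synthetic_data import (
    ArchitectureConfig,
    PopulationConfig,
    simulate_expression,
    simulate_gene_annotation,
    simulate_phenotypes,
    simulate_population,
    simulate_promoter_alignment,
)


class TestPopulationConfig:
    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("n_subpops", 0, "n_subpops"),
            ("missing_rate", 1.0, "missing_rate"),
            ("divergence", 1.0, "divergence"),
            ("snp_spacing", 0, "snp_spacing"),
        ],
    )
    def test_invalid_fields_named_in_error(self, field, value, match):
        cfg = PopulationConfig(**{field: value})
        with pytest.raises(ConfigurationError, match=match):
            cfg.validate()

    def test_positions_strictly_increasing_per_chromosome(self):
        G, _ = simulate_population(PopulationConfig(n_accessions=10, n_snps=500, seed=0))
        for _, sub in G.snpmap.groupby("chrom"):
            assert (np.diff(sub["pos"]) > 0).all()


class TestSimulatePopulation:
    def test_unstructured_limit_has_no_kinship_structure(self, unstructured_panel):
        G, true_q = unstructured_panel
        assert true_q.shape[1] == 1
        K = kinship_matrix(G).to_numpy()
        off = K[~np.eye(K.shape[0], dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_dosages_are_binary_with_missing(self):
        cfg = PopulationConfig(n_accessions=40, n_snps=800, missing_rate=0.1, seed=5)
        G, _ = simulate_population(cfg)
        vals = G.values()
        miss = np.isnan(vals)
        assert 0.05 < miss.mean() < 0.15
        assert set(np.unique(vals[~miss])) <= {0.0, 1.0}

    def test_true_q_rows_sum_to_one(self, two_pop_panel):
        _, true_q = two_pop_panel
        np.testing.assert_allclose(true_q.sum(axis=1), 1.0, atol=1e-12)

    def test_adjacent_ld_exceeds_background(self):
        # blocks much longer than spacing -> strong local correlation
        cfg = PopulationConfig(
            n_accessions=100, n_snps=2000, ld_block_length=12000,
            snp_spacing=400, missing_rate=0.0, seed=23,
        )
        G, _ = simulate_population(cfg)
        X = G.values()
        def r2(a, b):
            return np.corrcoef(X[:, a], X[:, b])[0, 1] ** 2
        poly = np.flatnonzero(X.std(axis=0) > 0)
        adjacent = [r2(j, j + 1) for j in poly[:-1] if j + 1 in set(poly)][:500]
        rng = np.random.default_rng(0)
        far = [r2(a, b) for a, b in zip(rng.choice(poly[:800], 300), rng.choice(poly[-800:], 300))]
        assert np.median(adjacent) > np.median(far) + 0.1


class TestSimulatePhenotypes:
    def test_noiseless_limit_gives_h2_one(self, two_pop_panel):
        G, _ = two_pop_panel
        arch = ArchitectureConfig.oligogenic_rare(
            heritability=1.0, rare_lof_count=0, seed=3
        )
        pheno, _ = simulate_phenotypes(G, arch)
        tab = phs.rrl_table(pheno, stress="stress")
        assert phs.trait_summary(tab).h_b2 == pytest.approx(1.0, abs=1e-6)

    def test_effect_fractions_capped_by_heritability(self, two_pop_panel):
        G, _ = two_pop_panel
        arch = ArchitectureConfig.oligogenic_rare(
            heritability=0.5, qtl_effect_fractions=(0.4, 0.2), n_qtl=2, seed=1
        )
        with pytest.raises(ConfigurationError, match="exceeds heritability"):
            simulate_phenotypes(G, arch)

    def test_h2_recovery_on_preset(self, two_pop_panel):
        """One-way ANOVA repeatability recovers the simulated value."""
        G, _ = two_pop_panel
        arch = ArchitectureConfig.oligogenic_rare(heritability=0.75, seed=9)
        pheno, _ = simulate_phenotypes(G, arch)
        tab = phs.rrl_table(pheno, stress="stress")
        assert phs.trait_summary(tab).h_b2 == pytest.approx(0.75, abs=0.1)

    def test_rare_carrier_latent_scaled_by_multiplier(self, two_pop_panel):
        G, _ = two_pop_panel
        base = ArchitectureConfig.oligogenic_rare(rare_lof_count=0, seed=7)
        with_lof = ArchitectureConfig.oligogenic_rare(rare_lof_count=3, seed=7)
        _, truth0 = simulate_phenotypes(G, base)
        _, truth1 = simulate_phenotypes(G, with_lof)
        carriers = truth1.rare_carrier_ids
        assert len(carriers) == 3
        ratio = truth1.latent_rrl.loc[carriers] / truth0.latent_rrl.loc[carriers]
        np.testing.assert_allclose(ratio, 0.39, rtol=1e-9)
        others = truth1.latent_rrl.drop(carriers)
        pd.testing.assert_series_equal(others, truth0.latent_rrl.drop(carriers))

    def test_voeran_like_scenario_difference_rate(self):
        """A loss-of-function multiplier of 0.39 produces the observed-6.6 /
        predicted-16.9 style gap: log2(0.39) ~ -1.36."""
        assert np.log2(0.39) == pytest.approx(-1.36, abs=0.01)

    def test_truth_records_qtls_present_in_panel(self, oligo_panel):
        G, _, _, truth = oligo_panel
        assert set(truth.qtl_snp_ids) <= set(G.snp_ids)
        assert len(truth.qtl_effects) == len(truth.qtl_snp_ids)


class TestSimulateExpression:
    def test_zero_noise_separates_allele_groups(self, two_pop_panel):
        G, _ = two_pop_panel
        snp = G.snp_ids[10]
        expr = simulate_expression(G, snp, effect=2.0, noise_sd=0.0, seed=0)
        x = G.dosage[snp]
        assert expr[x == 1].min() > expr[x == 0].max()

    def test_unknown_cis_snp_rejected(self, two_pop_panel):
        G, _ = two_pop_panel
        with pytest.raises(ConfigurationError, match="not in the SNP map"):
            simulate_expression(G, "Chr9_123", effect=1.0, noise_sd=0.1)

    def test_null_effect_p_values_uniform(self, unstructured_panel):
        """Null calibration: ELP p-values vs a cis SNP with zero effect are
        uniform (KS test not rejected at 0.01)."""
        from scipy import stats

        from acidarch.association import allele_expression_test

        G, _ = unstructured_panel
        maf = G.maf()
        snps = list(G.snp_ids[(maf >= 0.2).to_numpy()][:250])
        pvals = []
        for i, snp in enumerate(snps):
            expr = simulate_expression(G, snp, effect=0.0, noise_sd=1.0, seed=1000 + i)
            pvals.append(allele_expression_test(expr, G.dosage[snp]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestGeneAnnotation:
    def test_models_do_not_overlap_and_cover_snps(self, two_pop_panel):
        G, _ = two_pop_panel
        ann = simulate_gene_annotation(G.snpmap, seed=2)
        for chrom, sub in ann.table.groupby("chrom"):
            starts = sub["utr5_start"].combine(sub["utr3_start"], min)
            ends = sub["utr5_end"].combine(sub["utr3_end"], max)
            order = np.argsort(starts)
            assert (starts.to_numpy()[order][1:] > ends.to_numpy()[order][:-1]).all()
            assert ann.chrom_lengths[chrom] >= G.snpmap[G.snpmap["chrom"] == chrom]["pos"].max()

    def test_snp_upstream_of_utr5_lands_in_one_promoter(self, two_pop_panel):
        from acidarch.candidate_genes import gene_models

        G, _ = two_pop_panel
        ann = simulate_gene_annotation(G.snpmap, seed=2)
        models = gene_models(ann)
        row = ann.table[ann.table["strand"] == "+"].iloc[3]
        pos = int(row["utr5_start"]) - 1000  # 1 kb upstream of the 5'UTR end
        inside = [
            m.gene_id
            for m in models.values()
            if m.chrom == row["chrom"] and m.promoter_interval[0] <= pos <= m.promoter_interval[1]
        ]
        assert inside == [row.name]


def test_promoter_alignment_truth_matches_major_haplotypes():
    records, truth = simulate_promoter_alignment(seed=4)
    assert len(records) == 46
    lengths = {len(s) for _, s in records}
    assert len(lengths) == 1  # aligned
    major = [h for h in set(truth.values()) if not h.startswith("minor")]
    assert len(major) == 4
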