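"""Mixed-model scan, GLM scan, SNP filtering and ELP allele tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from acidarch import association as assoc
from acidarch import population_structure as ps
from acidarch.datatypes import Genotypes
from tests.conftest import toy_genotypes


class TestFilterSnps:
    @staticmethod
    def _toy_panel():
        """100 SNPs: 7 fail MAF (1 of them also fails missingness), 4 fail
        missingness -> 90 survive. Counts enumerated by construction."""
        rng = np.random.default_rng(12)
        n = 40
        dosage = (rng.random((n, 100)) < 0.5).astype(float)
        # SNPs 0..6: MAF below 5% (one minor allele among 40 accessions)
        for j in range(7):
            dosage[:, j] = 0.0
            dosage[0, j] = 1.0
        # SNPs 6..9: missingness above 5% (3 missing of 40); SNP 6 fails both
        for j in range(6, 10):
            dosage[1:4, j] = np.nan
        return toy_genotypes(dosage)

    def test_joint_filter_count_by_enumeration(self):
        G = self._toy_panel()
        kept = assoc.filter_snps(G)
        assert kept.n_snps == 90

    def test_maf_boundary_retained(self):
        # exactly 5% minor allele frequency: 2 of 40
        dosage = np.zeros((40, 3))
        dosage[:2, 0] = 1.0  # MAF 0.05 exactly
        dosage[:1, 1] = 1.0  # MAF 0.025: dropped
        dosage[:20, 2] = 1.0
        G = toy_genotypes(dosage)
        kept = assoc.filter_snps(G)
        assert list(kept.snp_ids) == [G.snp_ids[0], G.snp_ids[2]]

    def test_monomorphic_always_removed(self):
        dosage = np.zeros((30, 2))
        dosage[:15, 1] = 1.0
        kept = assoc.filter_snps(toy_genotypes(dosage))
        assert list(kept.snp_ids) == [kept.snp_ids[0]]
        assert kept.n_snps == 1

    def test_empty_result_warns(self):
        dosage = np.zeros((30, 2))
        with pytest.warns(UserWarning, match="every SNP"):
            assoc.filter_snps(toy_genotypes(dosage))


class TestMlmScan:
    def test_identity_kinship_equals_simple_regression(self, unstructured_panel):
        """Degenerate mixed model: kinship = I, intercept only -> exact OLS."""
        G, _ = unstructured_panel
        sub = G.subset_snps(G.snp_ids[:60])
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(50, 8, size=sub.n_accessions), index=sub.accessions)
        res = assoc.mlm_scan(sub, y)
        for snp in sub.snp_ids[:25]:
            x = sub.dosage[snp]
            if x.std() == 0:
                continue
            oracle = stats.linregress(x, y).pvalue
            mine = res.loc[snp, "p_value"]
            assert abs(mine - oracle) / oracle < 1e-8

    def test_glm_equals_mlm_with_identity_kinship(self, unstructured_panel):
        G, _ = unstructured_panel
        sub = G.subset_snps(G.snp_ids[:40])
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(0, 1, size=sub.n_accessions), index=sub.accessions)
        a = assoc.mlm_scan(sub, y)
        b = assoc.glm_scan(sub, y)
        np.testing.assert_allclose(a["p_value"], b["p_value"], rtol=1e-12)
        assert (b["model"] == "GLM").all()

    def test_exact_linear_trait_ranks_causal_snp_first(self):
        # unlinked SNPs so the floor-level p is unique to the causal one
        rng = np.random.default_rng(14)
        sub = toy_genotypes((rng.random((60, 50)) < 0.4).astype(float))
        causal = sub.snp_ids[7]
        y = 10.0 + 5.0 * sub.dosage[causal]
        res = assoc.glm_scan(sub, y)
        assert res["p_value"].idxmin() == causal
        assert res.loc[causal, "p_value"] <= np.finfo(float).tiny * 10

    def test_accession_permutation_invariance(self, two_pop_panel):
        G, true_q = two_pop_panel
        sub = G.subset_snps(G.snp_ids[:50])
        K = ps.kinship_matrix(G)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(50, 5, size=sub.n_accessions), index=sub.accessions)
        base = assoc.mlm_scan(sub, y, Q=true_q, kinship=K)
        perm = rng.permutation(sub.n_accessions)
        order = sub.accessions[perm]
        sub_p = Genotypes(sub.dosage.loc[order], sub.snpmap)
        shuffled = assoc.mlm_scan(
            sub_p, y.loc[order], Q=true_q.loc[order], kinship=K.loc[order, order]
        )
        # eigendecomposition of the permuted kinship is not bitwise
        # permutation-equivariant; agreement is to numerical precision
        np.testing.assert_allclose(
            base["p_value"], shuffled["p_value"], rtol=0, atol=1e-6
        )

    def test_missing_genotypes_dropped_casewise(self, unstructured_panel):
        G, _ = unstructured_panel
        sub = G.subset_snps(G.snp_ids[(G.maf() >= 0.3).to_numpy()][:10])
        dosage = sub.dosage.copy()
        dosage.iloc[0:5, 3] = np.nan
        holey = Genotypes(dosage, sub.snpmap)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(50, 5, size=sub.n_accessions), index=sub.accessions)
        res = assoc.mlm_scan(holey, y)
        # oracle: plain regression on the called subset
        x = dosage.iloc[:, 3].dropna()
        oracle = stats.linregress(x, y.loc[x.index]).pvalue
        snp = holey.snp_ids[3]
        assert res.loc[snp, "n_called"] == sub.n_accessions - 5
        assert res.loc[snp, "p_value"] == pytest.approx(oracle, rel=1e-8)

    def test_constant_phenotype_rejected(self, unstructured_panel):
        G, _ = unstructured_panel
        y = pd.Series(1.0, index=G.accessions)
        with pytest.raises(ValueError, match="constant"):
            assoc.mlm_scan(G.subset_snps(G.snp_ids[:5]), y)

    def test_structured_null_mlm_calibrated_naive_inflated(self, two_pop_panel):
        """The mixed model's purpose: on a structured null trait drawn from
        the kinship covariance, MLM p-values stay calibrated while naive
        regression inflates."""
        G, true_q = two_pop_panel
        K = ps.kinship_matrix(G)
        rng = np.random.default_rng(6)
        Km = K.to_numpy() + 1e-6 * np.eye(G.n_accessions)
        u = np.linalg.cholesky(Km) @ rng.normal(size=G.n_accessions)
        y = pd.Series(
            10 * u + rng.normal(scale=1.0, size=G.n_accessions), index=G.accessions
        )
        mlm = assoc.mlm_scan(G, y, Q=true_q, kinship=K)["p_value"].dropna()
        glm = assoc.glm_scan(G, y)["p_value"].dropna()
        assert (mlm < 0.05).mean() < 0.08
        assert (glm < 0.05).mean() > 0.12


class TestAlleleExpressionTest:
    @staticmethod
    def _groups(n0, n1, shift, seed=0):
        rng = np.random.default_rng(seed)
        expr = pd.Series(
            np.concatenate([rng.normal(0, 1, n0), rng.normal(shift, 1, n1)])
        )
        g = pd.Series([0.0] * n0 + [1.0] * n1)
        return expr, g

    def test_matches_pooled_t_test(self):
        expr, g = self._groups(8, 17, shift=1.0, seed=1)
        mine = assoc.allele_expression_test(expr, g)
        oracle = stats.ttest_ind(expr[g == 1], expr[g == 0], equal_var=True).pvalue
        assert mine == pytest.approx(oracle, rel=1e-10)

    def test_identical_groups_give_p_one(self):
        expr = pd.Series([1.0, 2.0, 3.0] * 4)
        g = pd.Series([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        # construct exactly equal group means
        expr = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert assoc.allele_expression_test(expr, g) >= 0.999

    def test_low_maf_refused(self):
        expr, g = self._groups(19, 1, shift=0.0)
        with pytest.raises(ValueError, match="refused"):
            assoc.allele_expression_test(expr, g)

    def test_empty_class_rejected(self):
        expr = pd.Series(np.arange(10.0))
        g = pd.Series([0.0] * 10)
        with pytest.raises(ValueError):
            assoc.allele_expression_test(expr, g, maf_min=0.0)

    def test_power_with_unbalanced_groups(self):
        """Simulation oracle: effect = 1 sd with groups of 8 vs 17 has power
        around 0.6-0.75 at alpha = 0.05."""
        hits = 0
        n_reps = 1000
        for rep in range(n_reps):
            expr, g = self._groups(17, 8, shift=1.0, seed=rep)
            if assoc.allele_expression_test(expr, g) < 0.05:
                hits += 1
        assert 0.57 <= hits / n_reps <= 0.78


def test_egwas_top_hit_is_cis_locus(unstructured_panel):
    """A simulated cis-regulated transcript maps back to its own locus."""
    from acidarch.synthetic_data import simulate_expression

    G, _ = unstructured_panel
    maf = G.maf()
    cis = G.snp_ids[(maf >= 0.3).to_numpy()][5]
    expr = simulate_expression(G, cis, effect=2.0, noise_sd=1.0, seed=9)
    res = assoc.glm_scan(G, expr)
    top = res["p_value"].idxmin()
    cis_pos = G.snpmap.loc[cis, "pos"]
    top_row = G.snpmap.loc[top]
    assert top_row["chrom"] == G.snpmap.loc[cis, "chrom"]
    assert abs(top_row["pos"] - cis_pos) <= 12000  # same LD block
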