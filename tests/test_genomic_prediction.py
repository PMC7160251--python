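"""Top-SNP ridge prediction: imputation, ranking, CV curves, outliers."""

import numpy as np
import pandas as pd
import pytest

from acidarch import genomic_prediction as gp
from acidarch.datatypes import Genotypes
from tests.conftest import toy_genotypes


class TestImputeMissing:
    def test_complete_input_unchanged(self, unstructured_panel):
        G, _ = unstructured_panel
        out = gp.impute_missing(G)
        pd.testing.assert_frame_equal(out.dosage, G.dosage)

    def test_mode_fill(self):
        col = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, np.nan, np.nan, np.nan]
        G = toy_genotypes(np.column_stack([col, np.tile([0, 1], 5)]))
        out = gp.impute_missing(G)
        filled = out.dosage.iloc[7:, 0]
        assert (filled == 1.0).all()
        # called entries untouched
        assert out.dosage.iloc[6, 0] == 0.0

    def test_fully_missing_snp_rejected(self):
        arr = np.tile([0.0, 1.0], (6, 1))
        arr = np.column_stack([arr, np.full(6, np.nan)])
        with pytest.raises(ValueError, match="fully missing"):
            gp.impute_missing(toy_genotypes(arr))


class TestRankSnps:
    @staticmethod
    def _assoc(pvals, chroms=None, positions=None):
        m = len(pvals)
        return pd.DataFrame(
            {
                "p_value": pvals,
                "chrom": chroms or [1] * m,
                "pos": positions or list(range(100, 100 + m)),
            },
            index=pd.Index([f"s{i}" for i in range(m)], name="snp_id"),
        )

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        tab = self._assoc(list(p))
        expected = list(tab.sort_values("p_value").index)
        assert gp.rank_snps(tab) == expected

    def test_ties_broken_by_genomic_coordinate(self):
        tab = self._assoc([0.5, 0.1, 0.1], chroms=[1, 2, 1], positions=[10, 5, 7])
        assert gp.rank_snps(tab) == ["s2", "s1", "s0"]

    def test_deterministic_across_repeat_runs(self):
        rng = np.random.default_rng(1)
        p = list(np.round(rng.random(200), 2))  # many ties
        tab = self._assoc(p)
        assert gp.rank_snps(tab) == gp.rank_snps(tab.copy())

    def test_missing_p_rejected(self):
        tab = self._assoc([0.1, np.nan])
        with pytest.raises(ValueError, match="missing"):
            gp.rank_snps(tab)


class TestRidgeOracle:
    def test_closed_form_on_small_instance(self):
        """Ridge via the SVD path equals (X'X + aI)^-1 X'y on 10 x 8."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 8))
        y = rng.normal(size=10)
        alpha = 2.5
        xm, ym = X.mean(0), y.mean()
        Xc = X - xm
        b_direct = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(8), Xc.T @ (y - ym))
        b_mine, b0 = gp.ridge_solve(X, y, alpha)
        np.testing.assert_allclose(b_mine, b_direct, atol=1e-10)
        pred_path = gp._svd_ridge_paths(X, y, X, [alpha])[0]
        np.testing.assert_allclose(pred_path, X @ b_mine + b0, atol=1e-8)

    def test_agrees_with_sklearn(self):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        alpha = 0.7
        sk = Ridge(alpha=alpha).fit(X, y)
        b, b0 = gp.ridge_solve(X, y, alpha)
        np.testing.assert_allclose(b, sk.coef_, atol=1e-8)
        assert b0 == pytest.approx(sk.intercept_, abs=1e-8)


@pytest.fixture(scope="module")
def noiseless_qtl_panel():
    """Noiseless trait from exactly 40 QTLs; ranking lists them first."""
    rng = np.random.default_rng(21)
    n, m = 120, 400
    dosage = (rng.random((n, m)) < rng.uniform(0.15, 0.5, size=m)).astype(float)
    G = toy_genotypes(dosage)
    qtl_cols = list(G.snp_ids[:40])
    effects = rng.normal(1.0, 0.3, size=40)
    y = pd.Series(
        50.0 + (dosage[:, :40] - dosage[:, :40].mean(0)) @ effects, index=G.accessions
    )
    ranking = qtl_cols + [s for s in G.snp_ids if s not in qtl_cols]
    return G, y, ranking


class TestGPCurve:
    def test_noiseless_qtl_curve_saturates(self, noiseless_qtl_panel):
        G, y, ranking = noiseless_qtl_panel
        curve = gp.gp_curve(
            G, y, ranking, k_grid=[20, 40, 60], n_reps=5, seed=3, reference=False
        )
        r2 = curve.table["r2_mean"]
        assert r2.loc[40] > 0.95 and r2.loc[60] > 0.95
        assert r2.loc[40] - r2.loc[20] > 0.05  # steep rise to saturation

    def test_null_trait_has_no_signal(self):
        """Pure-noise trait on unlinked SNPs: r2 stays below 0.05 at n=200."""
        rng = np.random.default_rng(9)
        n, m = 200, 400
        dosage = (rng.random((n, m)) < 0.4).astype(float)
        G = toy_genotypes(dosage)
        y = pd.Series(rng.normal(0, 1, n), index=G.accessions)
        ranking = list(G.snp_ids)
        curve = gp.gp_curve(
            G, y, ranking, k_grid=[20, 40], n_reps=5, seed=4, reference=False
        )
        assert (curve.table["r2_mean"] < 0.05).all()

    def test_reference_curve_below_top_snp_curve(self, noiseless_qtl_panel):
        G, y, ranking = noiseless_qtl_panel
        curve = gp.gp_curve(
            G, y, ranking, k_grid=[40], n_reps=5, seed=5, reference=True
        )
        row = curve.table.loc[40]
        assert row["reference_r2"] <= row["r2_mean"]

    def test_identical_seed_reproducible(self, noiseless_qtl_panel):
        G, y, ranking = noiseless_qtl_panel
        a = gp.gp_curve(G, y, ranking, k_grid=[20], n_reps=3, seed=6, reference=False)
        b = gp.gp_curve(G, y, ranking, k_grid=[20], n_reps=3, seed=6, reference=False)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_invalid_grid_rejected(self, noiseless_qtl_panel):
        G, y, ranking = noiseless_qtl_panel
        with pytest.raises(ValueError, match="ranking covers"):
            gp.gp_curve(G, y, ranking[:10], k_grid=[20], n_reps=2, seed=0)


class TestSelectK:
    @staticmethod
    def _curve(r2_means, sds=None):
        ks = list(range(20, 20 * len(r2_means) + 1, 20))
        tab = pd.DataFrame(
            {
                "r2_mean": r2_means,
                "r2_sd": sds if sds is not None else [0.01] * len(r2_means),
                "rmse_mean": 5.0,
                "rmse_sd": 0.1,
                "reference_r2": 0.05,
            },
            index=pd.Index(ks, name="k"),
        )
        return gp.GPCurve(tab, 5, 10, 0)

    def test_peak_before_plateau_selected(self):
        # rises to a strict max at k = 140 then stays flat
        r2 = [0.3, 0.45, 0.55, 0.62, 0.67, 0.70, 0.75, 0.75, 0.75, 0.75]
        eff = gp.select_k(self._curve(r2))
        assert eff.k_selected == 140
        assert not eff.no_plateau

    def test_strictly_increasing_with_zero_sd_flags_no_plateau(self):
        r2 = list(np.linspace(0.2, 0.8, 8))
        eff = gp.select_k(self._curve(r2, sds=[0.0] * 8))
        assert eff.k_selected == 160
        assert eff.no_plateau

    def test_flat_curve_selects_smallest_k(self):
        eff = gp.select_k(self._curve([0.5] * 6))
        assert eff.k_selected == 20

    def test_p_cutoff_is_worst_selected_p(self):
        r2 = [0.3, 0.7, 0.7, 0.7]
        ranking = [f"s{i}" for i in range(80)]
        assoc = pd.DataFrame(
            {"p_value": np.linspace(1e-6, 1e-3, 80)},
            index=pd.Index(ranking, name="snp_id"),
        )
        eff = gp.select_k(self._curve(r2), ranking, assoc)
        assert eff.k_selected == 40
        assert eff.p_cutoff == pytest.approx(assoc["p_value"].iloc[39])
        assert len(eff.snp_ids) == 40


class TestPredictions:
    def test_difference_rate_identities(self):
        assert gp.difference_rate(10.0, 10.0) == 0.0
        assert gp.difference_rate(20.0, 10.0) == 1.0
        assert np.isnan(gp.difference_rate(-1.0, 10.0))
        assert np.isnan(gp.difference_rate(10.0, 0.0))

    def test_worked_example_matches_published_rate(self):
        """Observed 6.6% vs predicted 16.9% -> difference rate -1.36, the
        hypersensitive-accession flag."""
        rate = gp.difference_rate(6.6, 16.9)
        assert rate == pytest.approx(np.log2(6.6 / 16.9), rel=1e-12)
        assert abs(rate - (-1.35)) <= 0.02
        assert abs(rate) >= 0.5  # flagged unusual

    def test_predictions_reproducible_and_flagging_consistent(
        self, noiseless_qtl_panel
    ):
        G, y, ranking = noiseless_qtl_panel
        a = gp.predict_accessions(G, y, ranking, 40, n_reps=4, seed=11)
        b = gp.predict_accessions(G, y, ranking, 40, n_reps=4, seed=11)
        pd.testing.assert_frame_equal(a, b)
        flagged = a["unusual"]
        recomputed = a["difference_rate"].abs() >= 0.5
        assert (flagged == recomputed.fillna(False)).all()
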