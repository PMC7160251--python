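"""Genomic prediction on top-ranked GWAS SNPs and difference-rate outliers.

Ridge regression is fitted on the dosages of the k top-ranked GWAS SNPs for
k on a grid (20-300 by 20), with repeated 5-fold cross-validation (100
replicates). Predictive ability is the squared Pearson correlation (r2)
between assembled out-of-fold predictions and observations, and RMSE on the
same pairs; a random-SNP curve computed identically serves as the
reference. The effective SNP set is the smallest k whose mean r2 comes
within one standard deviation of the curve's global maximum ("highest
before plateau"), and the GWAS p-value of its worst member defines the
study's significance cutoff. Per-accession predictions at the selected k
give the difference rate log2(observed RRL / predicted RRL); accessions
with |rate| >= 0.5 carry phenotypes the common-variant model cannot
explain — the rare-allele signature.

The ridge penalty is chosen by inner 5-fold selection over a log-spaced
grid within each training split (no information leakage into the held-out
fold). SNP ranking is computed once on the full data, exactly as the
two-stage GWAS-then-GP procedure implies; the optimism this induces is
inherent to the reproduced method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Genotypes

__all__ = [
    "GPCurve",
    "EffectiveSet",
    "impute_missing",
    "rank_snps",
    "gp_curve",
    "select_k",
    "predict_accessions",
    "difference_rate",
    "ridge_solve",
    "DEFAULT_K_GRID",
    "DEFAULT_ALPHAS",
]

DEFAULT_K_GRID = tuple(range(20, 301, 20))
DEFAULT_ALPHAS = tuple(np.logspace(-3, 3, 13))


@dataclass
class GPCurve:
    table: pd.DataFrame  # index k; columns r2_mean, r2_sd, rmse_mean, rmse_sd, reference_r2
    n_folds: int
    n_reps: int
    seed: int


@dataclass
class EffectiveSet:
    k_selected: int
    snp_ids: list
    p_cutoff: float | None
    r2_at_k: float
    no_plateau: bool = False


def impute_missing(G: Genotypes) -> Genotypes:
    """Per-SNP mode imputation (inbred haploid coding needs no phasing).

    Non-missing entries are unchanged; a fully missing SNP is an error.
    Ties (allele frequency exactly 0.5 among called) impute the reference
    (0) allele, a documented deterministic choice.
    """
    X = G.values()
    n_called = (~np.isnan(X)).sum(axis=0)
    if (n_called == 0).any():
        bad = G.snp_ids[n_called == 0][0]
        raise ValueError(f"SNP {bad} is fully missing; cannot impute")
    freq = np.nanmean(X, axis=0)
    mode = (freq > 0.5).astype(float)
    X = np.where(np.isnan(X), mode[None, :], X)
    return Genotypes(pd.DataFrame(X, index=G.accessions, columns=G.snp_ids), G.snpmap)


def rank_snps(assoc: pd.DataFrame) -> list:
    """SNP ids by ascending GWAS p-value; ties broken by (chrom, pos)."""
    tab = assoc.reset_index() if "snp_id" not in assoc.columns else assoc.copy()
    if tab["p_value"].isna().any():
        raise ValueError("p-values missing for some SNPs; cannot rank")
    tab = tab.sort_values(["p_value", "chrom", "pos"], kind="mergesort")
    return list(tab["snp_id"])


def ridge_solve(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple:
    """Closed-form centered ridge: returns (coef, intercept).

    Solves (Xc' Xc + alpha I) b = Xc' yc on column-centered data; the
    intercept absorbs the means (standard glmnet-style parameterization
    without predictor rescaling).
    """
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    b = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(X.shape[1]), Xc.T @ (y - ym))
    return b, float(ym - xm @ b)


def _svd_ridge_paths(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, alphas) -> np.ndarray:
    """Test-set predictions for every alpha from one SVD of the training X."""
    xm = Xtr.mean(axis=0)
    ym = ytr.mean()
    U, s, Vt = np.linalg.svd(Xtr - xm, full_matrices=False)
    uty = U.T @ (ytr - ym)
    M = (Xte - xm) @ Vt.T  # (n_te, r)
    preds = np.empty((len(alphas), Xte.shape[0]))
    for a, alpha in enumerate(alphas):
        shrink = s / (s**2 + alpha)
        preds[a] = M @ (shrink * uty) + ym
    return preds


def _cv_oof_predictions(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_folds: int,
    alphas,
    inner_folds: int = 5,
) -> np.ndarray:
    """One CV replicate: out-of-fold ridge predictions with inner-fold
    penalty selection per training split."""
    n = y.size
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    oof = np.empty(n)
    for f in range(n_folds):
        test_idx = folds[f]
        train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
        Xtr, ytr = X[train_idx], y[train_idx]
        # inner selection of the penalty
        n_tr = train_idx.size
        inner_order = rng.permutation(n_tr)
        inner = np.array_split(inner_order, inner_folds)
        sse = np.zeros(len(alphas))
        for g in range(inner_folds):
            val = inner[g]
            fit = np.concatenate([inner[h] for h in range(inner_folds) if h != g])
            preds = _svd_ridge_paths(Xtr[fit], ytr[fit], Xtr[val], alphas)
            sse += np.sum((preds - ytr[val][None, :]) ** 2, axis=1)
        best = int(np.argmin(sse))
        oof[test_idx] = _svd_ridge_paths(Xtr, ytr, X[test_idx], [alphas[best]])[0]
    return oof


def _r2_rmse(obs: np.ndarray, pred: np.ndarray) -> tuple:
    if np.std(pred) == 0 or np.std(obs) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return r2, rmse


def gp_curve(
    G: Genotypes,
    y: pd.Series,
    ranking: list,
    k_grid=DEFAULT_K_GRID,
    n_folds: int = 5,
    n_reps: int = 100,
    seed: int = 0,
    alphas=DEFAULT_ALPHAS,
    reference: bool = True,
) -> GPCurve:
    """Cross-validated r2/RMSE curves over the top-k grid.

    For each k and each of ``n_reps`` replicates, accessions are split into
    ``n_folds`` folds; ridge models on the top-k SNP dosages produce
    out-of-fold predictions, scored by squared Pearson correlation and
    RMSE over the assembled predictions. ``reference_r2`` repeats the
    computation with k randomly drawn SNPs per replicate.
    """
    y = pd.Series(y).astype(float).loc[G.accessions]
    if y.isna().any():
        raise ValueError("phenotype must be complete for genomic prediction")
    k_grid = [int(k) for k in k_grid]
    if max(k_grid) > len(ranking):
        raise ValueError(f"ranking covers {len(ranking)} SNPs < max k {max(k_grid)}")
    if max(k_grid) > G.n_snps:
        raise ValueError("k exceeds the number of SNPs")
    if n_folds > G.n_accessions:
        raise ValueError("more folds than accessions")
    X_all = G.dosage.to_numpy(dtype=float)
    if np.isnan(X_all).any():
        raise ValueError("genotypes must be imputed before genomic prediction")
    col_of = {s: i for i, s in enumerate(G.snp_ids)}
    y_arr = y.to_numpy()
    rows = []
    for k in k_grid:
        cols = [col_of[s] for s in ranking[:k]]
        Xk = X_all[:, cols]
        rng = np.random.default_rng((seed, k, 0))
        r2s, rmses = [], []
        for _ in range(n_reps):
            oof = _cv_oof_predictions(Xk, y_arr, rng, n_folds, alphas)
            r2, rmse = _r2_rmse(y_arr, oof)
            r2s.append(r2)
            rmses.append(rmse)
        ref_r2 = np.nan
        if reference:
            rng_ref = np.random.default_rng((seed, k, 1))
            ref_vals = []
            for _ in range(n_reps):
                cols_ref = rng_ref.choice(G.n_snps, size=k, replace=False)
                oof = _cv_oof_predictions(X_all[:, cols_ref], y_arr, rng_ref, n_folds, alphas)
                ref_vals.append(_r2_rmse(y_arr, oof)[0])
            ref_r2 = float(np.mean(ref_vals))
        rows.append(
            dict(
                k=k,
                r2_mean=float(np.mean(r2s)),
                r2_sd=float(np.std(r2s, ddof=1)) if n_reps > 1 else 0.0,
                rmse_mean=float(np.mean(rmses)),
                rmse_sd=float(np.std(rmses, ddof=1)) if n_reps > 1 else 0.0,
                reference_r2=ref_r2,
            )
        )
    table = pd.DataFrame(rows).set_index("k")
    return GPCurve(table, n_folds, n_reps, seed)


def select_k(curve: GPCurve, ranking: list | None = None, assoc: pd.DataFrame | None = None) -> EffectiveSet:
    """Effective SNP set: smallest k within one sd of the peak r2.

    Operationalizes "the highest r2 before the plateau": the global maximum
    of the mean-r2 curve defines the plateau level, and the smallest k whose
    mean r2 reaches that level minus one replicate standard deviation is
    selected. A curve still rising at the end of the grid selects the
    largest k and is flagged ``no_plateau``. ``p_cutoff`` is the largest
    GWAS p-value among the selected top-k SNPs when ``assoc`` is given.
    """
    tab = curve.table
    kmax = int(tab["r2_mean"].idxmax())
    level = tab.loc[kmax, "r2_mean"] - tab.loc[kmax, "r2_sd"]
    qualifying = tab.index[tab["r2_mean"] >= level]
    k_sel = int(qualifying[0])
    r2s = tab["r2_mean"].to_numpy()
    no_plateau = bool(
        (k_sel == int(tab.index[-1])) and len(tab) > 1 and r2s[-1] > r2s[-2]
    )
    snp_ids = list(ranking[:k_sel]) if ranking is not None else []
    p_cutoff = None
    if assoc is not None and snp_ids:
        p_cutoff = float(assoc.loc[snp_ids, "p_value"].max())
    return EffectiveSet(k_sel, snp_ids, p_cutoff, float(tab.loc[k_sel, "r2_mean"]), no_plateau)


def difference_rate(observed: float, predicted: float) -> float:
    """log2(observed RRL / predicted RRL); NaN when either is <= 0."""
    if observed <= 0 or predicted <= 0 or not np.isfinite(observed) or not np.isfinite(predicted):
        return float("nan")
    return float(np.log2(observed / predicted))


def predict_accessions(
    G: Genotypes,
    y: pd.Series,
    ranking: list,
    k_selected: int,
    n_folds: int = 5,
    n_reps: int = 100,
    seed: int = 0,
    alphas=DEFAULT_ALPHAS,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Per-accession GP predictions and difference-rate outlier flags.

    ``predicted_rrl`` is the mean of each accession's out-of-fold
    predictions over the CV replicates at the selected k;
    ``difference_rate = log2(observed / predicted)`` and ``unusual`` flags
    |rate| >= ``cutoff``. Accessions with non-positive observed or
    predicted values get an undefined (NaN) rate and are never flagged.
    """
    y = pd.Series(y).astype(float).loc[G.accessions]
    X_all = G.dosage.to_numpy(dtype=float)
    if np.isnan(X_all).any():
        raise ValueError("genotypes must be imputed before genomic prediction")
    col_of = {s: i for i, s in enumerate(G.snp_ids)}
    Xk = X_all[:, [col_of[s] for s in ranking[:k_selected]]]
    y_arr = y.to_numpy()
    rng = np.random.default_rng((seed, k_selected, 0))
    preds = np.zeros((n_reps, y_arr.size))
    for rep in range(n_reps):
        preds[rep] = _cv_oof_predictions(Xk, y_arr, rng, n_folds, alphas)
    mean_pred = preds.mean(axis=0)
    rates = np.array([difference_rate(o, p) for o, p in zip(y_arr, mean_pred)])
    unusual = np.where(np.isnan(rates), False, np.abs(rates) >= cutoff)
    return pd.DataFrame(
        {
            "observed_rrl": y_arr,
            "predicted_rrl": mean_pred,
            "difference_rate": rates,
            "unusual": unusual.astype(bool),
        },
        index=G.accessions.rename("accession"),
    )
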