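"""Association scans: Q+K mixed-model GWAS, GLM eGWAS, ELP allele tests.

The GWAS model is

    y = mu + Q alpha + x_j beta_j + u + e,
    u ~ (0, sigma2_g * kinship),  e ~ (0, sigma2_e * I)

with admixture proportions Q as fixed covariates (one column dropped for
identifiability) and a kinship-structured polygenic random effect. Variance
components are estimated once under the null by REML over the ratio
lambda = sigma2_e / sigma2_g (the P3D / "population parameters previously
determined" approximation, the compressed-model special case when every
accession is its own group), then each SNP is tested by exact generalized
least squares with a one-degree-of-freedom t-test.

No multiple-testing correction is applied in the scan: significance is
derived downstream from the genomic-prediction effective-SNP-set cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import Genotypes

__all__ = [
    "VarianceComponents",
    "filter_snps",
    "mlm_scan",
    "glm_scan",
    "allele_expression_test",
    "reml_variance_components",
]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    lambda_: float  # sigma2_e / sigma2_g
    reml_loglik: float


def filter_snps(G: Genotypes, maf_min: float = 0.05, missing_max: float = 0.05) -> Genotypes:
    """Retain SNPs with MAF >= ``maf_min`` and missing fraction <=
    ``missing_max`` (both boundaries inclusive)."""
    keep = (G.maf() >= maf_min) & (G.missing_fraction() <= missing_max)
    if not keep.any():
        warnings.warn("filter_snps removed every SNP", stacklevel=2)
    return G.subset_snps(G.snp_ids[keep.to_numpy()])


def _design(n: int, Q: pd.DataFrame | np.ndarray | None, index=None) -> np.ndarray:
    """Fixed-effect design: intercept plus Q with one column dropped."""
    X = [np.ones((n, 1))]
    if Q is not None:
        q = Q.loc[index].to_numpy(dtype=float) if isinstance(Q, pd.DataFrame) else np.asarray(Q, dtype=float)
        if q.ndim == 1:
            q = q[:, None]
        if q.shape[1] > 1:
            q = q[:, :-1]  # drop one ancestry column: rows of Q sum to 1
        X.append(q)
    X = np.hstack(X)
    # guard against a residual rank deficiency (e.g. near-identical columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient after dropping one Q column")
    return X


def reml_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    eigvals: np.ndarray,
    y_rot: np.ndarray,
    X_rot: np.ndarray,
    grid: tuple = (-10.0, 10.0),
    n_grid: int = 41,
    tol: float = 1e-6,
) -> VarianceComponents:
    """REML over log lambda on a fixed grid with bounded refinement.

    Works in the eigenbasis of the kinship matrix, where the covariance is
    diagonal: V = sigma2_g * diag(eigvals + lambda)."""
    n, p = X.shape

    _, logdet_xx = np.linalg.slogdet(X.T @ X)

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = eigvals + lam
        w = 1.0 / d
        XtWX = (X_rot * w[:, None]).T @ X_rot
        XtWy = (X_rot * w[:, None]).T @ y_rot
        beta = np.linalg.solve(XtWX, XtWy)
        r = y_rot - X_rot @ beta
        rss = float(np.sum(w * r * r))
        sigma2_g = rss / (n - p)
        _, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma2_g) + 1)
            + np.sum(np.log(d))
            + logdet_xwx
            - logdet_xx
        )
        return -ll

    grid_pts = np.linspace(grid[0], grid[1], n_grid)
    vals = np.array([neg_reml(g) for g in grid_pts])
    i = int(np.argmin(vals))
    lo = grid_pts[max(i - 1, 0)]
    hi = grid_pts[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        neg_reml, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    log_lam = float(res.x) if res.fun <= vals[i] else float(grid_pts[i])
    lam = float(np.exp(log_lam))
    d = eigvals + lam
    w = 1.0 / d
    XtWX = (X_rot * w[:, None]).T @ X_rot
    beta = np.linalg.solve(XtWX, (X_rot * w[:, None]).T @ y_rot)
    r = y_rot - X_rot @ beta
    sigma2_g = float(np.sum(w * r * r)) / (n - p)
    return VarianceComponents(sigma2_g, sigma2_g * lam, lam, -neg_reml(log_lam))


def mlm_scan(
    G: Genotypes,
    y: pd.Series,
    Q: pd.DataFrame | None = None,
    kinship: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Q+K mixed-model scan (P3D), one exact GLS t-test per SNP.

    ``y`` holds one phenotype value per accession (e.g. RRL). Missing
    genotypes at SNP j drop those accessions for test j only. Returns a
    frame with columns snp_id, chrom, pos, maf, n_called, beta, p_value,
    model, sorted by the SNP map order.
    """
    y = pd.Series(y).astype(float)
    common = G.accessions.intersection(y.dropna().index)
    if len(common) < 3:
        raise ValueError("fewer than 3 accessions with phenotype and genotype")
    y = y.loc[common]
    if float(np.std(y)) == 0:
        raise ValueError("phenotype is constant")
    dosage = G.dosage.loc[common]
    n = len(common)

    if kinship is None:
        Kmat = np.eye(n)
    else:
        Kmat = kinship.loc[common, common].to_numpy(dtype=float)
        Kmat = (Kmat + Kmat.T) / 2
    eigvals, U = np.linalg.eigh(Kmat + 1e-8 * np.eye(n))
    if eigvals[0] < -1e-6:
        raise ValueError(f"kinship is not PSD: smallest eigenvalue {eigvals[0]:.3e}")
    eigvals = np.clip(eigvals, 0.0, None)

    X = _design(n, Q, index=common)
    p_cov = X.shape[1]
    y_arr = y.to_numpy()
    y_rot = U.T @ y_arr
    X_rot = U.T @ X
    vc = reml_variance_components(y_arr, X, eigvals, y_rot, X_rot)
    w = 1.0 / (eigvals + vc.lambda_)

    # fast path: SNPs with complete calls, fully vectorized via
    # Frisch-Waugh-Lovell in the rotated (whitened) basis
    Xw = X_rot * w[:, None]
    XtWX_inv = np.linalg.inv(Xw.T @ X_rot)
    proj = X_rot @ (XtWX_inv @ Xw.T)  # hat matrix under W
    y_res = y_rot - proj @ y_rot
    ywy = float(np.sum(w * y_res * y_rot))

    Xsnp = dosage.to_numpy(dtype=float)
    called = ~np.isnan(Xsnp)
    n_called = called.sum(axis=0)
    freq = np.nanmean(Xsnp, axis=0)
    maf = np.minimum(freq, 1 - freq)

    beta = np.full(G.n_snps, np.nan)
    pval = np.full(G.n_snps, np.nan)
    complete = n_called == n
    if complete.any():
        Xc = Xsnp[:, complete]
        Xc_rot = U.T @ Xc
        Xc_res = Xc_rot - proj @ Xc_rot
        sxx = np.einsum("i,ij,ij->j", w, Xc_res, Xc_res)
        sxy = np.einsum("i,ij,i->j", w, Xc_res, y_res)
        ok = sxx > 1e-12
        df = n - p_cov - 1
        b = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        sse = ywy - b**2 * sxx
        sigma2 = sse / df
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = b / np.sqrt(sigma2 / sxx)
        pv = 2 * stats.t.sf(np.abs(tstat), df)
        pv = np.clip(pv, np.finfo(float).tiny, 1.0)
        idx = np.flatnonzero(complete)
        beta[idx] = np.where(ok, b, np.nan)
        pval[idx] = np.where(ok, pv, np.nan)

    # slow path: per-SNP casewise deletion in the original basis
    for j in np.flatnonzero(~complete):
        mask = called[:, j]
        if mask.sum() < p_cov + 2:
            continue
        x_sub = Xsnp[mask, j]
        if np.std(x_sub) == 0:
            continue
        V_sub = vc.sigma2_g * (Kmat[np.ix_(mask, mask)] + vc.lambda_ * np.eye(mask.sum()))
        b, pv = _gls_single(y_arr[mask], X[mask], x_sub, V_sub)
        beta[j], pval[j] = b, pv

    return pd.DataFrame(
        {
            "snp_id": G.snp_ids,
            "chrom": G.snpmap["chrom"].to_numpy(),
            "pos": G.snpmap["pos"].to_numpy(),
            "maf": maf,
            "n_called": n_called,
            "beta": beta,
            "p_value": pval,
            "model": "MLM",
        }
    ).set_index("snp_id")


def _gls_single(y, X, x, V) -> tuple:
    """Exact GLS one-df test of x after covariates X under covariance V."""
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, np.column_stack([X, x]))
    n, p1 = Xw.shape
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    df = n - p1
    sigma2 = float(r @ r) / df
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    t = beta[-1] / se
    p = float(np.clip(2 * stats.t.sf(abs(t), df), np.finfo(float).tiny, 1.0))
    return float(beta[-1]), p


def glm_scan(G: Genotypes, y: pd.Series) -> pd.DataFrame:
    """Fixed-effects (GLM) scan: per-SNP regression of the trait on dosage.

    Used for the expression GWAS; identical contract to :func:`mlm_scan`
    and exactly equal to it when kinship = I and Q = intercept only.
    """
    out = mlm_scan(G, y, Q=None, kinship=None)
    out["model"] = "GLM"
    return out


def allele_expression_test(
    expr: pd.Series, g_j: pd.Series, maf_min: float = 0.10
) -> float:
    """Expression-level-polymorphism test: expression ~ allele linear model.

    Two-group linear-model p-value (algebraically the pooled-variance
    two-sample t-test). The test is refused for SNPs below ``maf_min`` and
    errors when an allele class is empty among jointly observed accessions.
    """
    expr = pd.Series(expr).astype(float)
    g = pd.Series(g_j).astype(float)
    common = expr.dropna().index.intersection(g.dropna().index)
    expr, g = expr.loc[common], g.loc[common]
    freq = g.mean()
    maf = min(freq, 1 - freq)
    if maf < maf_min:
        raise ValueError(f"SNP MAF {maf:.3f} below the {maf_min:.2f} threshold; test refused")
    y0 = expr[g == 0].to_numpy()
    y1 = expr[g == 1].to_numpy()
    if y0.size == 0 or y1.size == 0:
        raise ValueError("one allele class is empty")
    if y0.size + y1.size < 4:
        raise ValueError("too few accessions for a two-group test")
    # OLS of expression on dosage; t-test on the slope
    x = g.to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, expr.to_numpy(), rcond=None)
    r = expr.to_numpy() - X @ beta
    df = x.size - 2
    sigma2 = float(r @ r) / df
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sigma2 == 0:
        return 1.0 if abs(beta[1]) < 1e-12 else float(np.finfo(float).tiny)
    t = beta[1] / np.sqrt(sigma2 / sxx)
    return float(np.clip(2 * stats.t.sf(abs(t), df), np.finfo(float).tiny, 1.0))
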