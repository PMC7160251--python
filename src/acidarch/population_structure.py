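"""Population structure: admixture proportions, Evanno delta-K, kinship.

The admixture model treats each inbred accession's dosage at SNP j as
Bernoulli(sum_k q_ik p_jk): Q (accessions x K) holds ancestry proportions
and P (SNPs x K) subpopulation allele frequencies. The model is the one a
Bayesian MCMC structure program samples from; here it is fitted by EM block
relaxation with multiple restarts, which is deterministic given the seed
and maximises the identical likelihood. The number of subpopulations is
chosen by the Evanno delta-K statistic over a K grid, and the kinship
matrix for the mixed model is a VanRaden-style centered cross-product
adapted to haploid dosage coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Genotypes

__all__ = [
    "StructureFit",
    "DeltaKResult",
    "select_structure_snps",
    "admixture_fit",
    "admixture_loglik",
    "evanno_delta_k",
    "kinship_matrix",
    "match_columns",
]

_EPS = 1e-9


@dataclass
class StructureFit:
    K: int
    Q: pd.DataFrame  # accessions x K, rows sum to 1
    P: pd.DataFrame  # SNPs x K allele frequencies
    loglik: float
    replicate_id: int = 0
    restart_logliks: list = field(default_factory=list)
    n_iter: int = 0


@dataclass
class DeltaKResult:
    K_grid: list
    mean_loglik: dict
    delta_k: dict
    K_selected: int | None
    ambiguous: bool = False
    undefined_at: list = field(default_factory=list)


def select_structure_snps(G: Genotypes, n: int = 1000) -> list:
    """Pick ``n`` SNPs for structure estimation.

    Criteria: (1) MAF >= 10% (boundary inclusive), (2) no missing calls,
    (3) biallelic (polymorphic in this panel), (4) near-uniform physical
    intervals across the genome. Uniformity is achieved by walking the
    genome-wide cumulative coordinate and taking the nearest still-unused
    eligible SNP to each of ``n`` evenly spaced targets.
    """
    maf = G.maf()
    eligible = (maf >= 0.10) & (G.missing_fraction() == 0.0) & (maf > 0.0)
    ids = G.snp_ids[eligible.to_numpy()]
    if len(ids) < n:
        raise ValueError(
            f"only {len(ids)} SNPs satisfy the structure-SNP criteria; {n} required"
        )
    snpmap = G.snpmap.loc[ids]
    # genome-wide cumulative coordinate
    offsets = {}
    running = 0
    for chrom, sub in G.snpmap.groupby("chrom"):
        offsets[chrom] = running
        running += int(sub["pos"].max()) + 1
    cum = snpmap["pos"].to_numpy() + np.array([offsets[c] for c in snpmap["chrom"]])
    order = np.argsort(cum)
    cum_sorted = cum[order]
    ids_sorted = np.asarray(ids)[order]
    targets = np.linspace(cum_sorted[0], cum_sorted[-1], n)
    chosen: list = []
    used = np.zeros(len(ids_sorted), dtype=bool)
    for t in targets:
        j = int(np.searchsorted(cum_sorted, t))
        # nearest unused SNP around the insertion point
        best, best_d = None, None
        lo, hi = j - 1, j
        while lo >= 0 or hi < len(ids_sorted):
            for cand in (lo, hi):
                if 0 <= cand < len(ids_sorted) and not used[cand]:
                    d = abs(cum_sorted[cand] - t)
                    if best is None or d < best_d:
                        best, best_d = cand, d
            if best is not None:
                break
            lo -= 1
            hi += 1
        used[best] = True
        chosen.append(ids_sorted[best])
    return chosen


def admixture_loglik(g: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    """Exact log-likelihood of the Bernoulli admixture model."""
    F = np.clip(Q @ P.T, _EPS, 1 - _EPS)
    return float(np.sum(g * np.log(F) + (1 - g) * np.log(1 - F)))


def _em_fit(g: np.ndarray, K: int, rng: np.random.Generator,
            tol: float, max_iter: int):
    n, m = g.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(rng.uniform(0.05, 0.95, size=(m, K)), _EPS, 1 - _EPS)
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        F = np.clip(Q @ P.T, _EPS, 1 - _EPS)  # (n, m)
        A = g / F          # weight of the "allele 1" responsibility
        B = (1 - g) / (1 - F)
        # responsibilities summed over accessions / SNPs without forming
        # the full (n, m, K) tensor
        num_p = (A.T @ Q) * P        # (m, K): sum_i g a_ijk
        den_p = num_p + ((B.T @ Q) * (1 - P))
        new_P = np.clip(num_p / np.maximum(den_p, _EPS), _EPS, 1 - _EPS)
        num_q = (A @ P) * Q + (B @ (1 - P)) * Q  # (n, K)
        new_Q = num_q / num_q.sum(axis=1, keepdims=True)
        Q, P = new_Q, new_P
        ll = admixture_loglik(g, Q, P)
        if ll < prev - 1e-6:
            raise RuntimeError(f"EM log-likelihood decreased at iteration {it}")
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
    return Q, P, prev, it


def admixture_fit(
    G_subset: Genotypes | pd.DataFrame | np.ndarray,
    K: int,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> StructureFit:
    """Fit the admixture model by EM with multiple restarts.

    Requires a complete (no missing calls) genotype subset, typically the
    output of :func:`select_structure_snps`. Returns the best fit across
    restarts; ``restart_logliks`` carries all restart log-likelihoods for
    the delta-K computation.
    """
    if isinstance(G_subset, Genotypes):
        g = G_subset.values()
        accessions, snp_ids = list(G_subset.accessions), list(G_subset.snp_ids)
    elif isinstance(G_subset, pd.DataFrame):
        g = G_subset.to_numpy(dtype=float)
        accessions, snp_ids = list(G_subset.index), list(G_subset.columns)
    else:
        g = np.asarray(G_subset, dtype=float)
        accessions = [f"acc{i}" for i in range(g.shape[0])]
        snp_ids = [f"snp{j}" for j in range(g.shape[1])]
    if np.isnan(g).any():
        raise ValueError("admixture_fit requires no missing calls")
    n = g.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of accessions ({n})")

    cols = [f"pop{k+1}" for k in range(K)]
    if K == 1:
        # closed form: P = observed allele frequencies
        p = g.mean(axis=0)
        Q = np.ones((n, 1))
        ll = admixture_loglik(g, Q, p[:, None])
        return StructureFit(
            1,
            pd.DataFrame(Q, index=accessions, columns=cols),
            pd.DataFrame(p[:, None], index=snp_ids, columns=cols),
            ll,
            restart_logliks=[ll] * n_restarts,
        )

    rng = np.random.default_rng(seed)
    best = None
    logliks = []
    for r in range(n_restarts):
        Q, P, ll, it = _em_fit(g, K, rng, tol, max_iter)
        logliks.append(ll)
        if best is None or ll > best[2]:
            best = (Q, P, ll, r, it)
    Q, P, ll, r, it = best
    return StructureFit(
        K,
        pd.DataFrame(Q, index=accessions, columns=cols),
        pd.DataFrame(P, index=snp_ids, columns=cols),
        ll,
        replicate_id=r,
        restart_logliks=logliks,
        n_iter=it,
    )


def evanno_delta_k(logliks: dict) -> DeltaKResult:
    """Evanno delta-K from replicate log-likelihoods per K.

    ``logliks`` maps K -> list of replicate log-likelihoods (>= 2 each) for
    at least 3 consecutive K values. For interior K,

        delta_k(K) = mean(|L(K+1) - 2 L(K) + L(K-1)|) / sd(L(K))

    with the numerator averaged over replicate runs when the replicate
    counts match (the classical form), else over replicate means. K with
    sd(L(K)) = 0 is
    flagged undefined rather than reported as infinite; a flat second
    difference everywhere yields an ambiguous selection (K_selected None).
    """
    grid = sorted(logliks)
    if len(grid) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(grid, grid[1:])):
        raise ValueError("K grid must be consecutive integers")
    for k in grid:
        if len(logliks[k]) < 2:
            raise ValueError(f"need >= 2 replicates at K={k}")
    mean_l = {k: float(np.mean(logliks[k])) for k in grid}
    sd_l = {k: float(np.std(logliks[k], ddof=1)) for k in grid}
    delta = {}
    undefined = []
    counts = {len(logliks[k]) for k in grid}
    paired = len(counts) == 1
    for k in grid[1:-1]:
        if paired:
            second = (
                np.asarray(logliks[k + 1], dtype=float)
                - 2 * np.asarray(logliks[k], dtype=float)
                + np.asarray(logliks[k - 1], dtype=float)
            )
            num = float(np.mean(np.abs(second)))
        else:
            num = abs(mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1])
        if sd_l[k] == 0:
            undefined.append(k)
            delta[k] = np.nan
        else:
            delta[k] = num / sd_l[k]
    finite = {k: v for k, v in delta.items() if np.isfinite(v)}
    if not finite or all(v == 0 for v in finite.values()):
        return DeltaKResult(grid, mean_l, delta, None, ambiguous=True,
                            undefined_at=undefined)
    k_sel = max(finite, key=lambda k: finite[k])
    return DeltaKResult(grid, mean_l, delta, int(k_sel), undefined_at=undefined)


def kinship_matrix(G: Genotypes | pd.DataFrame) -> pd.DataFrame:
    """VanRaden-style kinship for haploid dosages.

    ``K = Z Z' / sum_j f_j (1 - f_j)`` with Z the column-centered dosage
    matrix (missing entries contribute zero after centering, i.e. are set
    to the column mean). Symmetric and positive semi-definite by
    construction; monomorphic-only panels have no scale and raise.
    """
    dosage = G.dosage if isinstance(G, Genotypes) else G
    X = dosage.to_numpy(dtype=float)
    f = np.nanmean(X, axis=0)
    denom = float(np.sum(f * (1 - f)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: kinship scaling undefined")
    Z = np.where(np.isnan(X), 0.0, X - f)
    K = (Z @ Z.T) / denom
    K = (K + K.T) / 2
    return pd.DataFrame(K, index=dosage.index, columns=dosage.index)


def match_columns(Q_est: pd.DataFrame, Q_true: pd.DataFrame) -> pd.DataFrame:
    """Permute estimated ancestry columns to best match the truth.

    Greedy assignment on the column-correlation matrix is exact for the
    small K used here; returns the column-permuted estimate.
    """
    from itertools import permutations

    K = Q_true.shape[1]
    est = Q_est.to_numpy()
    true = Q_true.to_numpy()
    best_perm, best_err = None, np.inf
    for perm in permutations(range(K)):
        err = np.abs(est[:, list(perm)] - true).mean()
        if err < best_err:
            best_perm, best_err = perm, err
    out = Q_est.iloc[:, list(best_perm)]
    out.columns = Q_true.columns
    return out
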