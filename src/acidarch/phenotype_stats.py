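"""Root-length phenotype statistics.

Tolerance of an accession is scored as the relative root length (RRL):
root length under a stress condition divided by root length under control,
in percent, each condition summarised by the mean of its five longest roots.
Replicated RRL supports broad-sense heritability (line-mean repeatability),
coefficient of variation, subpopulation permutation tests and boxplot
outlier calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rrl",
    "replicate_rrl",
    "rrl_table",
    "trait_summary",
    "subpop_tests",
    "tukey_hsd",
    "TraitSummary",
]


def rrl(control_lengths, stress_lengths, top_n: int = 5) -> float:
    """Relative root length in percent from raw per-seedling root lengths.

    Uses the ``top_n`` longest roots in each condition:
    ``100 * mean(top-n stress) / mean(top-n control)``.

    Raises ``ValueError`` when fewer than ``top_n`` roots were measured in
    either condition (low-germination accessions are excluded upstream).
    """
    control = np.asarray(control_lengths, dtype=float)
    stress = np.asarray(stress_lengths, dtype=float)
    if control.size < top_n or stress.size < top_n:
        raise ValueError(
            f"need at least {top_n} measured roots per condition, "
            f"got {control.size} control / {stress.size} stress"
        )
    top_c = np.sort(control)[::-1][:top_n]
    top_s = np.sort(stress)[::-1][:top_n]
    return 100.0 * top_s.mean() / top_c.mean()


def replicate_rrl(control_lengths, stress_lengths, top_n: int = 5) -> np.ndarray:
    """Per-replicate RRL values for variance-component estimation.

    The ``top_n`` longest roots of each condition are selected, then paired
    in recorded (seedling) order — stress and control replicates are
    different seedlings, so any pairing is arbitrary and rank-pairing would
    understate the replicate variance. The mean of these ratios is close
    to, but intentionally not identical to, the ratio-of-means in
    :func:`rrl`.
    """
    control = np.asarray(control_lengths, dtype=float)
    stress = np.asarray(stress_lengths, dtype=float)
    if control.size < top_n or stress.size < top_n:
        raise ValueError(f"need at least {top_n} roots per condition")
    keep_c = np.sort(np.argsort(control)[::-1][:top_n])  # recorded order
    keep_s = np.sort(np.argsort(stress)[::-1][:top_n])
    return 100.0 * stress[keep_s] / control[keep_c]


def rrl_table(
    phenotypes: pd.DataFrame,
    stress: str,
    control: str = "control",
    top_n: int = 5,
) -> pd.DataFrame:
    """Accession-level and replicate-level RRL from a long phenotype table.

    ``phenotypes`` columns: accession, condition, replicate, length_mm.
    Returns a frame indexed by accession with columns ``rrl`` (ratio of
    top-n means, the reported phenotype) and ``rep_1..rep_n`` (rank-paired
    replicate RRLs used by :func:`trait_summary`).
    """
    out = {}
    for acc, sub in phenotypes.groupby("accession", sort=True):
        ctl = sub.loc[sub["condition"] == control, "length_mm"].to_numpy()
        st = sub.loc[sub["condition"] == stress, "length_mm"].to_numpy()
        if ctl.size < top_n or st.size < top_n:
            continue  # low-germination accession
        reps = replicate_rrl(ctl, st, top_n)
        row = {"rrl": rrl(ctl, st, top_n)}
        row.update({f"rep_{i + 1}": v for i, v in enumerate(reps)})
        out[acc] = row
    if not out:
        raise ValueError(f"no accession has >= {top_n} roots in both conditions")
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("accession")


@dataclass
class TraitSummary:
    h_b2: float  # broad-sense heritability (line-mean repeatability)
    cv: float  # coefficient of variation of accession means, percent
    sigma2_accession: float
    sigma2_residual: float
    n_accessions: int
    mean_replicates: float


def trait_summary(replicate_rrl_table: pd.DataFrame) -> TraitSummary:
    """Broad-sense heritability and CV from replicated accession RRLs.

    One-way random-effects ANOVA with accession as the grouping factor:
    ``sigma2_a = (MS_between - MS_within) / n0`` (n0 the ANOVA effective
    replicate number), truncated at 0, and

        H_b^2 = sigma2_a / (sigma2_a + sigma2_e / r_bar)

    i.e. repeatability of accession means at the mean replicate number.
    CV = 100 * sd(accession means) / mean(accession means).

    ``replicate_rrl_table``: rows = accessions, columns = replicate RRLs
    (``rep_*`` columns of :func:`rrl_table`, or any wide layout; NaN allowed
    for unbalanced designs).
    """
    cols = [c for c in replicate_rrl_table.columns if str(c).startswith("rep_")]
    wide = replicate_rrl_table[cols] if cols else replicate_rrl_table
    values = wide.to_numpy(dtype=float)
    counts = np.sum(~np.isnan(values), axis=1)
    keep = counts >= 2
    values, counts = values[keep], counts[keep]
    a = values.shape[0]
    if a < 2:
        raise ValueError("heritability undefined with fewer than 2 accessions")
    means = np.nanmean(values, axis=1)
    grand = np.average(means, weights=counts)
    n_total = counts.sum()
    ss_between = np.sum(counts * (means - grand) ** 2)
    ss_within = np.nansum((values - means[:, None]) ** 2)
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n_total - a)
    n0 = (n_total - np.sum(counts**2) / n_total) / (a - 1)
    sigma2_a = max((ms_between - ms_within) / n0, 0.0)
    r_bar = counts.mean()
    h2 = sigma2_a / (sigma2_a + ms_within / r_bar) if (sigma2_a + ms_within) > 0 else 1.0
    h2 = float(np.clip(h2, 0.0, 1.0))
    cv = 100.0 * float(np.std(means, ddof=1) / np.mean(means))
    return TraitSummary(h2, cv, float(sigma2_a), float(ms_within), int(a), float(r_bar))


def subpop_tests(
    rrl_values: pd.Series,
    subpop_labels: pd.Series,
    n_perm: int = 10000,
    seed: int | None = None,
    min_size: int = 3,
) -> pd.DataFrame:
    """Permutation test of each subpopulation's mean RRL against the whole
    population, plus within-subpopulation boxplot outliers.

    For each subpopulation the statistic is |mean(subpop) - mean(all)|; the
    null distribution resamples subpopulation membership. Two-sided p with
    add-one correction: ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    Outliers use the 1.5 x IQR fences within each subpopulation, strict
    inequality (a value exactly on a fence is not an outlier).

    Returns a frame indexed by subpopulation with columns n, mean,
    p_value (NaN with ``skipped=True`` when n < ``min_size``), and
    ``outliers`` (list of accession ids beyond the fences).
    """
    rrl_values = pd.Series(rrl_values).astype(float)
    labels = pd.Series(subpop_labels).reindex(rrl_values.index)
    rng = np.random.default_rng(seed)
    y = rrl_values.to_numpy()
    grand = y.mean()
    rows = {}
    for pop, members in rrl_values.groupby(labels):
        n = len(members)
        if n < min_size:
            warnings.warn(f"subpopulation {pop!r} has n={n} < {min_size}; test skipped")
            rows[pop] = dict(n=n, mean=members.mean(), p_value=np.nan, skipped=True,
                             outliers=_boxplot_outliers(members))
            continue
        obs = abs(members.mean() - grand)
        idx = np.argsort(rng.random((n_perm, y.size)), axis=1)[:, :n]
        perm_means = y[idx].mean(axis=1)
        exceed = int(np.sum(np.abs(perm_means - grand) >= obs))
        p = (1 + exceed) / (n_perm + 1)
        rows[pop] = dict(n=n, mean=members.mean(), p_value=p, skipped=False,
                         outliers=_boxplot_outliers(members))
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subpop")


def _boxplot_outliers(values: pd.Series) -> list:
    q1, q3 = np.percentile(values.to_numpy(dtype=float), [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (values < lo) | (values > hi)  # strict: fence value itself is kept
    return list(values.index[mask])


def tukey_hsd(rrl_values: pd.Series, subpop_labels: pd.Series, alpha: float = 0.05):
    """Routine Tukey HSD across subpopulations on accession means.

    Thin wrapper over statsmodels, provided for report parity with the
    subpopulation boxplot figure.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = pd.Series(subpop_labels).reindex(rrl_values.index)
    return pairwise_tukeyhsd(rrl_values.to_numpy(dtype=float), labels.to_numpy(), alpha=alpha)
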