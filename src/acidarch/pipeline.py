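"""End-to-end driver: simulate a panel, scan, predict, flag outliers.

Chains the pipeline stages exactly as the analysis scripts do — simulate a
structured panel and replicated phenotypes, compute RRL, filter and impute
SNPs, kinship + Q+K mixed-model GWAS, rank SNPs, cross-validated ridge
curves, effective-set selection and per-accession difference rates — and
returns every intermediate product for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import association as assoc
from . import genomic_prediction as gp
from . import phenotype_stats as phs
from . import population_structure as ps
from .synthetic_data import (
    ArchitectureConfig,
    PopulationConfig,
    simulate_phenotypes,
    simulate_population,
)

__all__ = ["StressPipelineResult", "run_stress_pipeline"]


@dataclass
class StressPipelineResult:
    genotypes: object
    true_q: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: object
    rrl: pd.Series
    trait_summary: object
    assoc: pd.DataFrame
    ranking: list
    curve: object | None = None
    effective: object | None = None
    predictions: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def run_stress_pipeline(
    preset: str = "oligogenic_rare",
    pop_seed: int = 0,
    arch_seed: int = 1,
    n_accessions: int = 200,
    n_snps: int = 20000,
    k_grid=gp.DEFAULT_K_GRID,
    curve_reps: int = 10,
    predict_reps: int = 20,
    cv_seed: int = 5,
    run_gp: bool = True,
    reference: bool = False,
    arch_overrides: dict | None = None,
) -> StressPipelineResult:
    """Run the full marker-based pipeline on one simulated panel.

    ``preset`` is ``oligogenic_rare`` (aluminum-tolerance-like) or
    ``polygenic`` (proton-tolerance-like). The true admixture matrix is used
    as the Q covariate — the structure-estimation stage is exercised
    separately — and the GWAS ranking feeds the genomic-prediction stage.
    """
    cfg = PopulationConfig(
        n_accessions=n_accessions, n_snps=n_snps, seed=pop_seed, missing_rate=0.02
    )
    G, true_q = simulate_population(cfg)
    maker = (
        ArchitectureConfig.oligogenic_rare
        if preset == "oligogenic_rare"
        else ArchitectureConfig.polygenic
    )
    arch = maker(seed=arch_seed, **(arch_overrides or {}))
    phenotypes, truth = simulate_phenotypes(G, arch)
    rrl_tab = phs.rrl_table(phenotypes, stress="stress")
    y = rrl_tab["rrl"]
    summary = phs.trait_summary(rrl_tab)

    G_filtered = assoc.filter_snps(G)
    G_imputed = gp.impute_missing(G_filtered)
    kinship = ps.kinship_matrix(G_imputed)
    scan = assoc.mlm_scan(G_imputed, y, Q=true_q, kinship=kinship)
    ranking = gp.rank_snps(scan.dropna(subset=["p_value"]))

    result = StressPipelineResult(
        genotypes=G_imputed,
        true_q=true_q,
        phenotypes=phenotypes,
        truth=truth,
        rrl=y,
        trait_summary=summary,
        assoc=scan,
        ranking=ranking,
    )
    result.extras["raw_genotypes"] = G
    if not run_gp:
        return result

    curve = gp.gp_curve(
        G_imputed, y, ranking, k_grid=k_grid, n_reps=curve_reps,
        seed=cv_seed, reference=reference,
    )
    effective = gp.select_k(curve, ranking, scan)
    predictions = gp.predict_accessions(
        G_imputed, y, ranking, effective.k_selected,
        n_reps=predict_reps, seed=cv_seed + 1,
    )
    result.curve = curve
    result.effective = effective
    result.predictions = predictions
    return result
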