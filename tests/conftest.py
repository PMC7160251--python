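"""Shared fixtures: small synthetic panels reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from acidarch.datatypes import Genotypes
from acidarch.synthetic_data import (
    ArchitectureConfig,
    PopulationConfig,
    simulate_phenotypes,
    simulate_population,
)


@pytest.fixture(scope="session")
def two_pop_panel():
    """Strongly diverged two-subpopulation panel, no missing calls."""
    cfg = PopulationConfig(
        n_accessions=60,
        n_snps=1500,
        n_subpops=2,
        admixture_concentration=0.05,
        divergence=0.45,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def unstructured_panel():
    """Single exchangeable population (no structure limit)."""
    cfg = PopulationConfig(
        n_accessions=80,
        n_snps=2000,
        n_subpops=1,
        divergence=0.0,
        missing_rate=0.0,
        seed=13,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def oligo_panel():
    """Medium oligogenic fixture with phenotypes, used by several modules."""
    cfg = PopulationConfig(n_accessions=150, n_snps=6000, seed=17, missing_rate=0.02)
    G, true_q = simulate_population(cfg)
    arch = ArchitectureConfig.oligogenic_rare(seed=18)
    phenotypes, truth = simulate_phenotypes(G, arch)
    return G, true_q, phenotypes, truth


def toy_genotypes(dosage_rows, positions=None, chrom=1):
    """Tiny Genotypes from a list of per-accession dosage rows."""
    arr = np.asarray(dosage_rows, dtype=float)
    n, m = arr.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    snp_ids = [f"Chr{chrom}_{p}" for p in positions]
    dosage = pd.DataFrame(
        arr, index=[f"acc{i:03d}" for i in range(n)], columns=snp_ids
    )
    snpmap = pd.DataFrame(
        {"chrom": chrom, "pos": positions}, index=pd.Index(snp_ids, name="snp_id")
    )
    return Genotypes(dosage, snpmap)
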