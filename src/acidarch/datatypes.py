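"""Shared containers for the acid-soil tolerance pipeline.

Accessions are inbred (fully homozygous) lines, so genotypes are stored as
haploid-equivalent minor-allele dosages in {0, 1}, with NaN for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A simulation or analysis configuration field is invalid."""


@dataclass
class Genotypes:
    """Accessions x SNPs dosage matrix plus the paired SNP map.

    Attributes
    ----------
    dosage : pd.DataFrame
        Rows indexed by accession id, columns by SNP id; entries 0.0/1.0
        (minor-allele dosage for an inbred line) or NaN for missing calls.
    snpmap : pd.DataFrame
        Indexed by SNP id, with columns ``chrom`` and ``pos`` (bp).
        Positions are strictly increasing within each chromosome.
    """

    dosage: pd.DataFrame
    snpmap: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosage.columns.equals(self.snpmap.index):
            # allow same set, different order, by aligning the map
            if set(self.dosage.columns) != set(self.snpmap.index):
                raise ValueError("dosage columns and snpmap index disagree")
            self.snpmap = self.snpmap.loc[self.dosage.columns]

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def accessions(self) -> pd.Index:
        return self.dosage.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.columns

    def maf(self) -> pd.Series:
        """Minor-allele frequency per SNP over called accessions."""
        freq = self.dosage.mean(axis=0, skipna=True)
        return np.minimum(freq, 1.0 - freq)

    def missing_fraction(self) -> pd.Series:
        return self.dosage.isna().mean(axis=0)

    def subset_snps(self, snp_ids) -> "Genotypes":
        ids = pd.Index(snp_ids)
        return Genotypes(self.dosage.loc[:, ids], self.snpmap.loc[ids])

    def values(self) -> np.ndarray:
        return self.dosage.to_numpy(dtype=float)


@dataclass
class GeneAnnotation:
    """Gene models with UTR/ORF coordinates (1-based inclusive, GFF-style).

    ``table`` columns: gene_id, chrom, strand, utr5_start, utr5_end,
    orf_start, orf_end, utr3_start, utr3_end. The promoter (2 kb upstream of
    the outer 5'UTR end, strand aware) is derived, not stored.
    """

    table: pd.DataFrame
    chrom_lengths: dict = field(default_factory=dict)
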