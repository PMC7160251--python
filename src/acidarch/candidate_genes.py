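"""Candidate-gene assignment around associated SNPs via local LD.

For each associated SNP the local LD block is the span of surrounding SNPs
within a 10 kb window whose pairwise r2 with the focal SNP exceeds 0.80
(strict). Genes are taken with their promoter-extended models — promoter =
2 kb upstream of the outer 5'UTR end, strand aware — and every gene whose
extended model overlaps the LD span expanded to at least +/- 10 kb around
the SNP becomes a candidate. A SNP with no LD partner falls back to its
single closest gene.

r2 is the squared Pearson correlation of dosages (composite LD); for fully
homozygous inbred lines this coincides with haplotype-frequency r2.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, Genotypes

__all__ = [
    "GeneModel",
    "CandidateAssignment",
    "gene_models",
    "pairwise_r2",
    "ld_interval",
    "assign_genes",
    "candidate_gene_table",
]

PROMOTER_LENGTH = 2000


@dataclass
class GeneModel:
    gene_id: str
    chrom: int
    strand: str
    orf_interval: tuple
    utr5_interval: tuple
    utr3_interval: tuple
    promoter_interval: tuple  # 2 kb upstream of the outer 5'UTR end

    @property
    def extended_span(self) -> tuple:
        parts = [self.orf_interval, self.utr5_interval, self.utr3_interval, self.promoter_interval]
        return (min(p[0] for p in parts), max(p[1] for p in parts))


def gene_models(annotation: GeneAnnotation) -> dict:
    """Promoter-extended :class:`GeneModel` per gene id.

    The promoter abuts the outer end of the 5'UTR on the upstream side
    (strand aware) and is truncated at chromosome edges.
    """
    models = {}
    for gene_id, row in annotation.table.iterrows():
        chrom = int(row["chrom"])
        length = annotation.chrom_lengths.get(chrom)
        if row["strand"] == "+":
            p_end = int(row["utr5_start"]) - 1
            p_start = max(p_end - PROMOTER_LENGTH + 1, 1)
        else:
            p_start = int(row["utr5_end"]) + 1
            p_end = p_start + PROMOTER_LENGTH - 1
            if length is not None:
                p_end = min(p_end, length)
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=row["strand"],
            orf_interval=(int(row["orf_start"]), int(row["orf_end"])),
            utr5_interval=(int(row["utr5_start"]), int(row["utr5_end"])),
            utr3_interval=(int(row["utr3_start"]), int(row["utr3_end"])),
            promoter_interval=(p_start, p_end),
        )
    return models


@dataclass
class CandidateAssignment:
    snp_id: str
    ld_interval: tuple | None
    linked_snp_ids: list
    gene_ids: list
    fallback_used: bool
    tie: bool = False


def pairwise_r2(g_i, g_j) -> float:
    """Squared dosage correlation over jointly called accessions.

    NaN when either SNP is monomorphic in the joint set (undefined).
    """
    x = np.asarray(g_i, dtype=float)
    y = np.asarray(g_j, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_interval(
    snp_id: str,
    G: Genotypes,
    window: int = 10000,
    r2_min: float = 0.80,
):
    """LD span around a focal SNP, or None when no partner passes.

    Partners are other SNPs on the same chromosome within +/- ``window`` bp
    with r2 strictly greater than ``r2_min``. The interval runs from the
    leftmost to the rightmost partner and always includes the focal
    position. Returns ``(start, end), linked_snp_ids`` or ``(None, [])``.
    """
    if snp_id not in G.snpmap.index:
        raise KeyError(f"SNP {snp_id} not in the map")
    chrom = G.snpmap.loc[snp_id, "chrom"]
    pos = int(G.snpmap.loc[snp_id, "pos"])
    nearby = G.snpmap[
        (G.snpmap["chrom"] == chrom)
        & (G.snpmap["pos"] - pos).abs().le(window)
        & (G.snpmap.index != snp_id)
    ]
    focal = G.dosage[snp_id].to_numpy(dtype=float)
    linked = []
    for other in nearby.index:
        r2 = pairwise_r2(focal, G.dosage[other].to_numpy(dtype=float))
        if np.isfinite(r2) and r2 > r2_min:
            linked.append(other)
    if not linked:
        return None, []
    positions = [int(G.snpmap.loc[s, "pos"]) for s in linked] + [pos]
    return (min(positions), max(positions)), linked


def assign_genes(
    snp_id: str,
    interval,
    annotation: GeneAnnotation,
    snpmap: pd.DataFrame,
    flank: int = 10000,
) -> CandidateAssignment:
    """Candidate genes for one SNP from its LD interval (or closest-gene
    fallback).

    With an LD interval, the query is the interval expanded to at least
    +/- ``flank`` around the focal SNP; every gene whose promoter-extended
    model overlaps it is a candidate. Without one, the single gene with the
    nearest extended-model boundary is chosen (distance 0 when the SNP lies
    inside); equidistant genes are all reported with ``tie=True``.
    """
    chrom = int(snpmap.loc[snp_id, "chrom"])
    pos = int(snpmap.loc[snp_id, "pos"])
    models = [m for m in gene_models(annotation).values() if m.chrom == chrom]
    if not models:
        raise ValueError(f"annotation has no genes on chromosome {chrom}")
    if interval is not None:
        lo = min(interval[0], pos - flank)
        hi = max(interval[1], pos + flank)
        hits = [
            m.gene_id
            for m in sorted(models, key=lambda m: m.extended_span)
            if m.extended_span[0] <= hi and m.extended_span[1] >= lo
        ]
        return CandidateAssignment(snp_id, tuple(interval), [], hits, fallback_used=False)
    dists = {}
    for m in models:
        s, e = m.extended_span
        dists[m.gene_id] = 0 if s <= pos <= e else min(abs(pos - s), abs(pos - e))
    dmin = min(dists.values())
    nearest = sorted(g for g, d in dists.items() if d == dmin)
    return CandidateAssignment(
        snp_id, None, [], nearest, fallback_used=True, tie=len(nearest) > 1
    )


def _relation(model: GeneModel, pos: int) -> str:
    for name, iv in (
        ("promoter", model.promoter_interval),
        ("utr5", model.utr5_interval),
        ("orf", model.orf_interval),
        ("utr3", model.utr3_interval),
    ):
        if iv[0] <= pos <= iv[1]:
            return name
    return "linked"


def candidate_gene_table(
    snp_ids,
    G: Genotypes,
    annotation: GeneAnnotation,
    window: int = 10000,
    r2_min: float = 0.80,
    flank: int = 10000,
) -> pd.DataFrame:
    """Full candidate table for a set of associated SNPs.

    One row per (SNP, gene) with the LD span, the SNP's relation to the
    gene model (promoter/utr5/orf/utr3, else linked/closest) and whether
    the closest-gene fallback was used.
    """
    models = gene_models(annotation)
    rows = []
    for snp in snp_ids:
        interval, linked = ld_interval(snp, G, window=window, r2_min=r2_min)
        assignment = assign_genes(snp, interval, annotation, G.snpmap, flank=flank)
        assignment.linked_snp_ids = linked
        pos = int(G.snpmap.loc[snp, "pos"])
        for gene in assignment.gene_ids:
            rel = _relation(models[gene], pos)
            if assignment.fallback_used and rel == "linked":
                rel = "closest"
            rows.append(
                dict(
                    snp_id=snp,
                    ld_start=None if assignment.ld_interval is None else assignment.ld_interval[0],
                    ld_end=None if assignment.ld_interval is None else assignment.ld_interval[1],
                    gene_id=gene,
                    relation=rel,
                    fallback=assignment.fallback_used,
                    tie=assignment.tie,
                )
            )
    return pd.DataFrame(rows, columns=["snp_id", "ld_start", "ld_end", "gene_id", "relation", "fallback", "tie"])
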