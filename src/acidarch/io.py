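"""Reading and writing the pipeline's plain-text fixture formats.

Genotypes travel as VCF 4.2 (homozygous diploid GT, ``0/0`` / ``1/1`` /
``./.``, so any standard VCF reader recovers the same dosage matrix) or as
a simple accessions x SNPs CSV. Phenotypes, expression, SNP maps and gene
models are CSV; promoter alignments are FASTA.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import GeneAnnotation, Genotypes

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotypes_csv",
    "read_genotypes_csv",
    "write_gene_annotation",
    "read_gene_annotation",
    "write_alignment_fasta",
    "read_alignment_fasta",
    "write_fixture_set",
    "read_fixture_set",
]


def write_vcf(G: Genotypes, path) -> None:
    """Write the panel as uncompressed VCF 4.2 with homozygous diploid GT."""
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##source=acidarch\n')
            for chrom in sorted(G.snpmap["chrom"].unique()):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            samples = "\t".join(G.accessions)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
            dosage = G.values()
            for j, snp_id in enumerate(G.snp_ids):
                chrom = G.snpmap.iloc[j]["chrom"]
                pos = G.snpmap.iloc[j]["pos"]
                calls = []
                for v in dosage[:, j]:
                    if np.isnan(v):
                        calls.append("./.")
                    elif v >= 0.5:
                        calls.append("1/1")
                    else:
                        calls.append("0/0")
                fh.write(
                    f"{chrom}\t{int(pos)}\t{snp_id}\tA\tT\t.\tPASS\t.\tGT\t"
                    + "\t".join(calls)
                    + "\n"
                )
    except OSError as exc:
        raise OSError(f"failed writing VCF to {path}: {exc}") from exc


def read_vcf(path) -> Genotypes:
    """Read a VCF written by :func:`write_vcf` (plain-text parser)."""
    samples: list[str] = []
    snp_rows = []
    dosages = []
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    samples = fields[9:]
                    continue
                chrom, pos, snp_id = fields[0], int(fields[1]), fields[2]
                snp_rows.append((snp_id, int(chrom), pos))
                row = []
                for call in fields[9:]:
                    gt = call.split(":")[0]
                    if gt in ("./.", "."):
                        row.append(np.nan)
                    else:
                        alleles = gt.replace("|", "/").split("/")
                        row.append(float(np.mean([int(a) for a in alleles])))
                dosages.append(row)
    except OSError as exc:
        raise OSError(f"failed reading VCF from {path}: {exc}") from exc
    snpmap = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"]).set_index("snp_id")
    dosage = pd.DataFrame(
        np.asarray(dosages, dtype=float).T, index=pd.Index(samples, name="accession"),
        columns=snpmap.index,
    )
    return Genotypes(dosage, snpmap)


def write_genotypes_csv(G: Genotypes, geno_path, snpmap_path) -> None:
    G.dosage.rename_axis("accession").to_csv(geno_path)
    G.snpmap.rename_axis("snp_id").to_csv(snpmap_path)


def read_genotypes_csv(geno_path, snpmap_path) -> Genotypes:
    dosage = pd.read_csv(geno_path, index_col=0)
    dosage.index.name = "accession"
    snpmap = pd.read_csv(snpmap_path, index_col=0)
    return Genotypes(dosage, snpmap)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    table = annotation.table.copy()
    # chromosome lengths ride along as a sidecar column for round-tripping
    table["chrom_length"] = table["chrom"].map(annotation.chrom_lengths)
    table.rename_axis("gene_id").to_csv(path)


def read_gene_annotation(path) -> GeneAnnotation:
    table = pd.read_csv(path, index_col=0)
    chrom_lengths = (
        table.groupby("chrom")["chrom_length"].first().astype(int).to_dict()
    )
    return GeneAnnotation(table.drop(columns=["chrom_length"]), chrom_lengths)


def write_alignment_fasta(records, path) -> None:
    """``records``: iterable of (accession_id, aligned_sequence)."""
    seqs = [SeqRecord(Seq(s), id=a, description="") for a, s in records]
    SeqIO.write(seqs, path, "fasta")


def read_alignment_fasta(path):
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def write_fixture_set(
    outdir,
    G: Genotypes,
    phenotypes: pd.DataFrame,
    expression: pd.Series | None = None,
    annotation: GeneAnnotation | None = None,
    alignment=None,
    truth=None,
    vcf: bool = True,
) -> None:
    """Write the full fixture directory consumed by the analysis scripts."""
    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(outdir, name)
    if vcf:
        write_vcf(G, join("genotypes.vcf"))
    write_genotypes_csv(G, join("genotypes.csv"), join("snpmap.csv"))
    phenotypes.to_csv(join("phenotypes.csv"), index=False)
    if expression is not None:
        expression.rename_axis("accession").to_frame().to_csv(join("expression.csv"))
    if annotation is not None:
        write_gene_annotation(annotation, join("genes.csv"))
    if alignment is not None:
        write_alignment_fasta(alignment, join("promoter_alignment.fasta"))
    if truth is not None:
        truth.to_json(join("truth.json"))


def read_fixture_set(outdir):
    """Read back a fixture directory; returns a dict of loaded pieces."""
    from .synthetic_data import SimulationTruth

    join = lambda name: os.path.join(outdir, name)
    out = {}
    if os.path.exists(join("genotypes.csv")):
        out["genotypes"] = read_genotypes_csv(join("genotypes.csv"), join("snpmap.csv"))
    elif os.path.exists(join("genotypes.vcf")):
        out["genotypes"] = read_vcf(join("genotypes.vcf"))
    if os.path.exists(join("phenotypes.csv")):
        out["phenotypes"] = pd.read_csv(join("phenotypes.csv"))
    if os.path.exists(join("expression.csv")):
        out["expression"] = pd.read_csv(join("expression.csv"), index_col=0)["expression"]
    if os.path.exists(join("genes.csv")):
        out["annotation"] = read_gene_annotation(join("genes.csv"))
    if os.path.exists(join("promoter_alignment.fasta")):
        out["alignment"] = read_alignment_fasta(join("promoter_alignment.fasta"))
    if os.path.exists(join("truth.json")):
        out["truth"] = SimulationTruth.from_json(join("truth.json"))
    return out
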