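#!/usr/bin/env python
"""Generate the two study panels and write them as plain-text fixtures.

Simulates an aluminum-tolerance-like panel (oligogenic architecture with two
rare loss-of-function carriers) and a proton-tolerance-like panel (polygenic
architecture) over the same genotype background style: ~200 inbred
accessions, 6 admixed subpopulations, block-structured LD. Writes
genotypes (VCF + CSV), the SNP map, replicated root-length phenotypes,
gene models, a promoter alignment, expression, and the simulation truth
under results/fixtures/<preset>/.
"""

import argparse
import os

from acidarch import io
from acidarch.synthetic_data import (
    ArchitectureConfig,
    PopulationConfig,
    simulate_expression,
    simulate_gene_annotation,
    simulate_phenotypes,
    simulate_population,
    simulate_promoter_alignment,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=200, help="accessions")
    ap.add_argument("--m", type=int, default=8000, help="SNPs")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/fixtures")
    args = ap.parse_args()

    for preset, label in (("oligogenic_rare", "al"), ("polygenic", "proton")):
        cfg = PopulationConfig(
            n_accessions=args.n, n_snps=args.m, seed=args.seed, missing_rate=0.02
        )
        G, true_q = simulate_population(cfg)
        maker = (
            ArchitectureConfig.oligogenic_rare
            if preset == "oligogenic_rare"
            else ArchitectureConfig.polygenic
        )
        arch = maker(seed=args.seed + 1)
        phenotypes, truth = simulate_phenotypes(G, arch)
        truth.true_Q = true_q
        annotation = simulate_gene_annotation(G.snpmap, seed=args.seed + 2)
        # expression driven by the strongest QTL as its own cis regulator
        cis = truth.qtl_snp_ids[0]
        truth.cis_eqtl_snp, truth.cis_eqtl_effect = cis, 1.0
        expression = simulate_expression(
            G, cis, effect=1.0, noise_sd=0.5, seed=args.seed + 3
        )
        alignment, _ = simulate_promoter_alignment(seed=args.seed + 4)
        outdir = os.path.join(args.out, label)
        io.write_fixture_set(
            outdir, G, phenotypes,
            expression=expression, annotation=annotation,
            alignment=alignment, truth=truth,
        )
        carriers = ", ".join(truth.rare_carrier_ids) or "none"
        print(f"[{label}] wrote {outdir}: {G.n_accessions} accessions x "
              f"{G.n_snps} SNPs, {len(truth.qtl_snp_ids)} QTL, "
              f"rare carriers: {carriers}")


if __name__ == "__main__":
    main()
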