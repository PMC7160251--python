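#!/usr/bin/env python
"""Phenotype statistics for both simulated stress traits.

Computes relative root length (RRL) per accession, broad-sense heritability
and coefficient of variation for the aluminum-like and proton-like traits,
and runs subpopulation permutation tests with boxplot outlier calls against
the simulated ancestry. Writes results/phenotypes/<label>_rrl.csv and a
summary JSON.
"""

import argparse
import json
import os

from acidarch import phenotype_stats as phs
from acidarch.synthetic_data import (
    ArchitectureConfig,
    PopulationConfig,
    simulate_phenotypes,
    simulate_population,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=200)
    ap.add_argument("--m", type=int, default=8000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/phenotypes")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    cfg = PopulationConfig(n_accessions=args.n, n_snps=args.m, seed=args.seed)
    G, true_q = simulate_population(cfg)
    subpop = true_q.idxmax(axis=1)

    summary = {}
    for preset, label in (("oligogenic_rare", "al"), ("polygenic", "proton")):
        maker = (
            ArchitectureConfig.oligogenic_rare
            if preset == "oligogenic_rare"
            else ArchitectureConfig.polygenic
        )
        pheno, truth = simulate_phenotypes(G, maker(seed=args.seed + 1))
        tab = phs.rrl_table(pheno, stress="stress")
        ts = phs.trait_summary(tab)
        tests = phs.subpop_tests(tab["rrl"], subpop.loc[tab.index], n_perm=2000, seed=args.seed)
        tab.to_csv(os.path.join(args.out, f"{label}_rrl.csv"))
        tests.drop(columns=["outliers"]).to_csv(os.path.join(args.out, f"{label}_subpops.csv"))
        summary[label] = {
            "h_b2": round(ts.h_b2, 3),
            "cv_percent": round(ts.cv, 1),
            "n_accessions": ts.n_accessions,
            "significant_subpops": [str(i) for i in tests.index[tests["p_value"] < 0.05]],
            "outliers_per_subpop": {str(i): len(o) for i, o in tests["outliers"].items()},
        }
        print(f"[{label}] H_b2={ts.h_b2:.3f} CV={ts.cv:.1f}% "
              f"subpops deviating at p<0.05: {summary[label]['significant_subpops']}")
    with open(os.path.join(args.out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)


if __name__ == "__main__":
    main()
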