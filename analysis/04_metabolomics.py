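#!/usr/bin/env python
"""Plasma metabolomics: differential abundance, pathway enrichment, and
the metabolite-enzyme network mapping.

Welch t-tests per metabolite (30 vs 12 subjects at the default scale),
hypergeometric pathway enrichment with the p < 0.05 & fold-enrichment > 1
dysregulation rule, and extraction of connected dysregulated components
around significant enzymes and metabolites in the bipartite reaction
network. Requires 01 and 02 to have run into the same --out directory.
"""

import argparse
from pathlib import Path

import pandas as pd

from pahomics import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = pipeline.load_config({"seed": args.seed})
    pipeline.run_metabolomics_stage(config, args.out)

    diff = pd.read_csv(args.out / "metab" / "metabolite_de.tsv", sep="\t")
    enrich = pd.read_csv(args.out / "metab" / "enrichment.tsv", sep="\t")
    comps = pd.read_csv(args.out / "metab" / "dysregulated_components.tsv",
                        sep="\t")
    n_sig = int((diff["direction"] != "ns").sum())
    n_up = int((diff["direction"] == "up").sum())
    print(f"metabolome: {len(diff)} measured, {n_sig} significantly altered "
          f"({n_up} up, {n_sig - n_up} down)")
    flagged = enrich[enrich["dysregulated"]]
    print(f"enrichment: {len(flagged)} of {len(enrich)} pathways "
          f"dysregulated (p < 0.05, fold enrichment > 1):")
    for _, row in flagged.iterrows():
        print(f"  {row.pathway}: {row.k}/{row.m} significant, "
              f"fold {row.fold_enrichment:.2f}, p = {row.p:.3g}")
    if len(comps):
        top = comps.iloc[0]
        print(f"metabolite-enzyme mapping: {len(comps)} dysregulated "
              f"component(s); largest holds {top.n_significant} significant "
              f"of {top['size']} nodes")


if __name__ == "__main__":
    main()
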