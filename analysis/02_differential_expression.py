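#!/usr/bin/env python
"""Differential proteome and phosphoproteome analysis.

Normalizes (median-ratio calibration + glog2), imputes missing values by
feature-wise kNN, applies the empirical-Bayes moderated t-test with BH FDR,
and classifies features as up/down/ns. Phosphosites are first filtered at
the >50% localization threshold and the S/T/Y residue tally reported.
Requires 01_simulate_inputs.py to have run into the same --out directory.
"""

import argparse
from pathlib import Path

import pandas as pd

from pahomics import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--rule", choices=["raw_p", "fdr"], default="raw_p")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    config = pipeline.load_config(
        {"seed": args.seed, "de": {"rule": args.rule, "alpha": args.alpha}})
    pipeline.run_de_proteome(config, args.out)
    pipeline.run_de_phospho(config, args.out)

    prot = pd.read_csv(args.out / "de" / "proteome_de.tsv", sep="\t")
    phos = pd.read_csv(args.out / "de" / "phospho_de.tsv", sep="\t")
    tally = pd.read_csv(args.out / "de" / "residue_tally.tsv", sep="\t")
    n_up = int((prot["direction"] == "up").sum())
    n_down = int((prot["direction"] == "down").sum())
    print(f"proteome: {len(prot)} quantified, {n_up + n_down} differential "
          f"({n_up} up, {n_down} down; {args.rule} < {args.alpha})")
    p_up = int((phos["direction"] == "up").sum())
    p_down = int((phos["direction"] == "down").sum())
    print(f"phosphoproteome: {len(phos)} localized peptides, "
          f"{p_up + p_down} differential ({p_up} up, {p_down} down)")
    print("phosphosite residue tally (of localized sites):")
    for _, row in tally.iterrows():
        print(f"  {row.residue}: {row['count']:5d} ({row.percent}%)")


if __name__ == "__main__":
    main()
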