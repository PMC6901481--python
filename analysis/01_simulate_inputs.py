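#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes the desk-scale interactome, the 4-vs-5 proteome and phosphoproteome
matrices (with MNAR missingness and planted, network-proximal differential
sets), the plasma metabolome with pathway annotations, the enzyme-metabolite
reaction table and the glucose dose-response assay tables under
<out>/sim/. Run this before the numbered analysis scripts.
"""

import argparse
from pathlib import Path

from pahomics import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    config = pipeline.load_config({"seed": args.seed})
    written = pipeline.simulate_inputs(config, args.out)
    print(f"simulated inputs for seed {args.seed}:")
    for path in written:
        print(f"  {path}")


if __name__ == "__main__":
    main()
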