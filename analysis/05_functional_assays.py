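#!/usr/bin/env python
"""Functional bioenergetics assay statistics.

Exact Wilcoxon rank-sum comparison of basal OCR between case and control
cell lines, and the subject-level bootstrap comparison of glucose
dose-response AUCs for OCR and ECAR. Requires 01_simulate_inputs.py to
have run into the same --out directory.
"""

import argparse
import json
from pathlib import Path

from pahomics import pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--n-boot", type=int, default=10000)
    args = ap.parse_args()

    config = pipeline.load_config(
        {"seed": args.seed, "assays": {"n_boot": args.n_boot}})
    pipeline.run_assays_stage(config, args.out)

    res = json.loads((args.out / "assays" / "assays.json").read_text())
    basal = res["basal_ocr"]
    print(f"basal OCR: control {basal['control_mean']:.1f} vs case "
          f"{basal['case_mean']:.1f} pmol O2/min, Wilcoxon p = "
          f"{basal['p']:.3g}")
    for measure in ("ocr", "ecar"):
        auc = res[f"auc_{measure}"]
        print(f"{measure.upper()} dose-response AUC shift "
              f"(case - control): {auc['delta_auc']:.1f}, bootstrap p = "
              f"{auc['p']:.3g} ({auc['n_boot']} resamples)")


if __name__ == "__main__":
    main()
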