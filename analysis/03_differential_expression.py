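#!/usr/bin/env python
"""NB Wald differential expression for the four contiguous progression
contrasts (NT-I, I-II, II-III, III-IV) and the four NT-vs-stage contrasts,
with the study thresholds (genes: |log2FC| > 1, BH p < 1e-5; miRs:
|log2FC| > 0.5, raw p < 1e-5).  Prints the per-contrast DEG/DEM counts."""

import argparse
from pathlib import Path

import pandas as pd

from mirgenet import pipeline as pl
from mirgenet.config import PipelineConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    pl.stage_de(PipelineConfig(seed=args.seed), args.out)
    print("contrast        over_g under_g over_m under_m")
    for label in ("NT-I", "I-II", "II-III", "III-IV"):
        g = pd.read_csv(args.out / "de" / f"genes_contiguous_{label}.tsv",
                        sep="\t", comment="#")
        m = pd.read_csv(args.out / "de" / f"mirs_contiguous_{label}.tsv",
                        sep="\t", comment="#")
        print(f"{label:<15} {(g.status == 'over').sum():6d} "
              f"{(g.status == 'under').sum():7d} {(m.status == 'over').sum():6d} "
              f"{(m.status == 'under').sum():7d}")


if __name__ == "__main__":
    main()
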