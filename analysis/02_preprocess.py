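#!/usr/bin/env python
"""Apply the feature filters (annotation presence, >50% zeros, mean < 10)
to the raw count matrices and report the removal accounting."""

import argparse
import json
from pathlib import Path

from mirgenet import pipeline as pl
from mirgenet.config import PipelineConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    pl.stage_preprocess(PipelineConfig(seed=args.seed), args.out)
    for kind in ("genes", "mirs"):
        rep = json.loads((args.out / "preprocess" / f"filter_report_{kind}.json").read_text())
        print(f"{kind}: {rep['n_input']} -> {rep['n_kept']} kept "
              f"(unannotated {rep['n_removed_unannotated']}, "
              f"high-zero {rep['n_removed_zeros']}, "
              f"low-mean {rep['n_removed_low_mean']})")


if __name__ == "__main__":
    main()
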