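#!/usr/bin/env python
"""Infer the five per-phenotype bipartite miR-gene networks: all-pairs
mutual information on rank-binned normalized expression, then top-K
retention.  Also writes the four canonical (opposite-sign filtered)
networks keyed to each stage's contiguous contrast."""

import argparse
from pathlib import Path

from mirgenet import pipeline as pl
from mirgenet.config import PipelineConfig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = PipelineConfig(seed=args.seed)
    series = pl.stage_network_and_filter(cfg, args.out)
    print(f"top-K networks: { {p: len(n) for p, n in series.topk.items()} }")
    print(f"canonical networks: { {s: len(n) for s, n in series.canonical.items()} }")


if __name__ == "__main__":
    main()
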