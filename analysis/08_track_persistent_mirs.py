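#!/usr/bin/env python
"""Find miRs differentially expressed in every contiguous contrast and
report their stage-specific canonical targets and target turnover."""

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

    cfg = PipelineConfig(seed=args.seed)
    series = pl.stage_network_and_filter(cfg, args.out)
    pl.stage_track(cfg, args.out, series)
    pl.write_manifest(cfg, args.out)

    report = json.loads((args.out / "track" / "trajectories.json").read_text())
    if not report:
        print("no persistently differentially expressed miR found")
        return
    for mir, info in report.items():
        print(f"persistent miR {mir}:")
        for label, stats in info["contrasts"].items():
            print(f"  {label:>7}: log2FC {stats['log2fc']:+.3f} "
                  f"p {stats['p']:.2e} ({stats['status']})")
        for stage, targets in info["stage_targets"].items():
            mean = info["mean_target_log2fc"].get(stage)
            mean_txt = f" (mean target log2FC {mean:+.3f})" if mean is not None else ""
            print(f"  stage {stage}: targets {sorted(targets) or '-'}{mean_txt}")


if __name__ == "__main__":
    main()
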