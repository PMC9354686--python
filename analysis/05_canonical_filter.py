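#!/usr/bin/env python
"""Check the canonical (opposite-sign) filter output written by the
network step: every stage network's canonical subset, its size, and the
soundness invariants (canonical is a subset of top-K; every retained edge
joins an overexpressed miR with an underexpressed gene or vice versa)."""

import argparse
from pathlib import Path

import pandas as pd

from mirgenet.io_formats import read_de_table, read_edges


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    contrasts = {"I": "NT-I", "II": "I-II", "III": "II-III", "IV": "III-IV"}
    for stage, label in contrasts.items():
        topk = read_edges(args.out / "network" / f"topk_{stage}.tsv", stage, filtered="topk")
        canon = read_edges(args.out / "filter" / f"canonical_{stage}.tsv", stage,
                           filtered="canonical")
        genes = read_de_table(args.out / "de" / f"genes_contiguous_{label}.tsv")
        mirs = read_de_table(args.out / "de" / f"mirs_contiguous_{label}.tsv")
        assert canon.edge_set() <= topk.edge_set()
        for mir, gene in canon.edge_set():
            pair = {mirs.loc[mir, "status"] if mir in mirs.index else "ns",
                    genes.loc[gene, "status"] if gene in genes.index else "ns"}
            assert pair == {"over", "under"}, (stage, mir, gene)
        print(f"stage {stage} ({label}): {len(canon)} canonical of {len(topk)} "
              "top-K edges; soundness invariants hold")


if __name__ == "__main__":
    main()
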