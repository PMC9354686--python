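#!/usr/bin/env python
"""Compare the five top-K networks: exclusive intersection (UpSet) counts,
per-network uniqueness fractions, the tumor-shared-not-control edge set,
and an UpSet-style figure.  Reads the edge lists written by the network
step and writes the comparison artifacts under <out>/compare/."""

import argparse
import json
from pathlib import Path

import pandas as pd

from mirgenet.io_formats import STAGE_ORDER, BipartiteNetwork, read_edges, write_edges, write_json
from mirgenet.netcompare import (
    intersection_counts,
    plot_intersections,
    uniqueness_fraction,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()

    nets = [read_edges(args.out / "network" / f"topk_{p}.tsv", p, filtered="topk")
            for p in STAGE_ORDER]
    table = intersection_counts(nets)
    uniq = {n.phenotype: uniqueness_fraction(n, [m for m in nets if m is not n])
            for n in nets}

    by_phen = {n.phenotype: n.edge_set() for n in nets}
    shared = frozenset.intersection(*(by_phen[s] for s in STAGE_ORDER[1:]))
    shared -= by_phen["NT"]
    shared_net = BipartiteNetwork(
        phenotype="tumor_shared",
        edges=pd.DataFrame([(m, g, 0.0) for m, g in sorted(shared)],
                           columns=["mir_id", "gene_id", "mi"]),
        filtered="topk",
    )

    cd = args.out / "compare"
    cd.mkdir(parents=True, exist_ok=True)
    table.to_dataframe().to_csv(cd / "intersections.tsv", sep="\t", index=False)
    write_json({"&".join(sorted(k)): v for k, v in table.exclusive.items()},
               cd / "intersections.json")
    write_json(uniq, cd / "uniqueness.json")
    write_edges(shared_net, cd / "tumor_shared.tsv")
    plot_intersections(table, cd / "upset.png")

    print(f"union of all edges: {table.union_size()}")
    print("uniqueness fraction per network:",
          {k: round(v, 3) for k, v in uniq.items()})
    print(f"edges shared by all four stages but absent from NT: {len(shared)}")
    for mir, gene in sorted(shared):
        print(f"  {mir} -- {gene}")


if __name__ == "__main__":
    main()
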