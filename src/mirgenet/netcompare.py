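"""Set-algebra comparison of the per-phenotype networks.

Edges are keyed by (miR id, gene id); MI scores are ignored.  The
intersection table gives, for every non-empty subset S of the network
labels, the *exclusive* count |edges present in exactly the networks of
S| - the quantity drawn by an UpSet plot.  Exclusive counts over all
subsets sum to the size of the union, and each network's total is the sum
of exclusive counts over subsets containing it.

Also provided: the tumor-shared-not-control edge set (edges present in all
four stage networks but absent from NT) and per-network uniqueness
fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import STAGE_ORDER, BipartiteNetwork
from .stagenet import StageSeries

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class IntersectionTable:
    """Exclusive intersection counts over every non-empty label subset."""

    labels: list[str]
    exclusive: dict[frozenset, int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    def count(self, labels: Iterable[str]) -> int:
        return self.exclusive.get(frozenset(labels), 0)

    def union_size(self) -> int:
        return sum(self.exclusive.values())

    def to_dataframe(self) -> pd.DataFrame:
        """Deterministic layout: subsets by size, then by label order."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        rows = []
        for size in range(1, len(self.labels) + 1):
            for combo in combinations(self.labels, size):
                key = frozenset(combo)
                rows.append(
                    {"subset": "&".join(sorted(combo, key=pos.get)),
                     "size": size,
                     "exclusive_count": self.exclusive.get(key, 0)}
                )
        return pd.DataFrame(rows)

    def check(self, union_size: int) -> None:
        assert self.union_size() == union_size
        for lab in self.labels:
            total = sum(c for s, c in self.exclusive.items() if lab in s)
            assert total == self.totals[lab], f"total mismatch for {lab}"


def intersection_counts(nets: Sequence[BipartiteNetwork]) -> IntersectionTable:
    """Exact exclusive-membership decomposition of >= 2 networks (<= 12)."""
    if len(nets) < 2:
        raise ValueError("need at least 2 networks")
    if len(nets) > 12:
        raise ValueError("at most 12 networks (2^n subsets must stay enumerable)")
    labels = [n.phenotype for n in nets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate network labels in {labels}")
    sets = {n.phenotype: n.edge_set() for n in nets}
    membership: dict[Edge, frozenset] = {}
    for lab, edges in sets.items():
        for e in edges:
            membership[e] = membership.get(e, frozenset()) | {lab}
    table = IntersectionTable(labels=labels)
    for subset in membership.values():
        table.exclusive[subset] = table.exclusive.get(subset, 0) + 1
    table.totals = {lab: len(edges) for lab, edges in sets.items()}
    table.check(len(membership))
    return table


def tumor_shared_not_control(
    series: StageSeries, level: str = "topk"
) -> frozenset[Edge]:
    """Edges in all four stage networks but not in NT, at the given level.

    ``level`` is "topk" or "canonical"; NT has no canonical network, so at
    canonical level the NT exclusion still uses NT's top-K edges.
    """
    if level not in ("topk", "canonical"):
        raise ValueError(f"level must be 'topk' or 'canonical', got {level!r}")
    stages = STAGE_ORDER[1:]
    if level == "topk":
        stage_sets = [series.topk[s].edge_set() for s in stages]
    else:
        stage_sets = [series.canonical[s].edge_set() for s in stages]
    shared = frozenset.intersection(*stage_sets)
    return shared - series.topk["NT"].edge_set()


def uniqueness_fraction(
    net: BipartiteNetwork, others: Sequence[BipartiteNetwork]
) -> float:
    """Fraction of a network's edges found in no other network (0/0 -> 0)."""
    own = net.edge_set()
    if not own:
        logger.warning("uniqueness of an empty network is defined as 0")
        return 0.0
    rest: set[Edge] = set()
    for other in others:
        rest |= other.edge_set()
    return len(own - rest) / len(own)


def plot_intersections(table: IntersectionTable, path) -> None:
    """Optional UpSet-style bar chart of the non-zero exclusive counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.to_dataframe()
    df = df[df["exclusive_count"] > 0].sort_values(
        ["size", "exclusive_count"], ascending=[True, False]
    )
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(df)), 4))
    ax.bar(range(len(df)), df["exclusive_count"], color="#444444")
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["subset"], rotation=90, fontsize=7)
    ax.set_yscale("log")
    ax.set_ylabel("exclusive edge count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
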