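"""Tracking of persistently differentially expressed miRs and their
stage-specific canonical targets.

A miR is *persistent* when its DE status is over or under in every one of
the four contiguous contrasts (NT-I, I-II, II-III, III-IV).  Persistence
does not require a constant sign: the motivating exemplar flips from
under- to overexpression mid-course.  For each persistent miR the
trajectory records the per-contrast log2 fold change, p-value and status,
and the miR's canonical targets in each stage network (genes connected to
it in that stage's opposite-sign-filtered network), with the target's own
log2 fold change from the same contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import STAGE_ORDER
from .stagenet import StageSeries

STAGES = STAGE_ORDER[1:]


@dataclass
class MirTrajectory:
    """One miR's DE course across contiguous contrasts plus per-stage targets.

    ``contrast_stats`` maps contrast label -> (log2fc, p, status); ``stage
    _targets`` maps stage -> {gene id: gene log2fc}.
    """

    mir_id: str
    contrast_stats: dict[str, tuple[float, float, str]] = field(default_factory=dict)
    stage_targets: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def persistent(self) -> bool:
        if len(self.contrast_stats) < 4:
            return False
        return all(s[2] != "ns" for s in self.contrast_stats.values())

    def sign_pattern(self) -> tuple[str, ...]:
        return tuple(s[2] for s in self.contrast_stats.values())

    def n_targets(self) -> dict[str, int]:
        return {stage: len(self.stage_targets.get(stage, {})) for stage in STAGES}

    def mean_target_log2fc(self, stage: str) -> float:
        targets = self.stage_targets.get(stage, {})
        if not targets:
            return float("nan")
        return float(np.mean(list(targets.values())))


def persistent_de_mirs(series: StageSeries) -> list[MirTrajectory]:
    """Trajectories of every miR with non-ns status in all four contiguous
    contrasts, each carrying its per-stage canonical target sets."""
    labels = [series.contrasts[s].label for s in STAGES]
    status_tables = {lab: series.de_mirs[lab].table for lab in labels}
    common = set(status_tables[labels[0]].index)
    for lab in labels[1:]:
        common &= set(status_tables[lab].index)

    trajectories = []
    for mir in sorted(common):
        stats = {}
        for lab in labels:
            row = status_tables[lab].loc[mir]
            use_adj = series.de_mirs[lab].params.get("use_adjusted", False)
            p = row["p_adj"] if use_adj else row["p_raw"]
            stats[lab] = (float(row["log2fc"]), float(p), str(row["status"]))
        if not all(s[2] != "ns" for s in stats.values()):
            continue
        traj = MirTrajectory(mir_id=mir, contrast_stats=stats)
        for stage in STAGES:
            net = series.canonical[stage]
            genes = net.edges.loc[net.edges["mir_id"] == mir, "gene_id"]
            gene_lfc = series.de_genes[series.contrasts[stage].label].table["log2fc"]
            traj.stage_targets[stage] = {
                g: float(gene_lfc.get(g, float("nan"))) for g in genes
            }
        trajectories.append(traj)
    return trajectories


def target_turnover(traj: MirTrajectory) -> pd.DataFrame:
    """Per-stage target counts with gained/lost sets vs the previous stage.

    The first stage reports all of its targets as gained.
    """
    rows = []
    prev: set[str] = set()
    for i, stage in enumerate(STAGES):
        current = set(traj.stage_targets.get(stage, {}))
        gained = current - prev if i > 0 else current
        lost = prev - current if i > 0 else set()
        rows.append(
            {
                "stage": stage,
                "n_targets": len(current),
                "n_gained": len(gained),
                "n_lost": len(lost),
                "gained": sorted(gained),
                "lost": sorted(lost),
            }
        )
        prev = current
    return pd.DataFrame(rows)


def trajectory_report(trajectories: list[MirTrajectory]) -> dict:
    """JSON-ready report of all persistent miRs."""
    report = {}
    for traj in trajectories:
        report[traj.mir_id] = {
            "contrasts": {
                lab: {"log2fc": lfc, "p": p, "status": status}
                for lab, (lfc, p, status) in traj.contrast_stats.items()
            },
            "stage_targets": {
                stage: targets for stage, targets in traj.stage_targets.items()
            },
            "n_targets": traj.n_targets(),
            "mean_target_log2fc": {
                stage: traj.mean_target_log2fc(stage)
                for stage in STAGES
                if traj.stage_targets.get(stage)
            },
        }
    return report


def trajectory_table(trajectories: list[MirTrajectory]) -> pd.DataFrame:
    """Flat TSV-ready table: one row per (miR, stage, target)."""
    rows = []
    for traj in trajectories:
        for stage, lab in zip(STAGES, traj.contrast_stats):
            lfc, p, status = traj.contrast_stats[lab]
            targets = traj.stage_targets.get(stage, {})
            if not targets:
                rows.append(
                    {"mir_id": traj.mir_id, "contrast": lab, "mir_log2fc": lfc,
                     "mir_status": status, "stage": stage, "target": "",
                     "target_log2fc": float("nan")}
                )
            for gene, glfc in sorted(targets.items()):
                rows.append(
                    {"mir_id": traj.mir_id, "contrast": lab, "mir_log2fc": lfc,
                     "mir_status": status, "stage": stage, "target": gene,
                     "target_log2fc": glfc}
                )
    return pd.DataFrame(
        rows,
        columns=["mir_id", "contrast", "mir_log2fc", "mir_status", "stage",
                 "target", "target_log2fc"],
    )
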