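"""File-level orchestration of the full analysis.

Each stage reads its inputs from and writes its outputs under a single
output directory, in the order: simulate (or load) -> preprocess -> de ->
network -> filter -> compare -> annotate -> track.  Every run finishes by
writing a reproducibility manifest (config snapshot, input checksums,
seed, per-stage counts, package version).  The stages are plain functions
so the CLI, the analysis scripts and the acceptance machinery share one
code path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .diffexpr import classify, contiguous_contrasts, nb_test, nt_vs_stage_contrasts
from .genomic import annotate_edges, colocation_summary
from .io_formats import (
    STAGE_ORDER,
    BipartiteNetwork,
    read_annotation,
    read_expression,
    read_sample_table,
    write_annotation,
    write_de_table,
    write_edges,
    write_expression,
    write_graphml,
    write_json,
    write_sample_table,
)
from .minet import MIEstimatorConfig
from .mirtrack import persistent_de_mirs, trajectory_report, trajectory_table
from .netcompare import (
    intersection_counts,
    tumor_shared_not_control,
    uniqueness_fraction,
)
from .preprocess import filter_features
from .stagenet import StageSeries, build_stage_series
from .synthetic_data import DEFAULT_STUDY_K, default_study, generate

logger = logging.getLogger(__name__)

DATA = "data"
PREP = "preprocess"
DE = "de"
NETWORK = "network"
FILTER = "filter"
COMPARE = "compare"
ANNOTATE = "annotate"
TRACK = "track"


class MissingInputError(FileNotFoundError):
    """A stage was invoked before the stage that produces its inputs."""


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingInputError(
            f"missing input {path}; run the producing subcommand first"
        )
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    """Generate the default synthetic study and write its artifacts."""
    sim = default_study(seed=cfg.seed)
    gene_mat, mir_mat, samples, annot, truth = generate(sim)
    d = outdir / DATA
    write_expression(gene_mat, d / "genes_raw.tsv")
    write_expression(mir_mat, d / "mirs_raw.tsv")
    write_sample_table(samples, d / "samples.tsv")
    write_annotation(annot, d / "annotation.tsv")
    truth.de_effects.to_csv(d / "truth_de_effects.tsv", sep="\t", index=False)
    truth.couplings.to_csv(d / "truth_couplings.tsv", sep="\t", index=False)
    write_json(
        {
            "persistent_mir": truth.persistent_mir,
            "persistent_targets": {k: sorted(v) for k, v in truth.persistent_targets().items()},
            "tumor_only_pairs": sorted(map(list, truth.tumor_only_pairs())),
        },
        d / "truth_summary.json",
    )
    logger.info("simulated %d genes x %d samples (seed %d)",
                gene_mat.n_features, gene_mat.n_samples, cfg.seed)


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    d = outdir / DATA
    genes = read_expression(_require(d / "genes_raw.tsv"), "gene")
    mirs = read_expression(_require(d / "mirs_raw.tsv"), "miR")
    annot = read_annotation(_require(d / "annotation.tsv"))
    pc = cfg.preprocess
    genes_f, rep_g = filter_features(
        genes, annot if pc.annotation_filter_genes else None,
        pc.max_zero_fraction, pc.min_mean,
    )
    mirs_f, rep_m = filter_features(
        mirs, annot if pc.annotation_filter_mirs else None,
        pc.max_zero_fraction, pc.min_mean,
    )
    p = outdir / PREP
    write_expression(genes_f, p / "genes_filtered.tsv")
    write_expression(mirs_f, p / "mirs_filtered.tsv")
    write_json(rep_g.to_dict(), p / "filter_report_genes.json")
    write_json(rep_m.to_dict(), p / "filter_report_mirs.json")


def _load_filtered(cfg: PipelineConfig, outdir: Path):
    p = outdir / PREP
    genes = read_expression(_require(p / "genes_filtered.tsv"), "gene")
    mirs = read_expression(_require(p / "mirs_filtered.tsv"), "miR")
    samples = read_sample_table(_require(outdir / DATA / "samples.tsv"))
    return genes, mirs, samples


def stage_de(cfg: PipelineConfig, outdir: Path) -> None:
    """All eight DE tables per feature kind: 4 contiguous + 4 NT-vs-stage."""
    genes, mirs, samples = _load_filtered(cfg, outdir)
    dd = outdir / DE
    dec = cfg.de
    for family, contrasts in (
        ("contiguous", contiguous_contrasts()),
        ("ntvs", nt_vs_stage_contrasts()),
    ):
        for contrast in contrasts:
            ref = samples.samples_for(contrast.reference)
            test = samples.samples_for(contrast.test)
            for kind, mat, (lfc, pthr, adj) in (
                ("genes", genes, (dec.gene_lfc, dec.gene_p, dec.gene_use_adjusted)),
                ("mirs", mirs, (dec.mir_lfc, dec.mir_p, dec.mir_use_adjusted)),
            ):
                res = classify(
                    nb_test(mat.subset_samples(ref), mat.subset_samples(test),
                            contrast, dec.dispersion_mode, dec.pseudocount),
                    lfc, pthr, adj,
                )
                write_de_table(
                    res.table, dd / f"{kind}_{family}_{contrast.label}.tsv",
                    contrast.label,
                )


def _effective_k(cfg: PipelineConfig) -> int:
    if cfg.k_override is not None:
        return cfg.k_override
    if cfg.use_default_study:
        return DEFAULT_STUDY_K
    return cfg.network.k


def _build_series(cfg: PipelineConfig, outdir: Path) -> StageSeries:
    genes, mirs, samples = _load_filtered(cfg, outdir)
    mcfg = MIEstimatorConfig(
        n_bins=cfg.network.n_bins,
        bias_correction=cfg.network.bias_correction,
        rank_transform=cfg.network.rank_transform,
    )
    return build_stage_series(
        genes, mirs, samples, mcfg, k=_effective_k(cfg),
        gene_thresholds=(cfg.de.gene_lfc, cfg.de.gene_p, cfg.de.gene_use_adjusted),
        mir_thresholds=(cfg.de.mir_lfc, cfg.de.mir_p, cfg.de.mir_use_adjusted),
        dispersion_mode=cfg.de.dispersion_mode,
    )


def stage_network_and_filter(cfg: PipelineConfig, outdir: Path) -> StageSeries:
    """Infer the five top-K networks and the four canonical networks."""
    series = _build_series(cfg, outdir)
    nd, fd = outdir / NETWORK, outdir / FILTER
    for phen, net in series.topk.items():
        write_edges(net, nd / f"topk_{phen}.tsv")
        write_graphml(net, nd / f"topk_{phen}.graphml")
    for stage, net in series.canonical.items():
        write_edges(net, fd / f"canonical_{stage}.tsv")
    manifest_counts = {
        "topk": {p: len(n) for p, n in series.topk.items()},
        "canonical": {s: len(n) for s, n in series.canonical.items()},
    }
    write_json(manifest_counts, fd / "edge_counts.json")
    return series


def stage_compare(cfg: PipelineConfig, outdir: Path, series: StageSeries) -> None:
    cd = outdir / COMPARE
    cd.mkdir(parents=True, exist_ok=True)
    level = cfg.compare.level
    nets = [series.topk[p] for p in STAGE_ORDER] if level == "topk" else (
        [series.canonical[s] for s in STAGE_ORDER[1:]]
    )
    table = intersection_counts(nets)
    table.to_dataframe().to_csv(cd / "intersections.tsv", sep="\t", index=False)
    write_json(
        {"&".join(sorted(k)): v for k, v in table.exclusive.items()},
        cd / "intersections.json",
    )
    shared = tumor_shared_not_control(series, level="topk")
    shared_net = BipartiteNetwork(
        phenotype="tumor_shared",
        edges=_edges_frame(series, shared),
        filtered="topk",
    )
    write_edges(shared_net, cd / "tumor_shared.tsv")
    uniq = {
        net.phenotype: uniqueness_fraction(net, [m for m in nets if m is not net])
        for net in nets
    }
    write_json(uniq, cd / "uniqueness.json")


def _edges_frame(series: StageSeries, edge_set):
    """Edge set -> frame with MI scores taken from stage I's top-K (or 0)."""
    import pandas as pd

    scores = {}
    for phen in STAGE_ORDER[1:]:
        for mir, gene, mi in series.topk[phen].edges.itertuples(index=False):
            scores.setdefault((mir, gene), mi)
    rows = [
        {"mir_id": m, "gene_id": g, "mi": scores.get((m, g), 0.0)}
        for m, g in sorted(edge_set)
    ]
    return pd.DataFrame(rows, columns=["mir_id", "gene_id", "mi"])


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> None:
    from .io_formats import read_edges

    annot = read_annotation(_require(outdir / DATA / "annotation.tsv"))
    shared = read_edges(_require(outdir / COMPARE / "tumor_shared.tsv"),
                        phenotype="tumor_shared", filtered="topk")
    annotated = annotate_edges(shared, annot)
    (outdir / ANNOTATE).mkdir(parents=True, exist_ok=True)
    annotated.to_csv(outdir / ANNOTATE / "tumor_shared_annotated.tsv",
                     sep="\t", index=False)
    write_json(colocation_summary(annotated).to_dict(),
               outdir / ANNOTATE / "colocation.json")


def stage_track(cfg: PipelineConfig, outdir: Path, series: StageSeries) -> None:
    trajectories = persistent_de_mirs(series)
    td = outdir / TRACK
    td.mkdir(parents=True, exist_ok=True)
    write_json(trajectory_report(trajectories), td / "trajectories.json")
    trajectory_table(trajectories).to_csv(td / "trajectories.tsv", sep="\t", index=False)


def write_manifest(cfg: PipelineConfig, outdir: Path, record_timestamp: bool = False) -> None:
    """Reproducibility manifest.

    The timestamp field is volatile and excluded from determinism
    comparisons; it is only filled when explicitly requested.
    """
    inputs = {}
    d = outdir / DATA
    if d.exists():
        for path in sorted(d.glob("*.tsv")):
            inputs[path.name] = _sha256(path)
    counts = {}
    ec = outdir / FILTER / "edge_counts.json"
    if ec.exists():
        counts = json.loads(ec.read_text())
    write_json(
        {
            "config": cfg.to_dict(),
            "input_checksums": inputs,
            "seed": cfg.seed,
            "edge_counts": counts,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat() if record_timestamp else None,
        },
        outdir / "manifest.json",
    )


def run_all(cfg: PipelineConfig, outdir: str | Path,
            record_timestamp: bool = False) -> StageSeries:
    """simulate -> preprocess -> de -> network -> filter -> compare ->
    annotate -> track -> manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.use_default_study:
        stage_simulate(cfg, outdir)
    stage_preprocess(cfg, outdir)
    stage_de(cfg, outdir)
    series = stage_network_and_filter(cfg, outdir)
    stage_compare(cfg, outdir, series)
    stage_annotate(cfg, outdir)
    stage_track(cfg, outdir, series)
    write_manifest(cfg, outdir, record_timestamp)
    return series
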