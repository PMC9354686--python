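"""Per-stage network assembly and the canonical (opposite-sign) filter.

For each of the five phenotypes a top-K MI network is inferred from that
phenotype's samples.  Each tumor stage s then gets a "canonical" network:
the subset of its top-K edges whose miR and gene have opposite
differential-expression status in the contiguous contrast ending at s
(NT-I for stage I, I-II for stage II, ...), i.e. overexpressed miR with
underexpressed gene or vice versa - the expression signature of canonical
miR-mediated repression.  The NT network has no preceding contrast and is
never canonically filtered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .diffexpr import (
    GENE_THRESHOLDS,
    MIR_THRESHOLDS,
    Contrast,
    DifferentialResult,
    classify,
    contiguous_contrasts,
    nb_test,
)
from .io_formats import STAGE_ORDER, BipartiteNetwork, ExpressionMatrix, SampleTable
from .minet import MIEstimatorConfig, all_pairs_mi, top_k
from .preprocess import normalize, size_factors

logger = logging.getLogger(__name__)


@dataclass
class StageSeries:
    """The full per-phenotype network family plus the DE results behind it.

    ``topk`` maps every phenotype to its top-K network; ``canonical`` maps
    each tumor stage to its opposite-sign-filtered network; ``contrasts``
    records which contiguous contrast keyed each stage's filter.
    """

    topk: dict[str, BipartiteNetwork] = field(default_factory=dict)
    canonical: dict[str, BipartiteNetwork] = field(default_factory=dict)
    contrasts: dict[str, Contrast] = field(default_factory=dict)
    de_genes: dict[str, DifferentialResult] = field(default_factory=dict)
    de_mirs: dict[str, DifferentialResult] = field(default_factory=dict)

    def check(self) -> None:
        for stage, net in self.canonical.items():
            assert net.edge_set() <= self.topk[stage].edge_set(), (
                f"canonical network of stage {stage} is not a subset of its top-K"
            )
            assert self.contrasts[stage].test == stage


def opposite_sign_filter(
    net: BipartiteNetwork,
    de_genes: DifferentialResult,
    de_mirs: DifferentialResult,
) -> BipartiteNetwork:
    """Keep edges whose endpoints have strictly opposite DE status.

    An edge survives iff (miR over and gene under) or (miR under and gene
    over).  Features missing from the DE tables count as ns.  MI scores are
    carried through unchanged; an empty result is legal.
    """
    gene_status = de_genes.status_map()
    mir_status = de_mirs.status_map()
    ms = net.edges["mir_id"].map(lambda m: mir_status.get(m, "ns"))
    gs = net.edges["gene_id"].map(lambda g: gene_status.get(g, "ns"))
    keep = ((ms == "over") & (gs == "under")) | ((ms == "under") & (gs == "over"))
    edges = net.edges[keep].reset_index(drop=True)
    if edges.empty:
        logger.info("canonical filter left no edges for phenotype %s", net.phenotype)
    return BipartiteNetwork(
        phenotype=net.phenotype, edges=edges, k=net.k, filtered="canonical"
    )


def build_stage_series(
    gene_mat: ExpressionMatrix,
    mir_mat: ExpressionMatrix,
    samples: SampleTable,
    cfg: MIEstimatorConfig | None = None,
    k: int = 100_000,
    gene_thresholds: tuple[float, float, bool] = GENE_THRESHOLDS,
    mir_thresholds: tuple[float, float, bool] = MIR_THRESHOLDS,
    dispersion_mode: str = "moments",
    min_samples: int = 4,
) -> StageSeries:
    """Run MI inference, top-K retention, DE and the canonical filter.

    ``gene_mat`` / ``mir_mat`` hold filtered raw counts over all samples.
    MI is computed on normalized expression (size factors over all samples
    of each matrix); the NB tests use raw counts with contrast-local joint
    size factors.  Every phenotype must have at least ``min_samples``
    samples.
    """
    cfg = cfg or MIEstimatorConfig()
    for phen in STAGE_ORDER:
        n = len(samples.samples_for(phen))
        if n < min_samples:
            raise ValueError(f"phenotype {phen} has {n} samples; need >= {min_samples}")

    genes_norm = normalize(gene_mat, size_factors(gene_mat, allow_total_fallback=True))
    mirs_norm = normalize(mir_mat, size_factors(mir_mat, allow_total_fallback=True))

    series = StageSeries()
    for phen in STAGE_ORDER:
        ids = samples.samples_for(phen)
        raw_net = all_pairs_mi(
            mirs_norm.subset_samples(ids), genes_norm.subset_samples(ids),
            cfg, phenotype=phen,
        )
        series.topk[phen] = top_k(raw_net, k)
        logger.info("phenotype %s: %d candidate pairs -> top %d",
                    phen, len(raw_net), len(series.topk[phen]))

    for contrast in contiguous_contrasts():
        ref_ids = samples.samples_for(contrast.reference)
        test_ids = samples.samples_for(contrast.test)
        de_g = classify(
            nb_test(gene_mat.subset_samples(ref_ids), gene_mat.subset_samples(test_ids),
                    contrast, dispersion_mode),
            *gene_thresholds,
        )
        de_m = classify(
            nb_test(mir_mat.subset_samples(ref_ids), mir_mat.subset_samples(test_ids),
                    contrast, dispersion_mode),
            *mir_thresholds,
        )
        stage = contrast.test
        series.contrasts[stage] = contrast
        series.de_genes[contrast.label] = de_g
        series.de_mirs[contrast.label] = de_m
        series.canonical[stage] = opposite_sign_filter(series.topk[stage], de_g, de_m)
        logger.info(
            "stage %s (%s): %d canonical edges", stage, contrast.label,
            len(series.canonical[stage]),
        )

    series.check()
    return series
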