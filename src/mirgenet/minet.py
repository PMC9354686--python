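"""Mutual-information estimation for all miR-gene pairs of one phenotype.

The estimator is deliberately simple and fully deterministic: expression
profiles are replaced by average-tie ranks, discretized into B
equal-frequency bins (B = max(2, floor(n^(1/3))) when "auto"), and MI is
the plugin estimate sum p_ij * ln(p_ij / (p_i * p_j)) over occupied cells
of the joint histogram, in nats.  An optional Miller-Madow correction adds
(occupied_cells - occupied_rows - occupied_cols + 1) / (2n), floored at 0.

Because binning is rank-based, the estimate is invariant under strictly
monotone transforms of either profile, mirroring the rank-kernel behavior
of ARACNe-style network inference.  With rank_transform disabled the bins
are equal-width over the raw value range instead.

Top-K retention sorts edges by (MI descending, miR id, gene id) so the
retained network is reproducible under ties and input reordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import EDGE_COLUMNS, BipartiteNetwork, ExpressionMatrix


@dataclass(frozen=True)
class MIEstimatorConfig:
    """Estimator settings: bin count ("auto" = max(2, floor(n^(1/3)))),
    Miller-Madow bias correction, and rank transform."""

    n_bins: int | str = "auto"
    bias_correction: bool = False
    rank_transform: bool = True

    def __post_init__(self):
        if isinstance(self.n_bins, str):
            if self.n_bins != "auto":
                raise ValueError(f"n_bins must be an int or 'auto', got {self.n_bins!r}")
        elif self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    def resolve_bins(self, n_samples: int) -> int:
        if self.n_bins == "auto":
            return max(2, int(np.floor(np.cbrt(n_samples))))
        return int(self.n_bins)


def _discretize(x: np.ndarray, n_bins: int, rank_transform: bool) -> np.ndarray:
    """Assign each value to a bin index in [0, n_bins).

    Rank mode: average-tie ranks mapped through floor((r-1)*B/n), which
    yields exactly equal-frequency bins when B divides n and sends residual
    boundary ties to the lower bin.  Value mode: equal-width bins.
    """
    n = x.shape[-1]
    if rank_transform:
        r = rankdata(x, method="average", axis=-1)
        return np.minimum((np.floor((r - 1.0) * n_bins / n)).astype(np.int64), n_bins - 1)
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.minimum(((x - lo) / span * n_bins).astype(np.int64), n_bins - 1)


def _plugin_mi(counts: np.ndarray, bias_correction: bool) -> np.ndarray:
    """Plugin MI (nats) from joint histograms, vectorized over axis 0.

    ``counts`` has shape (..., B, B).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=(-2, -1), keepdims=True)
    p = counts / n
    pi = p.sum(axis=-1, keepdims=True)
    pj = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (pi * pj))
    mi = np.nansum(terms, axis=(-2, -1))
    mi = np.maximum(mi, 0.0)  # guard against -0.0 / rounding
    if bias_correction:
        occ = (counts > 0).sum(axis=(-2, -1))
        occ_r = ((counts.sum(axis=-1)) > 0).sum(axis=-1)
        occ_c = ((counts.sum(axis=-2)) > 0).sum(axis=-1)
        term = np.maximum(occ - occ_r - occ_c + 1, 0) / (2.0 * n[..., 0, 0])
        mi = mi + term
    return mi


def mutual_information(
    x: np.ndarray, y: np.ndarray, cfg: MIEstimatorConfig | None = None
) -> float:
    """MI (nats) between two paired numeric vectors of length >= 4."""
    cfg = cfg or MIEstimatorConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    b = cfg.resolve_bins(n)
    bx = _discretize(x, b, cfg.rank_transform)
    by = _discretize(y, b, cfg.rank_transform)
    counts = np.zeros((b, b), dtype=np.int64)
    np.add.at(counts, (bx, by), 1)
    return float(_plugin_mi(counts, cfg.bias_correction))


def all_pairs_mi(
    mirs: ExpressionMatrix,
    genes: ExpressionMatrix,
    cfg: MIEstimatorConfig | None = None,
    phenotype: str = "",
) -> BipartiteNetwork:
    """MI for every miR x gene pair over one phenotype's samples.

    Both matrices must cover the same sample set; the gene matrix is
    reordered to the miR matrix's sample order if needed.  The result has
    exactly n_mirs * n_genes edges and is deterministic given inputs and
    config.
    """
    cfg = cfg or MIEstimatorConfig()
    if set(mirs.sample_ids) != set(genes.sample_ids):
        only_m = sorted(set(mirs.sample_ids) - set(genes.sample_ids))[:5]
        only_g = sorted(set(genes.sample_ids) - set(mirs.sample_ids))[:5]
        raise ValueError(
            f"sample sets differ (miR-only: {only_m}, gene-only: {only_g})"
        )
    if mirs.sample_ids != genes.sample_ids:
        genes = genes.subset_samples(mirs.sample_ids)
    n = mirs.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples per phenotype")
    b = cfg.resolve_bins(n)

    dm = _discretize(mirs.data.to_numpy(dtype=float), b, cfg.rank_transform)
    dg = _discretize(genes.data.to_numpy(dtype=float), b, cfg.rank_transform)
    n_genes = dg.shape[0]
    offsets = np.arange(n_genes)[:, None] * (b * b)

    mir_ids = mirs.feature_ids
    gene_ids = genes.feature_ids
    frames = []
    for i in range(dm.shape[0]):
        flat = dg * b + dm[i][None, :] + offsets
        counts = np.bincount(flat.ravel(), minlength=n_genes * b * b)
        counts = counts.reshape(n_genes, b, b)
        mi = _plugin_mi(counts, cfg.bias_correction)
        frames.append(
            pd.DataFrame(
                {"mir_id": mir_ids[i], "gene_id": gene_ids, "mi": mi},
                columns=list(EDGE_COLUMNS),
            )
        )
    edges = pd.concat(frames, ignore_index=True)
    return BipartiteNetwork(phenotype=phenotype, edges=edges, k=None, filtered="raw")


def top_k(net: BipartiteNetwork, k: int = 100_000) -> BipartiteNetwork:
    """Retain the k highest-MI edges (ties broken by miR id, then gene id)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if net.filtered != "raw":
        raise ValueError(f"top_k expects a raw network, got {net.filtered!r}")
    ordered = net.edges.sort_values(
        ["mi", "mir_id", "gene_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(min(k, len(net.edges)))
    return BipartiteNetwork(
        phenotype=net.phenotype,
        edges=ordered.reset_index(drop=True),
        k=k,
        filtered="topk",
    )


def candidate_pair_count(n_mirs: int, n_genes: int) -> int:
    """Number of candidate bipartite miR-gene pairs (all-pairs design)."""
    if n_mirs < 0 or n_genes < 0:
        raise ValueError("counts must be non-negative")
    return n_mirs * n_genes
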