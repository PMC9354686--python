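"""Feature filtering and normalization of raw count matrices.

Three filters are applied, in order: (1) remove features absent from the
annotation, (2) remove features with more than ``max_zero_fraction`` zero
counts across samples, (3) remove features whose mean count is below
``min_mean``.  Normalization uses median-of-ratios size factors (the
standard NB-count estimator: each sample's factor is the median across
features of its counts divided by the feature's geometric mean, using only
features with no zero count).

An optional covariate correction (equal-frequency binning on a per-feature
covariate such as GC content or length, rescaling each bin's median to the
global median) stands in for loess-based within-lane bias removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ExpressionMatrix, FeatureAnnotation

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Accounting of a :func:`filter_features` run.

    Invariant: ``n_input == n_kept + n_removed_unannotated +
    n_removed_zeros + n_removed_low_mean`` and every removed feature id
    appears exactly once in ``removed_ids``.
    """

    n_input: int = 0
    n_removed_unannotated: int = 0
    n_removed_zeros: int = 0
    n_removed_low_mean: int = 0
    n_kept: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    def check(self) -> None:
        total = (self.n_kept + self.n_removed_unannotated +
                 self.n_removed_zeros + self.n_removed_low_mean)
        assert total == self.n_input, "filter report does not balance"
        assert len(self.removed_ids) == self.n_input - self.n_kept

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_unannotated": self.n_removed_unannotated,
            "n_removed_zeros": self.n_removed_zeros,
            "n_removed_low_mean": self.n_removed_low_mean,
            "n_kept": self.n_kept,
            "removed_ids": [list(t) for t in self.removed_ids],
        }


def filter_features(
    mat: ExpressionMatrix,
    annot: FeatureAnnotation | None = None,
    max_zero_fraction: float = 0.5,
    min_mean: float = 10.0,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply the three feature filters in order; strict thresholds.

    A feature is removed when its zero fraction is strictly greater than
    ``max_zero_fraction`` ("more than 50% zeros") or its mean strictly less
    than ``min_mean`` ("mean expression of less than 10 counts").  Passing
    ``annot=None`` skips the annotation filter (used for pre-harmonized miR
    matrices).  Raises ``ValueError`` if nothing survives.
    """
    report = FilterReport(n_input=mat.n_features)
    df = mat.data

    if annot is not None:
        keep_mask = df.index.to_series().isin(annot.table.index)
        for fid in df.index[~keep_mask]:
            report.removed_ids.append((fid, "unannotated"))
        report.n_removed_unannotated = int((~keep_mask).sum())
        df = df.loc[keep_mask]

    values = df.to_numpy(dtype=float)
    zero_frac = (values == 0).mean(axis=1) if values.size else np.zeros(0)
    zmask = zero_frac > max_zero_fraction
    for fid in df.index[zmask]:
        report.removed_ids.append((fid, "zeros"))
    report.n_removed_zeros = int(zmask.sum())
    df = df.loc[~zmask]

    values = df.to_numpy(dtype=float)
    means = values.mean(axis=1) if values.size else np.zeros(0)
    mmask = means < min_mean
    for fid in df.index[mmask]:
        report.removed_ids.append((fid, "low_mean"))
    report.n_removed_low_mean = int(mmask.sum())
    df = df.loc[~mmask]

    report.n_kept = df.shape[0]
    report.check()
    if report.n_kept == 0:
        raise ValueError("no features survive filtering; pipeline cannot proceed")
    logger.info(
        "filter_features(%s): %d -> %d (unannotated %d, zeros %d, low mean %d)",
        mat.feature_kind, report.n_input, report.n_kept,
        report.n_removed_unannotated, report.n_removed_zeros, report.n_removed_low_mean,
    )
    return ExpressionMatrix(df.copy(), mat.feature_kind, mat.units), report


def size_factors(mat: ExpressionMatrix, allow_total_fallback: bool = False) -> np.ndarray:
    """Median-of-ratios size factors, one strictly positive value per sample.

    Only features with no zero count contribute to the reference geometric
    mean.  If no such feature exists, either raise (default) or fall back to
    total-count ratios when ``allow_total_fallback`` is set.
    """
    values = mat.data.to_numpy(dtype=float)
    eligible = (values > 0).all(axis=1)
    if not eligible.any():
        if not allow_total_fallback:
            raise ValueError(
                "no feature is nonzero in every sample; "
                "pass allow_total_fallback=True to use total-count ratios"
            )
        totals = values.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return factors
    ref = values[eligible]
    log_geomean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = ref / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    assert (factors > 0).all()
    return factors


def normalize(mat: ExpressionMatrix, factors: np.ndarray) -> ExpressionMatrix:
    """Divide each sample column by its size factor; tag units "normalized"."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (mat.n_samples,):
        raise ValueError(
            f"expected {mat.n_samples} size factors, got shape {factors.shape}"
        )
    if (factors <= 0).any() or not np.all(np.isfinite(factors)):
        raise ValueError("size factors must be finite and strictly positive")
    return ExpressionMatrix(mat.data / factors, mat.feature_kind, units="normalized")


def covariate_correct(
    mat: ExpressionMatrix, covariate: np.ndarray, n_bins: int = 10
) -> ExpressionMatrix:
    """Remove a per-feature covariate trend by equal-frequency bin rescaling.

    Features are stratified into ``n_bins`` equal-frequency bins of the
    covariate; each bin's values are rescaled so that the bin median (over
    its features and all samples) equals the global median.  Bins with a
    zero median are left unscaled (and logged).  ``n_bins`` larger than the
    number of features is reduced with a warning.
    """
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (mat.n_features,):
        raise ValueError(
            f"covariate length {covariate.shape} does not match {mat.n_features} features"
        )
    if n_bins > mat.n_features:
        logger.warning("n_bins=%d > n_features=%d; reducing", n_bins, mat.n_features)
        n_bins = mat.n_features
    order = np.argsort(covariate, kind="mergesort")
    bins = np.array_split(order, n_bins)
    values = mat.data.to_numpy(dtype=float).copy()
    global_median = np.median(values)
    for b, rows in enumerate(bins):
        if rows.size == 0:
            continue
        m = np.median(values[rows])
        if m == 0:
            logger.info("covariate bin %d has zero median; left unscaled", b)
            continue
        values[rows] *= global_median / m
    out = mat.data.copy()
    out.loc[:, :] = values
    return ExpressionMatrix(out, mat.feature_kind, mat.units)
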