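"""Feature filters, size factors, normalization and covariate correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirgenet.io_formats import ExpressionMatrix, FeatureAnnotation
from mirgenet.preprocess import (
    covariate_correct,
    filter_features,
    normalize,
    size_factors,
)


def _mat(rows: dict, kind="gene"):
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(df.astype(float), kind)


def _annot(ids):
    return FeatureAnnotation(
        pd.DataFrame(
            {"chromosome": "1", "cytoband": "1q11", "start": 1, "end": 10,
             "strand": "+", "biotype": "x"},
            index=pd.Index(ids, name="feature_id"),
        )
    )


class TestFilterFeatures:
    def test_reasons_and_order(self):
        mat = _mat({
            "zeros": [0, 0, 0, 10],     # zero fraction 0.75 > 0.5
            "kept": [12, 8, 15, 9],     # mean 11 >= 10
            "low": [3, 2, 4, 2],        # mean 2.75 < 10
            "noannot": [50, 50, 50, 50],
        })
        out, report = filter_features(mat, _annot(["zeros", "kept", "low"]))
        assert out.feature_ids == ["kept"]
        assert dict(report.removed_ids) == {
            "zeros": "zeros", "low": "low_mean", "noannot": "unannotated"
        }
        assert report.n_input == 4 and report.n_kept == 1

    def test_zero_fraction_boundary_is_strict(self):
        # exactly half zeros is kept ("more than 50%" removes)
        mat = _mat({"half": [0, 0, 20, 20]})
        out, _ = filter_features(mat, None)
        assert out.feature_ids == ["half"]

    def test_idempotent(self):
        mat = _mat({"a": [0, 0, 0, 12], "b": [20, 30, 25, 22], "c": [1, 2, 1, 1]})
        once, _ = filter_features(mat, None)
        twice, report = filter_features(once, None)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert report.n_kept == report.n_input

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError, match="no features"):
            filter_features(_mat({"a": [1, 1, 1, 1]}), None)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 20), st.integers(2, 8))
    def test_report_accounting_identity(self, seed, n_feat, n_samp):
        rng = np.random.default_rng(seed)
        values = rng.poisson(rng.uniform(0, 30), size=(n_feat, n_samp))
        df = pd.DataFrame(values, index=[f"f{i}" for i in range(n_feat)],
                          columns=[f"s{j}" for j in range(n_samp)])
        annot = _annot([f"f{i}" for i in range(0, n_feat, 2)])
        try:
            _, report = filter_features(ExpressionMatrix(df.astype(float), "gene"), annot)
        except ValueError:
            return  # everything filtered: legal hard error
        report.check()
        assert report.n_input == n_feat


class TestSizeFactors:
    def test_identical_samples(self):
        mat = _mat({"a": [10, 10], "b": [7, 7]})
        assert np.allclose(size_factors(mat), [1.0, 1.0])

    def test_proportional_columns(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 100, size=20).astype(float)
        df = pd.DataFrame({"s0": col, "s1": 2 * col},
                          index=[f"f{i}" for i in range(20)])
        f = size_factors(ExpressionMatrix(df, "gene"))
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_single_sample_is_unity(self):
        mat = _mat({"a": [10], "b": [40], "c": [90]})
        assert size_factors(mat) == pytest.approx([1.0])

    def test_no_eligible_feature(self):
        mat = _mat({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="total"):
            size_factors(mat)
        # fallback uses total counts
        f = size_factors(mat, allow_total_fallback=True)
        assert np.all(f > 0)


class TestNormalize:
    def test_unit_factors_identity(self):
        mat = _mat({"a": [1, 2, 3, 4]})
        out = normalize(mat, np.ones(4))
        pd.testing.assert_frame_equal(out.data, mat.data)
        assert out.units == "normalized"

    def test_inverse_scaling(self):
        base = _mat({"a": [10, 10], "b": [4, 4]})
        scaled = _mat({"a": [10, 20], "b": [4, 8]})
        out = normalize(scaled, np.array([1.0, 2.0]))
        pd.testing.assert_frame_equal(out.data, base.data)

    def test_bad_factors(self):
        mat = _mat({"a": [1, 2]})
        with pytest.raises(ValueError):
            normalize(mat, np.array([1.0]))
        with pytest.raises(ValueError):
            normalize(mat, np.array([1.0, 0.0]))

    def test_preserves_within_sample_rank_order(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.integers(0, 500, (30, 5)).astype(float),
                          index=[f"f{i}" for i in range(30)],
                          columns=[f"s{j}" for j in range(5)])
        mat = ExpressionMatrix(df, "gene")
        out = normalize(mat, rng.uniform(0.5, 2.0, 5))
        for j in range(5):
            assert (np.argsort(out.data.iloc[:, j].to_numpy(), kind="stable")
                    == np.argsort(df.iloc[:, j].to_numpy(), kind="stable")).all()


class TestCovariateCorrect:
    def test_constant_covariate_identity(self):
        mat = _mat({"a": [1, 2], "b": [3, 4]})
        out = covariate_correct(mat, np.array([5.0, 5.0]), n_bins=1)
        pd.testing.assert_frame_equal(out.data, mat.data)

    def test_two_bins_rescaled_to_global_median(self):
        # bin 1 (features a,b) has median m, bin 2 (c,d) median 2m
        mat = _mat({"a": [10, 10], "b": [10, 10], "c": [20, 20], "d": [20, 20]})
        out = covariate_correct(mat, np.array([1.0, 2.0, 3.0, 4.0]), n_bins=2)
        g = np.median(mat.data.to_numpy())
        assert np.allclose(out.data.loc["a"], g)
        assert np.allclose(out.data.loc["c"], g)

    def test_bin_reduction_when_too_many(self):
        mat = _mat({"a": [1, 2], "b": [3, 4]})
        out = covariate_correct(mat, np.array([1.0, 2.0]), n_bins=10)
        assert out.data.shape == mat.data.shape

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="covariate length"):
            covariate_correct(_mat({"a": [1, 2]}), np.array([1.0, 2.0]))
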