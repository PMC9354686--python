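"""NB Wald test, BH adjustment and threshold classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirgenet.diffexpr import (
    Contrast,
    adjust_bh,
    classify,
    contiguous_contrasts,
    nb_test,
    nt_vs_stage_contrasts,
)
from mirgenet.io_formats import ExpressionMatrix


def _nb_matrix(rng, mu, alpha, n, prefix):
    lam = rng.gamma(1.0 / alpha, np.multiply.outer(mu, np.ones(n)) * alpha)
    counts = rng.poisson(lam)
    return ExpressionMatrix(
        pd.DataFrame(counts.astype(float),
                     index=[f"f{i}" for i in range(len(mu))],
                     columns=[f"{prefix}{j}" for j in range(n)]),
        "gene",
    )


class TestContrasts:
    def test_contiguous_order(self):
        labels = [c.label for c in contiguous_contrasts()]
        assert labels == ["NT-I", "I-II", "II-III", "III-IV"]
        assert contiguous_contrasts()[2] == Contrast("II", "III")

    def test_nt_vs_stage(self):
        assert [c.label for c in nt_vs_stage_contrasts()] == [
            "NT-I", "NT-II", "NT-III", "NT-IV"
        ]
        assert contiguous_contrasts()[0] == nt_vs_stage_contrasts()[0]

    def test_label_round_trip(self):
        for c in contiguous_contrasts() + nt_vs_stage_contrasts():
            assert Contrast.from_label(c.label) == c

    def test_same_phenotype_rejected(self):
        with pytest.raises(ValueError):
            Contrast("I", "I")


def _bh_oracle(p):
    """Independent brute-force BH step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m * p[idx] / (rank + 1))
        q[idx] = min(running, 1.0)
    return q


class TestAdjustBH:
    def test_hand_example(self):
        assert adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_equal(self):
        assert adjust_bh(np.array([0.2])) == pytest.approx([0.2])
        assert adjust_bh(np.full(5, 0.07)) == pytest.approx(np.full(5, 0.07))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.2]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_brute_force_oracle(self, p):
        p = np.array(p)
        assert adjust_bh(p) == pytest.approx(_bh_oracle(p), abs=1e-12)

    def test_monotone_and_dominates_raw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        q = adjust_bh(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestNBTest:
    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        a = _nb_matrix(rng, 10 ** rng.uniform(1, 3, 100), 0.1, 10, "a")
        b = _nb_matrix(rng, 10 ** rng.uniform(1, 3, 100), 0.1, 12, "b")
        fwd = nb_test(a, b, Contrast("NT", "I"))
        rev = nb_test(b, a, Contrast("I", "NT"))
        assert fwd.table["log2fc"].to_numpy() == pytest.approx(
            -rev.table["log2fc"].to_numpy(), abs=1e-10
        )
        assert fwd.table["p_raw"].to_numpy() == pytest.approx(
            rev.table["p_raw"].to_numpy(), abs=1e-12
        )

    def test_all_zero_feature_defined(self):
        df = pd.DataFrame(
            {"s0": [0, 5], "s1": [0, 6], "s2": [0, 7], "s3": [0, 8]},
            index=["z", "x"], dtype=float,
        )
        mat = ExpressionMatrix(df, "gene")
        res = nb_test(mat.subset_samples(["s0", "s1"]), mat.subset_samples(["s2", "s3"]))
        assert res.table.loc["z", "p_raw"] == 1.0
        assert res.table.loc["z", "log2fc"] == 0.0

    def test_small_group_rejected(self):
        df = pd.DataFrame({"s0": [1.0], "s1": [2.0], "s2": [3.0]}, index=["f"])
        mat = ExpressionMatrix(df, "gene")
        with pytest.raises(ValueError, match="2 samples"):
            nb_test(mat.subset_samples(["s0"]), mat.subset_samples(["s1", "s2"]))

    def test_recovers_fourfold_effect(self):
        """A true 4-fold change (dispersion 0.1, n=30/group) is estimated
        near log2fc = 2 with a decisive adjusted p, in the bulk of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            mu = 10 ** rng.uniform(1.5, 3.0, 200)
            mu_b = mu.copy()
            mu_b[0] *= 4.0
            a = _nb_matrix(rng, mu, 0.1, 30, "a")
            b = _nb_matrix(rng, mu_b, 0.1, 30, "b")
            t = nb_test(a, b).table
            if 1.5 <= t.loc["f0", "log2fc"] <= 2.5 and t.loc["f0", "p_adj"] < 1e-5:
                hits += 1
        assert hits >= 19


class TestClassify:
    def _result(self, rows):
        table = pd.DataFrame(rows, columns=["log2fc", "p_raw", "p_adj"],
                             index=[f"f{i}" for i in range(len(rows))])
        from mirgenet.diffexpr import DifferentialResult
        return DifferentialResult(Contrast("NT", "I"), table)

    def test_mir_under_call(self):
        # the motivating exemplar: log2fc -1.322 at p = 1e-9, miR thresholds
        res = classify(self._result([(-1.322, 1e-9, 1e-7)]), 0.5, 1e-5, False)
        assert res.table["status"].tolist() == ["under"]

    def test_zero_lfc_is_ns(self):
        res = classify(self._result([(0.0, 1e-12, 1e-12)]), 1.0, 1e-5, True)
        assert res.table["status"].tolist() == ["ns"]

    def test_thresholds_are_strict(self):
        res = classify(self._result([(1.0, 1e-9, 1e-9)]), 1.0, 1e-5, True)
        assert res.table["status"].tolist() == ["ns"]

    def test_adjusted_vs_raw_rule(self):
        rows = [(2.0, 1e-9, 1e-3)]  # raw significant, adjusted not
        assert classify(self._result(rows), 1.0, 1e-5, True).table["status"].iloc[0] == "ns"
        assert classify(self._result(rows), 1.0, 1e-5, False).table["status"].iloc[0] == "over"

    def test_status_matches_invariant(self):
        rng = np.random.default_rng(13)
        rows = list(zip(rng.normal(0, 2, 300), rng.uniform(0, 1, 300),
                        rng.uniform(0, 1, 300)))
        res = classify(self._result(rows), 1.0, 0.05, True)
        t = res.table
        over = (t["log2fc"] > 1.0) & (t["p_adj"] < 0.05)
        under = (t["log2fc"] < -1.0) & (t["p_adj"] < 0.05)
        assert ((t["status"] == "over") == over).all()
        assert ((t["status"] == "under") == under).all()
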