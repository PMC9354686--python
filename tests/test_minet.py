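"""MI estimator against a brute-force oracle, plus top-K semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from mirgenet.io_formats import BipartiteNetwork, ExpressionMatrix
from mirgenet.minet import (
    MIEstimatorConfig,
    all_pairs_mi,
    candidate_pair_count,
    mutual_information,
    top_k,
)


def oracle_mi(x, y, n_bins, bias_correction=False):
    """Independent brute-force plugin MI: explicit rank binning and an
    explicit double loop over the joint histogram."""
    n = len(x)
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    bx = [min(int((r - 1.0) * n_bins / n), n_bins - 1) for r in rx]
    by = [min(int((r - 1.0) * n_bins / n), n_bins - 1) for r in ry]
    joint = [[0] * n_bins for _ in range(n_bins)]
    for i in range(n):
        joint[bx[i]][by[i]] += 1
    row = [sum(joint[a]) for a in range(n_bins)]
    col = [sum(joint[a][b] for a in range(n_bins)) for b in range(n_bins)]
    mi = 0.0
    for a in range(n_bins):
        for b in range(n_bins):
            if joint[a][b] > 0:
                pij = joint[a][b] / n
                mi += pij * np.log(pij / ((row[a] / n) * (col[b] / n)))
    mi = max(mi, 0.0)
    if bias_correction:
        occ = sum(1 for a in range(n_bins) for b in range(n_bins) if joint[a][b] > 0)
        occ_r = sum(1 for a in range(n_bins) if row[a] > 0)
        occ_c = sum(1 for b in range(n_bins) if col[b] > 0)
        mi += max(occ - occ_r - occ_c + 1, 0) / (2.0 * n)
    return mi


def _mat(values, kind, prefix):
    values = np.abs(np.asarray(values, dtype=float))  # expression is >= 0
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
                     columns=[f"s{j}" for j in range(values.shape[1])]),
        kind,
    )


class TestMutualInformation:
    def test_constant_vector_gives_zero(self):
        x = np.arange(12.0)
        assert mutual_information(x, np.full(12, 3.0)) == 0.0

    @pytest.mark.parametrize("b,n", [(2, 8), (3, 12), (4, 16)])
    def test_identity_gives_log_bins(self, b, n):
        # distinct values, B | n: the joint is diagonal, MI = ln B exactly
        x = np.arange(float(n))
        cfg = MIEstimatorConfig(n_bins=b)
        assert mutual_information(x, x, cfg) == pytest.approx(np.log(b), abs=1e-12)

    def test_two_by_two_diagonal(self):
        # joint bin counts [[2,0],[0,2]]: MI = ln 2
        x = np.array([1.0, 2.0, 10.0, 11.0])
        y = np.array([5.0, 6.0, 50.0, 51.0])
        cfg = MIEstimatorConfig(n_bins=2)
        assert mutual_information(x, y, cfg) == pytest.approx(np.log(2), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.arange(3.0), np.arange(3.0))

    @pytest.mark.parametrize("bias", [False, True])
    def test_matches_brute_force_oracle(self, bias):
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(4, 101))
            b = int(rng.integers(2, 6))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:  # exercise ties
                x = np.round(x, 1)
                y = np.round(y, 1)
            cfg = MIEstimatorConfig(n_bins=b, bias_correction=bias)
            assert mutual_information(x, y, cfg) == pytest.approx(
                oracle_mi(x, y, b, bias), abs=1e-12
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=24)
        y = rng.normal(size=24)
        cfg = MIEstimatorConfig(n_bins=4)
        mi = mutual_information(x, y, cfg)
        assert mi >= 0.0
        assert mutual_information(y, x, cfg) == pytest.approx(mi, abs=1e-12)
        # strictly monotone transforms leave rank-binned MI unchanged
        assert mutual_information(np.exp(x), y**3, cfg) == pytest.approx(mi, abs=1e-12)

    def test_auto_bin_rule(self):
        assert MIEstimatorConfig().resolve_bins(60) == 3
        assert MIEstimatorConfig().resolve_bins(1000) == 10
        assert MIEstimatorConfig().resolve_bins(4) == 2

    def test_coupled_vs_independent_separation(self):
        """Median MI of 1,000 independent pairs sits below the 5th
        percentile of MI for strongly coupled pairs (n = 60)."""
        rng = np.random.default_rng(17)
        cfg = MIEstimatorConfig()
        null = []
        for _ in range(1000):
            null.append(mutual_information(rng.normal(size=60), rng.normal(size=60), cfg))
        coupled = []
        rho = 0.8
        for _ in range(200):
            z = rng.normal(size=60)
            x = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=60)
            y = -np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=60)
            coupled.append(mutual_information(x, y, cfg))
        assert np.median(null) < np.percentile(coupled, 5)


class TestAllPairs:
    def test_cardinality(self):
        rng = np.random.default_rng(1)
        mirs = _mat(rng.normal(size=(2, 8)), "miR", "m")
        genes = _mat(rng.normal(size=(3, 8)), "gene", "g")
        net = all_pairs_mi(mirs, genes, phenotype="NT")
        assert len(net) == 6
        assert net.filtered == "raw"

    def test_study_scale_pair_count(self):
        assert candidate_pair_count(275, 16227) == 4_462_425

    def test_sample_mismatch_listed(self):
        rng = np.random.default_rng(2)
        mirs = _mat(rng.normal(size=(2, 6)), "miR", "m")
        genes = _mat(rng.normal(size=(2, 6)), "gene", "g")
        genes.data.columns = [f"t{j}" for j in range(6)]
        with pytest.raises(ValueError, match="sample sets differ"):
            all_pairs_mi(mirs, genes)

    def test_invariant_to_joint_sample_permutation(self):
        rng = np.random.default_rng(3)
        mirs = _mat(rng.normal(size=(3, 10)), "miR", "m")
        genes = _mat(rng.normal(size=(4, 10)), "gene", "g")
        net = all_pairs_mi(mirs, genes)
        perm = list(rng.permutation(mirs.sample_ids))
        net_p = all_pairs_mi(mirs.subset_samples(perm), genes.subset_samples(perm))
        merged = net.edges.merge(net_p.edges, on=["mir_id", "gene_id"])
        assert merged["mi_x"].to_numpy() == pytest.approx(
            merged["mi_y"].to_numpy(), abs=1e-12
        )


class TestTopK:
    def _net(self, scores):
        rows = [(f"m{i}", f"g{i}", s) for i, s in enumerate(scores)]
        df = pd.DataFrame(rows, columns=["mir_id", "gene_id", "mi"])
        return BipartiteNetwork(phenotype="I", edges=df, filtered="raw")

    def test_k_larger_than_network(self):
        net = self._net([3.0, 1.0])
        out = top_k(net, 100)
        assert out.edge_set() == net.edge_set()
        assert out.filtered == "topk"

    def test_tie_break_lexicographic(self):
        df = pd.DataFrame(
            [("m9", "g1", 2.0), ("m1", "g9", 2.0), ("m5", "g5", 3.0),
             ("m2", "g2", 1.0), ("m3", "g3", 0.0)],
            columns=["mir_id", "gene_id", "mi"],
        )
        net = BipartiteNetwork(phenotype="I", edges=df, filtered="raw")
        out = top_k(net, 2)
        assert list(map(tuple, out.edges[["mir_id", "gene_id"]].to_numpy())) == [
            ("m5", "g5"), ("m1", "g9")
        ]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            [(f"m{i}", f"g{j}", float(rng.choice([0.1, 0.2, 0.3])))
             for i in range(6) for j in range(6)],
            columns=["mir_id", "gene_id", "mi"],
        )
        net1 = BipartiteNetwork("I", df, filtered="raw")
        net2 = BipartiteNetwork("I", df.sample(frac=1, random_state=4), filtered="raw")
        out1, out2 = top_k(net1, 10), top_k(net2, 10)
        pd.testing.assert_frame_equal(
            out1.edges.reset_index(drop=True), out2.edges.reset_index(drop=True)
        )

    def test_invalid_inputs(self):
        net = self._net([1.0])
        with pytest.raises(ValueError, match="positive"):
            top_k(net, 0)
        with pytest.raises(ValueError, match="raw"):
            top_k(top_k(net, 1), 1)
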