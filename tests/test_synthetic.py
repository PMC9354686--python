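"""The synthetic-data generator: determinism, marginals, planted structure."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.stats import spearmanr

from mirgenet.io_formats import STAGE_ORDER
from mirgenet.synthetic_data import (
    Coupling,
    DEEffect,
    default_study,
    generate,
)


class TestConfig:
    def test_default_validates(self):
        default_study().validate()

    def test_sample_plan_direction(self):
        # NT smaller than stage I, echoing the study's imbalance
        plan = default_study().samples_per_phenotype
        assert plan["NT"] < plan["I"]

    def test_unknown_feature_rejected(self):
        cfg = default_study()
        cfg.de_plan.append(DEEffect("NT-I", "G9999", "gene", 2.0))
        with pytest.raises(ValueError, match="unknown feature"):
            cfg.validate()

    def test_bad_coupling_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            Coupling("miR-01", "G0001", -1, 1.5, ("I",))
        with pytest.raises(ValueError, match="sign"):
            Coupling("miR-01", "G0001", 0, 0.5, ("I",))

    def test_plan_composition(self):
        cfg = default_study()
        coup = cfg.coupling_plan
        assert len(coup) == 30
        negative_de = [c for c in coup if c.sign == -1 and c.category == "stage"]
        assert len(negative_de) == 20
        assert sum(c.category == "tumor_only" for c in coup) == 5
        assert sum(c.sign == 1 for c in coup) == 5


class TestGenerate:
    def test_seed_determinism_byte_identical(self):
        a = generate(default_study(7))
        b = generate(default_study(7))
        assert a[0].data.equals(b[0].data)
        assert a[1].data.equals(b[1].data)
        assert a[3].table.equals(b[3].table)
        c = generate(default_study(8))
        assert not a[0].data.equals(c[0].data)

    def test_shapes_and_sample_table(self):
        gene_mat, mir_mat, samples, annot, _ = generate(default_study(1))
        assert gene_mat.data.shape == (300, 220)
        assert mir_mat.data.shape == (50, 220)
        assert samples.counts() == {"NT": 40, "I": 60, "II": 40, "III": 40, "IV": 40}
        # the two deliberately unannotated genes are absent
        assert "G0289" not in annot and "G0290" not in annot

    def test_planted_effect_realized(self):
        """A planted log2fc = 2 gene effect between NT and stage I shows a
        realized normalized-mean log2 ratio within [1.6, 2.4]."""
        cfg = default_study(3)
        cfg.de_plan.append(DEEffect("NT-I", "G0250", "gene", 2.0))
        cfg.baseline_log10_overrides["G0250"] = (2.0, 2.5)
        gene_mat, _, samples, _, _ = generate(cfg)
        from mirgenet.preprocess import normalize, size_factors

        norm = normalize(gene_mat, size_factors(gene_mat, allow_total_fallback=True))
        nt = norm.data.loc["G0250", samples.samples_for("NT")].mean()
        st1 = norm.data.loc["G0250", samples.samples_for("I")].mean()
        assert 1.6 <= np.log2(st1 / nt) <= 2.4

    def test_negative_coupling_rank_correlation(self):
        """rho = 0.8 negative couplings realize a rank correlation in
        [-0.95, -0.5] within their active phenotype."""
        gene_mat, mir_mat, samples, _, truth = generate(default_study(2))
        neg = truth.couplings[(truth.couplings["sign"] == -1)
                              & (truth.couplings["category"] == "stage")]
        cors = []
        for _, row in neg.iterrows():
            ids = samples.samples_for(row["stage"])
            r = spearmanr(mir_mat.data.loc[row["mir_id"], ids],
                          gene_mat.data.loc[row["gene_id"], ids]).statistic
            cors.append(r)
        cors = np.array(cors)
        assert (cors < 0).all()
        assert -0.95 <= np.median(cors) <= -0.5

    def test_uncoupled_pairs_center_on_zero(self):
        # library-size variation is shared across features, so correlations
        # are measured on size-factor-normalized data, as the pipeline does
        from mirgenet.preprocess import normalize, size_factors

        gene_mat, mir_mat, samples, _, _ = generate(default_study(4))
        genes = normalize(gene_mat, size_factors(gene_mat, allow_total_fallback=True))
        mirs = normalize(mir_mat, size_factors(mir_mat, allow_total_fallback=True))
        rng = np.random.default_rng(0)
        ids = samples.samples_for("NT")
        cors = []
        for _ in range(200):
            m = f"miR-{rng.integers(36, 41):02d}"  # never coupled
            g = f"G{rng.integers(220, 281):04d}"  # never coupled
            cors.append(spearmanr(mirs.data.loc[m, ids],
                                  genes.data.loc[g, ids]).statistic)
        assert abs(np.median(cors)) < 0.1

    def test_nb_marginal_moments(self):
        """Null features match NB(mu, alpha=0.1): across features the
        variance tracks mu + alpha*mu^2 (checked on log scale)."""
        cfg = replace(default_study(6), library_size_cv=1e-6)
        gene_mat, _, samples, _, truth = generate(cfg)
        planted = set(truth.de_effects["feature_id"]) | set(truth.couplings["gene_id"])
        null_ids = [g for g in gene_mat.feature_ids
                    if g not in planted and g < "G0287"]
        data = gene_mat.data.loc[null_ids]
        mu = data.mean(axis=1).to_numpy()
        var = data.var(axis=1, ddof=1).to_numpy()
        expected = mu + 0.1 * mu**2
        ratio = var / expected
        assert 0.85 <= np.median(ratio) <= 1.15

    def test_filter_fodder_present(self, study, filtered):
        """The default study plants features for each removal reason."""
        _, _, gene_report, _ = filtered
        reasons = dict(gene_report.removed_ids)
        assert reasons.get("G0289") == "unannotated"
        assert reasons.get("G0291") == "low_mean"
        assert reasons.get("G0287") == "zeros"
        # planted features always survive
        kept_needed = {"G0001", "G0101", "G0104", "G0201", "G0211"}
        assert not (kept_needed & set(reasons))
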