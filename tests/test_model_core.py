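"""Design encoding, least-squares oracle equivalence, Gibbs agreement,
and the variance/heritability identities."""

import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import startlenet as sn
from startlenet.model_core import (
    Design,
    partial_f,
    sex_contrast,
    term_variance,
)
from startlenet.scan import _LocusKernel

from conftest import balanced_pair_panel


def random_design(rng, n_lines=10, n_loci=2):
    """A random continuous-predictor design for oracle comparisons."""
    values = rng.normal(size=(n_lines, 2, n_loci))
    ids = [f"p{i}" for i in range(n_loci)]
    ps = sn.PredictorSet(ids, values)
    spec = sn.DesignSpec(loci=ids, include_qe=False)
    y = rng.normal(size=(n_lines, 2))
    return sn.encode_design(spec, ps, y)


class TestEncoding:
    def test_snp_codes_and_product_coding(self):
        panel = balanced_pair_panel()
        ps = sn.PredictorSet.from_genotypes(panel)
        i, j = panel.snp_ids
        spec = sn.DesignSpec(loci=[i, j], pairs=[(i, j)])
        y = np.zeros((8, 2))
        design = sn.encode_design(spec, ps, y)
        codes = panel.codes()
        qi = design.X[:, design.labels.index(("q", i))]
        assert set(np.unique(qi)) == {-1.0, 1.0}
        np.testing.assert_array_equal(qi.reshape(8, 2)[:, 0], codes[:, 0])
        qq = design.X[:, design.labels.index(("qq", i, j))]
        np.testing.assert_array_equal(
            qq.reshape(8, 2)[:, 0], codes[:, 0] * codes[:, 1]
        )
        # pair coefficient for codes (+1, -1) is -1
        row = np.flatnonzero((codes[:, 0] == 1) & (codes[:, 1] == -1))[0]
        assert qq.reshape(8, 2)[row, 0] == -1.0

    def test_qe_column_is_code_times_sex_contrast(self):
        panel = balanced_pair_panel()
        ps = sn.PredictorSet.from_genotypes(panel)
        locus = panel.snp_ids[0]
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, np.zeros((8, 2))
        )
        q = design.X[:, design.labels.index(("q", locus))]
        qe = design.X[:, design.labels.index(("qe", locus))]
        np.testing.assert_array_equal(qe, q * sex_contrast(8))

    def test_transcript_predictors_standardized_per_sex(self, small_panel):
        cfg = sn.SimConfig(n_lines=60, n_snps=40, n_transcripts=6, seed=11)
        expr = sn.simulate_expression(small_panel, cfg)
        ps = sn.PredictorSet.from_expression(expr)
        np.testing.assert_allclose(ps.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(ps.values.std(axis=0), 1.0, atol=1e-12)

    def test_unknown_predictor_raises(self, small_panel):
        ps = sn.PredictorSet.from_genotypes(small_panel)
        with pytest.raises(KeyError, match="nope"):
            sn.encode_design(sn.DesignSpec(loci=["nope"]), ps, np.zeros((60, 2)))

    def test_zero_variance_column_excluded_with_warning(self):
        values = np.ones((10, 2, 1))
        ps = sn.PredictorSet(["flat"], values)
        with pytest.warns(UserWarning, match="zero-variance"):
            design = sn.encode_design(
                sn.DesignSpec(loci=["flat"]), ps, np.zeros((10, 2))
            )
        assert ("q", "flat") not in design.labels
        assert ("q", "flat") in design.dropped


class TestFixedFit:
    def test_noise_free_balanced_recovery_is_exact(self):
        panel = balanced_pair_panel()
        locus = panel.snp_ids[0]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: 2.0})
        cfg = sn.SimConfig(n_lines=8, n_snps=2, min_minor_lines=2,
                           truth=truth, residual_sd_pheno=0.0, seed=1)
        pheno, _ = sn.simulate_phenotype(panel, cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, pheno.line_sex_means(panel.line_ids)
        )
        model = sn.fit_fixed_model(design)
        assert model.effect(("q", locus)) == pytest.approx(2.0, abs=1e-12)
        assert model.mu_hat == pytest.approx(20.0, abs=1e-12)

    def test_estimates_match_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            design = random_design(rng, n_lines=10, n_loci=3)
            model = sn.fit_fixed_model(design)
            X, y = design.X, design.y
            oracle = np.linalg.inv(X.T @ X) @ (X.T @ y)
            np.testing.assert_allclose(model.beta, oracle, atol=1e-10)

    def test_null_locus_p_values_are_uniform(self):
        # 1,000 null responses against one fixed locus; KS at the 1% level
        rng = np.random.default_rng(7)
        cfg = sn.SimConfig(n_lines=50, n_snps=1, n_transcripts=1, seed=15)
        panel = sn.simulate_genotypes(cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        kernel = _LocusKernel(ps.values)
        Y = rng.normal(size=(1000, 50, 2))
        f = kernel.f_stats(Y)[0]
        p = kernel.p_nominal(f)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_rank_deficiency_names_aliased_columns(self):
        values = np.zeros((10, 2, 2))
        values[:, :, 0] = np.random.default_rng(0).normal(size=(10, 2))
        values[:, :, 1] = values[:, :, 0]          # exact duplicate
        ps = sn.PredictorSet(["a", "b"], values)
        design = sn.encode_design(
            sn.DesignSpec(loci=["a", "b"], include_qe=False),
            ps, np.zeros((10, 2)),
        )
        with pytest.raises(ValueError, match="aliased"):
            sn.fit_fixed_model(design)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(1)
        design = random_design(rng, n_lines=2, n_loci=3)
        with pytest.raises(ValueError, match="observations"):
            sn.fit_fixed_model(design)


class TestGibbs:
    def test_posterior_means_agree_with_least_squares(self):
        rng = np.random.default_rng(3)
        panel = balanced_pair_panel()
        locus = panel.snp_ids[0]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: 2.0})
        cfg = sn.SimConfig(n_lines=8, n_snps=2, min_minor_lines=2,
                           truth=truth, residual_sd_pheno=0.5, seed=5)
        pheno, _ = sn.simulate_phenotype(panel, cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, pheno.line_sex_means(panel.line_ids)
        )
        model = sn.fit_fixed_model(design)
        post = sn.gibbs_estimate(design, sn.GibbsConfig(iterations=4000, seed=8))
        for i in range(len(design.labels)):
            assert abs(post.mean[i] - model.beta[i]) < 2 * post.sd[i]

    def test_constant_response_centres_effects_at_zero(self):
        panel = balanced_pair_panel()
        locus = panel.snp_ids[0]
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, np.full((8, 2), 20.0)
        )
        post = sn.gibbs_estimate(design, sn.GibbsConfig(iterations=3000, seed=2))
        i = design.labels.index(("q", locus))
        assert abs(post.mean[i]) < 2 * post.sd[i] + 1e-6
        assert post.sd[i] < 0.05

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(11)
        design = random_design(rng, n_lines=12, n_loci=2)
        cfg = sn.GibbsConfig(iterations=1000, seed=99)
        a = sn.gibbs_estimate(design, cfg)
        b = sn.gibbs_estimate(design, cfg)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.sd, b.sd)


class TestVarianceAndHeritability:
    def _balanced_fit(self, q=2.0, noise=0.0, seed=1):
        panel = balanced_pair_panel()
        locus = panel.snp_ids[0]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: q})
        cfg = sn.SimConfig(n_lines=8, n_snps=2, min_minor_lines=2,
                           truth=truth, residual_sd_pheno=noise, seed=seed)
        pheno, _ = sn.simulate_phenotype(panel, cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, pheno.line_sex_means(panel.line_ids)
        )
        return sn.fit_fixed_model(design)

    def test_single_balanced_locus_gives_v_q_four(self):
        model = self._balanced_fit(q=2.0)
        vc = sn.variance_components(model)
        # brute force: contributions are +-2 in equal numbers -> variance 4
        assert vc["V_Q"] == pytest.approx(4.0, abs=1e-10)
        assert vc["V_QQ"] == 0.0

    def test_v_p_identity_holds(self):
        model = self._balanced_fit(q=1.5, noise=1.0, seed=3)
        vc = sn.variance_components(model)
        total = vc["V_Q"] + vc["V_QQ"] + vc["V_QE"] + vc["V_QQE"] + vc["V_eps"]
        assert vc["V_P"] == pytest.approx(total, abs=1e-8)

    def test_components_recover_generator_truth(self):
        cfg = sn.SimConfig(n_lines=500, n_snps=30, n_transcripts=2, seed=19,
                           residual_sd_pheno=1.0)
        panel = sn.simulate_genotypes(cfg)
        loci = [panel.snp_ids[2], panel.snp_ids[15]]
        truth = sn.SimulationTruth(
            mu=20.0, qts_effects={loci[0]: 1.0, loci[1]: -0.8}
        )
        cfg = dataclasses.replace(cfg, truth=truth)
        pheno, _ = sn.simulate_phenotype(panel, cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=loci), ps, pheno.line_sex_means(panel.line_ids)
        )
        model = sn.fit_fixed_model(design)
        vc = sn.variance_components(model)
        # plug-in truth on the realised panel
        codes = panel.codes()
        g = 1.0 * codes[:, 2] + (-0.8) * codes[:, 15]
        v_q_true = g.var()
        se = v_q_true * np.sqrt(2.0 / (cfg.n_lines - 1)) * 3
        assert abs(vc["V_Q"] - v_q_true) < 3 * se + 0.05
        # residual per observation: replicate mean of two draws
        v_eps_true = cfg.residual_sd_pheno ** 2 / cfg.replicate_count
        assert vc["V_eps"] == pytest.approx(v_eps_true, rel=0.25)

    def test_noise_free_heritability_is_one(self):
        model = self._balanced_fit(q=2.0, noise=0.0)
        h2 = sn.heritability(model)
        assert h2["h2_T"] == pytest.approx(1.0, abs=1e-10)

    def test_table_proportions_decompose(self):
        h2 = sn.heritability_from_components(
            {"V_Q": 0.826, "V_QQ": 0.109, "V_eps": 0.065}
        )
        assert round(h2["h2_T"], 3) == 0.935
        assert h2["h2_T"] == pytest.approx(h2["h2_Q"] + h2["h2_QQ"]
                                           + h2["h2_QE"] + h2["h2_QQE"])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="V_P"):
            sn.heritability_from_components({"V_Q": 0.0, "V_eps": 0.0})

    @given(st.lists(st.floats(min_value=0.0, max_value=100.0),
                    min_size=5, max_size=5).filter(lambda v: sum(v) > 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decomposition_identity_is_universal(self, comps):
        keys = ("V_Q", "V_QQ", "V_QE", "V_QQE", "V_eps")
        h2 = sn.heritability_from_components(dict(zip(keys, comps)))
        total = h2["h2_Q"] + h2["h2_QQ"] + h2["h2_QE"] + h2["h2_QQE"]
        assert h2["h2_T"] == pytest.approx(total)
        assert 0.0 <= h2["h2_T"] <= 1.0 + 1e-12


class TestPrediction:
    def test_noise_free_r2_is_one(self):
        panel = balanced_pair_panel()
        locus = panel.snp_ids[0]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: 2.0})
        cfg = sn.SimConfig(n_lines=8, n_snps=2, min_minor_lines=2,
                           truth=truth, residual_sd_pheno=0.0, seed=1)
        pheno, _ = sn.simulate_phenotype(panel, cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, pheno.line_sex_means(panel.line_ids)
        )
        model = sn.fit_fixed_model(design)
        _, r2 = sn.predict_and_r2(model)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_r2_tracks_half_heritability_simulation(self):
        cfg = sn.SimConfig(n_lines=500, n_snps=20, n_transcripts=2, seed=23,
                           replicate_count=1)
        panel = sn.simulate_genotypes(cfg)
        locus = panel.snp_ids[5]
        code_sd = panel.codes()[:, 5].std()
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: 1.0})
        # residual SD chosen so genetic and residual variance match: h2 = 0.5
        cfg = dataclasses.replace(cfg, truth=truth, residual_sd_pheno=code_sd)
        pheno, _ = sn.simulate_phenotype(panel, cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, pheno.line_sex_means(panel.line_ids)
        )
        model = sn.fit_fixed_model(design)
        _, r2 = sn.predict_and_r2(model)
        assert abs(r2 - 0.5) < 0.05

    def test_destroyed_association_collapses_r2(self):
        rng = np.random.default_rng(31)
        model = self_fit = None
        panel = balanced_pair_panel()
        locus = panel.snp_ids[0]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: 2.0})
        cfg = sn.SimConfig(n_lines=8, n_snps=2, min_minor_lines=2,
                           truth=truth, residual_sd_pheno=0.0, seed=1)
        pheno, _ = sn.simulate_phenotype(panel, cfg)
        ps = sn.PredictorSet.from_genotypes(panel)
        design = sn.encode_design(
            sn.DesignSpec(loci=[locus]), ps, pheno.line_sex_means(panel.line_ids)
        )
        model = sn.fit_fixed_model(design)
        ghat, _ = sn.predict_and_r2(model)
        perm = rng.permutation(len(ghat))
        r = np.corrcoef(ghat[perm], design.y)[0, 1]
        assert r ** 2 < 0.3

    def test_constant_prediction_warns_and_returns_zero(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(10, 2, 1))
        ps = sn.PredictorSet(["p0"], values)
        y = rng.normal(size=(10, 2))
        design = sn.encode_design(
            sn.DesignSpec(loci=[], include_sex=False), ps, y
        )
        model = sn.fit_fixed_model(design)
        with pytest.warns(UserWarning, match="constant"):
            _, r2 = sn.predict_and_r2(model)
        assert r2 == 0.0
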