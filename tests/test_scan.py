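"""Two-step detection: prescreen behaviour, permutation threshold
conventions, 1D/2D scans, and model selection."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import startlenet as sn
from startlenet.mapping_layers import two_step_scan
from startlenet.scan import (
    PermutationNull,
    ScanConfig,
    candidate_pairs,
    critical_f_from_null,
    permutation_critical_f,
    prescreen_candidates,
)

from conftest import balanced_pair_panel


def _simulated_response(panel, truth, noise, seed):
    cfg = sn.SimConfig(
        n_lines=panel.n_lines, n_snps=panel.n_snps, n_transcripts=2,
        truth=truth, residual_sd_pheno=noise, seed=seed,
        min_minor_lines=min(4, panel.n_lines // 4),
    )
    pheno, _ = sn.simulate_phenotype(panel, cfg)
    return pheno.line_sex_means(panel.line_ids)


class TestPrescreen:
    def test_overwhelming_effect_is_retained(self):
        cfg = sn.SimConfig(n_lines=200, n_snps=50, n_transcripts=2, seed=3)
        panel = sn.simulate_genotypes(cfg)
        locus = panel.snp_ids[7]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: 5.0})
        Y = _simulated_response(panel, truth, noise=1.0, seed=3)
        cands = prescreen_candidates(
            Y, sn.PredictorSet.from_genotypes(panel), ScanConfig(seed=1)
        )
        assert locus in list(cands["id"])
        assert list(cands["id"])[0] == locus     # ordered by P

    def test_default_threshold_is_one_in_a_thousand(self):
        assert ScanConfig().prescreen_alpha == 0.001

    def test_null_retention_within_binomial_interval(self):
        # 10,000 null predictors at alpha = 0.001: 99% binomial interval
        rng = np.random.default_rng(29)
        L = 100
        values = rng.normal(size=(L, 2, 10_000))
        ps = sn.PredictorSet([f"p{i}" for i in range(10_000)], values)
        Y = rng.normal(size=(L, 2))
        cands = prescreen_candidates(Y, ps, ScanConfig(seed=1))
        from scipy import stats
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.001)
        assert lo <= len(cands) <= hi


class TestPermutationThreshold:
    def _null_setup(self, n_perm=200, seed=17, n_snps=50, n_lines=80):
        cfg = sn.SimConfig(n_lines=n_lines, n_snps=n_snps, n_transcripts=2,
                           seed=seed)
        panel = sn.simulate_genotypes(cfg)
        rng = np.random.default_rng(seed + 1)
        Y = rng.normal(20.0, 1.0, size=(n_lines, 2))
        ps = sn.PredictorSet.from_genotypes(panel)
        return Y, ps

    def test_minimum_permutations_order_statistic(self):
        Y, ps = self._null_setup()
        cfg = ScanConfig(n_permutations=19, seed=5)
        null = permutation_critical_f(Y, ps, cfg)
        # ceil(0.95 * 19) = 19: the largest null maximum
        assert null.critical_f == null.null_max.max()

    def test_fewer_than_19_permutations_rejected(self):
        with pytest.raises(ValueError, match="19"):
            ScanConfig(n_permutations=18)

    def test_critical_f_monotone_in_alpha(self):
        Y, ps = self._null_setup()
        null = permutation_critical_f(Y, ps, ScanConfig(n_permutations=100, seed=5))
        crits = [critical_f_from_null(null.null_max, a)
                 for a in (0.20, 0.10, 0.05)]
        assert crits[0] <= crits[1] <= crits[2]

    def test_experiment_wise_p_never_below_nominal(self):
        # max over 50 predictors makes P_EW >= the single-test nominal P
        Y, ps = self._null_setup()
        cfg = ScanConfig(n_permutations=200, seed=5)
        null = permutation_critical_f(Y, ps, cfg)
        res = sn.scan_main_effects(Y, ps, ps.ids, null)
        assert (res.table["p_ew"] >= res.table["p_nominal"]).all()

    def test_p_ew_has_add_one_smoothing_floor(self):
        null = PermutationNull(np.arange(200.0), 0.05, 200)
        assert null.p_ew([1e6])[0] == pytest.approx(1 / 201)

    def test_invariant_to_line_relabelling(self):
        Y, ps = self._null_setup()
        cfg = ScanConfig(n_permutations=100, seed=5)
        res_a = sn.scan_main_effects(Y, ps, ps.ids[:5],
                                     permutation_critical_f(Y, ps, cfg))
        ps_renamed = sn.PredictorSet(
            [f"renamed_{i}" for i in ps.ids], ps.values, None
        )
        res_b = sn.scan_main_effects(Y, ps_renamed, ps_renamed.ids[:5],
                                     permutation_critical_f(Y, ps_renamed, cfg))
        np.testing.assert_array_equal(res_a.table["p_ew"], res_b.table["p_ew"])


class TestEpistasisScan:
    def test_pair_count_is_k_choose_2(self):
        cands = [f"c{i}" for i in range(7)]
        ps = sn.PredictorSet(cands, np.random.default_rng(0).normal(
            size=(30, 2, 7)))
        pairs = candidate_pairs(cands, ps, ScanConfig(pair_budget=500))
        assert len(pairs) == 7 * 6 // 2

    def test_pair_budget_truncates_with_warning(self):
        cands = [f"c{i}" for i in range(10)]
        ps = sn.PredictorSet(cands, np.random.default_rng(0).normal(
            size=(30, 2, 10)))
        with pytest.warns(UserWarning, match="pair_budget"):
            pairs = candidate_pairs(cands, ps, ScanConfig(pair_budget=10))
        assert len(pairs) <= 10

    def test_xor_phenotype_detected_as_pure_epistasis(self):
        # y = product of the two +-1 codes: mains are exactly null
        panel = balanced_pair_panel(repeats=10)     # 40 balanced lines
        i, j = panel.snp_ids
        truth = sn.SimulationTruth(mu=20.0, epistasis_effects={(i, j): 3.0})
        Y = _simulated_response(panel, truth, noise=0.2, seed=1)
        ps = sn.PredictorSet.from_genotypes(panel)
        cfg = ScanConfig(n_permutations=100, seed=9, prescreen_alpha=0.999)
        null = permutation_critical_f(Y, ps, cfg, pairs=[(i, j)])
        mains = sn.scan_main_effects(Y, ps, [i, j], null)
        epi = sn.scan_epistasis(Y, ps, [(i, j)], null)
        assert not mains.table["passed"].any()
        assert epi.table["passed"].all()
        assert epi.table["F"].iloc[0] > 100 * mains.table["F"].max()
        # brute force on the noise-free 2x2 cell means: pure epistasis
        g = sn.synthetic_data.genetic_values(panel, truth).mean(axis=1)
        codes = panel.codes()
        for col in (0, 1):
            assert g[codes[:, col] == 1].mean() == pytest.approx(
                g[codes[:, col] == -1].mean())
        for ui in (+1, -1):
            for uj in (+1, -1):
                cell = (codes[:, 0] == ui) & (codes[:, 1] == uj)
                assert g[cell].mean() == pytest.approx(20.0 + 3.0 * ui * uj)

    def test_additive_truth_rarely_yields_epistasis(self):
        # 50 simulations with a strong additive locus and no epistasis
        false_epi = 0
        for rep in range(50):
            cfg = sn.SimConfig(n_lines=60, n_snps=20, n_transcripts=2,
                               seed=1000 + rep)
            panel = sn.simulate_genotypes(cfg)
            loci = [panel.snp_ids[3], panel.snp_ids[12]]
            truth = sn.SimulationTruth(
                mu=20.0, qts_effects={loci[0]: 2.0, loci[1]: 1.5})
            Y = _simulated_response(panel, truth, noise=1.0, seed=2000 + rep)
            ps = sn.PredictorSet.from_genotypes(panel)
            cfg_s = ScanConfig(n_permutations=100, seed=3000 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, null, _, epi_res, _ = two_step_scan(Y, ps, cfg_s)
            if epi_res is not None and epi_res.table["passed"].any():
                false_epi += 1
        assert 50 - false_epi >= 45

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_critical_f_is_an_order_statistic_of_the_null(self, seed):
        rng = np.random.default_rng(seed)
        null_max = rng.exponential(size=rng.integers(19, 200))
        crit = critical_f_from_null(null_max, 0.05)
        assert crit in null_max
        assert (null_max > crit).mean() <= 0.05


class TestSelectModel:
    def test_single_overwhelming_main_effect(self):
        cfg = sn.SimConfig(n_lines=150, n_snps=30, n_transcripts=2, seed=41)
        panel = sn.simulate_genotypes(cfg)
        locus = panel.snp_ids[11]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={locus: 4.0})
        Y = _simulated_response(panel, truth, noise=1.0, seed=41)
        ps = sn.PredictorSet.from_genotypes(panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            *_, spec = two_step_scan(Y, ps, ScanConfig(n_permutations=200, seed=1))
        assert spec.loci == [locus]
        assert spec.pairs == []

    def test_perfectly_linked_duplicate_keeps_smaller_position(self):
        cfg = sn.SimConfig(n_lines=150, n_snps=30, n_transcripts=2, seed=43)
        panel = sn.simulate_genotypes(cfg)
        # duplicate SNP 5's calls into SNP 6 (same chromosome, larger pos)
        calls = panel.calls.copy()
        calls[:, 6] = calls[:, 5]
        panel = sn.GenotypePanel(panel.line_ids, panel.snps.copy(), calls)
        first, second = panel.snp_ids[5], panel.snp_ids[6]
        truth = sn.SimulationTruth(mu=20.0, qts_effects={first: 3.0})
        Y = _simulated_response(panel, truth, noise=1.0, seed=43)
        ps = sn.PredictorSet.from_genotypes(panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            *_, spec = two_step_scan(Y, ps, ScanConfig(n_permutations=200, seed=1))
        # exactly one of the two perfectly linked copies survives, chosen by
        # the deterministic (chromosome, position) tie-break
        kept = {first, second} & set(spec.loci)
        assert len(kept) == 1
        assert kept == {min(first, second, key=ps.sort_key)}

    def test_selection_invariant_to_candidate_order(self):
        cfg = sn.SimConfig(n_lines=150, n_snps=30, n_transcripts=2, seed=47)
        panel = sn.simulate_genotypes(cfg)
        loci = [panel.snp_ids[4], panel.snp_ids[20]]
        truth = sn.SimulationTruth(
            mu=20.0, qts_effects={loci[0]: 2.5, loci[1]: 2.0})
        Y = _simulated_response(panel, truth, noise=1.0, seed=47)
        ps = sn.PredictorSet.from_genotypes(panel)
        rev = sn.PredictorSet(
            ps.ids[::-1], ps.values[:, :, ::-1],
            ps.positions.iloc[::-1] if ps.positions is not None else None,
        )
        cfg_s = ScanConfig(n_permutations=200, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            *_, spec_a = two_step_scan(Y, ps, cfg_s)
            *_, spec_b = two_step_scan(Y, rev, cfg_s)
        assert sorted(spec_a.loci) == sorted(spec_b.loci)
        assert sorted(map(tuple, spec_a.pairs)) == sorted(map(tuple, spec_b.pairs))

    def test_empty_selection_is_a_valid_model(self):
        rng = np.random.default_rng(51)
        L = 80
        values = rng.normal(size=(L, 2, 30))
        ps = sn.PredictorSet([f"p{i}" for i in range(30)], values)
        Y = rng.normal(20.0, 1.0, size=(L, 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            *_, spec = two_step_scan(Y, ps, ScanConfig(n_permutations=50, seed=1))
        assert spec.loci == []
        assert spec.pairs == []
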