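"""Shared fixtures: hand-built balanced panels and the planted-truth
recovery scenario used by the end-to-end tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import startlenet as sn


def balanced_pair_panel(repeats: int = 2) -> sn.GenotypePanel:
    """``4 * repeats`` lines x 2 SNPs covering every +-1 code combination.

    Codes are +1 for dosage 0 (major) and -1 for dosage 2 (minor), so the
    2x2 genotype table is perfectly balanced and main/epistasis columns
    are mutually orthogonal.
    """
    code_combos = [(+1, +1), (+1, -1), (-1, +1), (-1, -1)] * repeats
    calls = np.array([[1 - a, 1 - b] for a, b in code_combos])  # {0, 2}
    snps = pd.DataFrame(
        {
            "chrom": ["2L", "2L"],
            "pos": [100, 200],
            "major": ["A", "C"],
            "minor": ["T", "G"],
        },
        index=pd.Index(["2L_100_T", "2L_200_G"], name="snp_id"),
    )
    lines = [f"line_{k + 1:03d}" for k in range(4 * repeats)]
    return sn.GenotypePanel(lines, snps, calls)


@pytest.fixture(scope="session")
def small_panel() -> sn.GenotypePanel:
    cfg = sn.SimConfig(n_lines=60, n_snps=40, n_transcripts=6, seed=11)
    return sn.simulate_genotypes(cfg)


def make_recovery_scenario(seed: int) -> dict:
    """A panel with 3 planted QTSs, 2 mediated QTTs, and 2 tQTT edges.

    Three SNPs carry additive effects of 1 residual SD on the phenotype;
    two of them also drive one transcript each (strong cis effect), which
    makes those transcripts true QTTs; each of those transcripts is in
    turn regulated by one otherwise-inert transcript, the true tQTT
    regulators.
    """
    base = sn.SimConfig(
        n_lines=300, n_snps=200, n_transcripts=40, seed=seed,
        residual_sd_pheno=1.0, residual_sd_expr=1.0,
    )
    panel = sn.simulate_genotypes(base)
    s1, s2, s3 = panel.snp_ids[10], panel.snp_ids[80], panel.snp_ids[150]
    t1, t2, t3, t4 = "T0001", "T0002", "T0003", "T0004"
    truth = sn.SimulationTruth(
        mu=20.0,
        qts_effects={s1: 1.0, s2: 1.0, s3: 1.0},
        cis_trans_effects={(s1, t1): 2.0, (s2, t2): 2.0},
        tt_effects={(t3, t1): 1.0, (t4, t2): 1.0},
    )
    cfg = dataclasses.replace(base, truth=truth)
    expr = sn.simulate_expression(panel, cfg)
    pheno, _ = sn.simulate_phenotype(panel, cfg)
    return {
        "panel": panel,
        "expression": expr,
        "phenotype": pheno,
        "truth": truth,
        "qts": (s1, s2, s3),
        "qtt": (t1, t2),
        "tqtt": {(t3, t1), (t4, t2)},
        "config": cfg,
    }
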