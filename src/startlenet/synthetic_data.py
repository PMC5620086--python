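"""DGRP-like inbred-panel simulator with known ground truth.

Generates fully homozygous, no-missing genotype panels, sex-stratified
transcript abundances, and replicated startle phenotypes whose mean
structure follows the additive + epistatic + sex-interaction linear model
used throughout the package:

    y_kh = mu + sum_i q_i u_ik + sum_{i<j} qq_ij u_ijk + e_h
         + sum_i qe_ih u_ikh + sum_{i<j} qqe_ijh u_ijkh + eps_kh

with u_ik = +1 for the major-allele homozygote and -1 for the minor
(inbred lines carry no heterozygotes), u_ijk = u_ik * u_jk, and a
sum-to-zero sex effect.  Because every effect is known, downstream stages
can be tested by parameter recovery.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    SEXES,
    ExpressionPanel,
    GenotypePanel,
    PhenotypeTable,
    snp_id,
    write_expression,
    write_genotypes_tsv,
    write_genotypes_vcf,
    write_phenotypes,
)

_ALLELES = np.array(list("ACGT"))

#: Default chromosome arms of the D. melanogaster panel (chromosome 4 is
#: excluded from mapping but can be simulated for filter tests).
DEFAULT_CHROMOSOMES = ("X", "2L", "2R", "3L", "3R")


@dataclass
class SimulationTruth:
    """Ground-truth effects for one simulated study.

    All maps are keyed by SNP ids (``chrom_pos_allele``) and/or transcript
    ids.  ``sex_effects`` is ``(e_male, e_female)`` and must sum to zero so
    that ``mu`` is the grand mean; per-locus sex-interaction effects
    likewise sum to zero across the two sexes.
    """

    mu: float = 20.0
    qts_effects: dict = field(default_factory=dict)          # locus -> q_i
    epistasis_effects: dict = field(default_factory=dict)    # (i, j) -> qq_ij
    sex_effects: tuple = (0.0, 0.0)                          # (e_male, e_female)
    qe_effects: dict = field(default_factory=dict)           # (locus, sex) -> qe
    qqe_effects: dict = field(default_factory=dict)          # ((i, j), sex) -> qqe
    cis_trans_effects: dict = field(default_factory=dict)    # (locus, transcript) -> b
    tt_effects: dict = field(default_factory=dict)           # (regulator, target) -> b
    expr_sex_effects: dict = field(default_factory=dict)     # (transcript, sex) -> e

    def __post_init__(self) -> None:
        if abs(self.sex_effects[0] + self.sex_effects[1]) > 1e-12:
            raise ValueError("sex effects must sum to zero (sum-to-zero coding)")
        for keyed, name in ((self.qe_effects, "qe"), (self.expr_sex_effects, "expression sex")):
            by_unit: dict = {}
            for (unit, sex), val in keyed.items():
                if sex not in SEXES:
                    raise ValueError(f"unknown sex {sex!r} in {name} effects")
                by_unit[unit] = by_unit.get(unit, 0.0) + val
            for unit, total in by_unit.items():
                if abs(total) > 1e-12:
                    raise ValueError(
                        f"{name} effects for {unit} must sum to zero across sexes"
                    )
        by_pair: dict = {}
        for (pair, sex), val in self.qqe_effects.items():
            by_pair[pair] = by_pair.get(pair, 0.0) + val
        for pair, total in by_pair.items():
            if abs(total) > 1e-12:
                raise ValueError(f"qqe effects for {pair} must sum to zero across sexes")
        for reg, tgt in self.tt_effects:
            if reg == tgt:
                raise ValueError(f"self-regulation {reg} -> {tgt} is not allowed")

    # -- referenced ids ------------------------------------------------
    def loci(self) -> set:
        out = set(self.qts_effects)
        for i, j in self.epistasis_effects:
            out |= {i, j}
        out |= {locus for locus, _ in self.qe_effects}
        for (i, j), _ in self.qqe_effects:
            out |= {i, j}
        out |= {locus for locus, _ in self.cis_trans_effects}
        return out

    def transcripts(self) -> set:
        out = {t for _, t in self.cis_trans_effects}
        for reg, tgt in self.tt_effects:
            out |= {reg, tgt}
        out |= {t for t, _ in self.expr_sex_effects}
        return out


@dataclass
class SimConfig:
    """Panel dimensions, noise levels, and ground truth for one simulation.

    Defaults emulate the structure of the real panel at reduced scale:
    156 fully inbred lines, two phenotype replicates per line and sex, a
    minor allele present in at least 4 lines, and startle scores centred
    well inside the 45 s assay window.
    """

    n_lines: int = 156
    n_snps: int = 500
    n_transcripts: int = 50
    min_minor_lines: int = 4
    chromosomes: list | None = None        # [(label, n_snps), ...]
    ld_block_size: int = 1                 # SNPs per correlated block
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    residual_sd_pheno: float = 3.0         # seconds, per replicate
    residual_sd_expr: float = 1.0          # abundance units
    replicate_count: int = 2
    seed: int = 0
    bound_phenotype: bool = False          # clip to the [0, 45] s assay window
    expr_baseline_mean: float = 10.0
    expr_baseline_sd: float = 2.0
    ld_mutation_prob: float = 0.05         # per-line flip within an LD block
    maf_range: tuple = (0.1, 0.5)

    def __post_init__(self) -> None:
        if self.n_lines < 2 * self.min_minor_lines:
            raise ValueError(
                f"n_lines={self.n_lines} cannot host a minor allele in at "
                f"least {self.min_minor_lines} lines on both sides; need "
                f"n_lines >= {2 * self.min_minor_lines}"
            )
        if self.residual_sd_pheno < 0 or self.residual_sd_expr < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.chromosomes is None:
            n = len(DEFAULT_CHROMOSOMES)
            base, extra = divmod(self.n_snps, n)
            self.chromosomes = [
                (chrom, base + (1 if i < extra else 0))
                for i, chrom in enumerate(DEFAULT_CHROMOSOMES)
            ]
        if sum(c for _, c in self.chromosomes) != self.n_snps:
            raise ValueError("chromosome SNP allocation does not sum to n_snps")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _enforce_min_minor(z: np.ndarray, min_minor: int, rng) -> np.ndarray:
    """Flip majority-class lines until the rarer class holds >= min_minor."""
    n = z.size
    ones = int(z.sum())
    while min(ones, n - ones) < min_minor:
        if ones <= n - ones:
            z[rng.choice(np.flatnonzero(~z))] = True
        else:
            z[rng.choice(np.flatnonzero(z))] = False
        ones = int(z.sum())
    return z


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a fully homozygous, no-missing biallelic SNP panel.

    SNPs inside an LD block share a latent haplotype indicator that each
    SNP copies with a small per-line mutation probability; ``ld_block_size
    = 1`` gives independent SNPs.  Every SNP's minor allele is guaranteed
    to be present in at least ``config.min_minor_lines`` lines.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_lines
    line_ids = [f"line_{k + 1:03d}" for k in range(L)]
    meta, cols = [], []
    for chrom, n_chrom in config.chromosomes:
        pos = np.cumsum(rng.integers(500, 5000, size=n_chrom)) + int(
            rng.integers(1, 1000)
        )
        j = 0
        while j < n_chrom:
            block = min(config.ld_block_size, n_chrom - j)
            p = rng.uniform(*config.maf_range)
            base = rng.random(L) < p
            for b in range(block):
                if config.ld_block_size == 1:
                    z = rng.random(L) < rng.uniform(*config.maf_range)
                else:
                    z = base ^ (rng.random(L) < config.ld_mutation_prob)
                z = _enforce_min_minor(z.copy(), config.min_minor_lines, rng)
                a1, a2 = rng.choice(4, size=2, replace=False)
                a1, a2 = _ALLELES[a1], _ALLELES[a2]
                if int(z.sum()) <= L - int(z.sum()):
                    minor, major, dosage = a2, a1, 2 * z.astype(np.int64)
                else:
                    minor, major, dosage = a1, a2, 2 * (~z).astype(np.int64)
                meta.append((snp_id(chrom, int(pos[j + b]), minor),
                             chrom, int(pos[j + b]), major, minor))
                cols.append(dosage)
            j += block
    snps = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "major", "minor"]
    ).set_index("snp_id")
    return GenotypePanel(line_ids, snps, np.stack(cols, axis=1))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def transcript_ids(config: SimConfig) -> list:
    return [f"T{t + 1:04d}" for t in range(config.n_transcripts)]


def simulate_expression(panel: GenotypePanel, config: SimConfig) -> ExpressionPanel:
    """Simulate sex-stratified transcript abundance.

    Each transcript's value is baseline + cis/trans SNP effects x genotype
    code + transcript-transcript effects x regulator value (evaluated in
    topological order over the regulatory DAG) + sex effect + Gaussian
    noise, independently per line and sex.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = config.truth
    tids = transcript_ids(config)
    t_index = {t: i for i, t in enumerate(tids)}
    for t in truth.transcripts():
        if t not in t_index:
            raise ValueError(f"truth references unknown transcript {t!r}")
    snp_index = {s: i for i, s in enumerate(panel.snp_ids)}
    for locus, _ in truth.cis_trans_effects:
        if locus not in snp_index:
            raise ValueError(f"truth references unknown locus {locus!r}")

    g = nx.DiGraph()
    g.add_nodes_from(tids)
    g.add_edges_from(truth.tt_effects.keys())
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"transcript regulatory effects contain a cycle: {cycle}")
    order = list(nx.topological_sort(g))

    L, T = panel.n_lines, len(tids)
    codes = panel.codes()
    baselines = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=T)
    noise = rng.normal(0.0, config.residual_sd_expr, size=(L, T, 2))
    values = np.zeros((L, T, 2))
    sex_eff = np.zeros((T, 2))
    for (t, sex), e in truth.expr_sex_effects.items():
        sex_eff[t_index[t], SEXES.index(sex)] = e
    cis = {}
    for (locus, t), b in truth.cis_trans_effects.items():
        cis.setdefault(t, []).append((snp_index[locus], b))
    regs = {}
    for (reg, tgt), b in truth.tt_effects.items():
        regs.setdefault(tgt, []).append((reg, b))
    for t in order:
        i = t_index[t]
        v = np.full((L, 2), baselines[i])
        for j, b in cis.get(t, ()):
            v += b * codes[:, j][:, None]
        for reg, b in regs.get(t, ()):
            v += b * values[:, t_index[reg], :]
        v += sex_eff[i][None, :]
        values[:, i, :] = v + noise[:, i, :]
    return ExpressionPanel(panel.line_ids, tids, values)


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def genetic_values(panel: GenotypePanel, truth: SimulationTruth) -> np.ndarray:
    """Noise-free phenotypic means per line x sex, ``(n_lines, 2)``."""
    snp_index = {s: i for i, s in enumerate(panel.snp_ids)}
    codes = panel.codes()
    g = np.full((panel.n_lines, 2), float(truth.mu))
    e_male, e_female = truth.sex_effects
    g[:, SEXES.index("female")] += e_female
    g[:, SEXES.index("male")] += e_male
    def code(locus):
        if locus not in snp_index:
            raise ValueError(f"truth references unknown locus {locus!r}")
        return codes[:, snp_index[locus]]
    for locus, q in truth.qts_effects.items():
        g += q * code(locus)[:, None]
    for (i, j), qq in truth.epistasis_effects.items():
        g += qq * (code(i) * code(j))[:, None]
    for (locus, sex), qe in truth.qe_effects.items():
        g[:, SEXES.index(sex)] += qe * code(locus)
    for ((i, j), sex), qqe in truth.qqe_effects.items():
        g[:, SEXES.index(sex)] += qqe * code(i) * code(j)
    return g


def simulate_phenotype(panel: GenotypePanel, config: SimConfig):
    """Simulate startle scores; returns ``(PhenotypeTable, SimulationTruth)``.

    Replicates receive independent Gaussian residuals.  Values are clipped
    to the [0, 45] s assay window only when ``config.bound_phenotype`` is
    set; otherwise a warning is issued if the truth implies out-of-range
    means (clipping would break the linear-Gaussian structure that the
    recovery tests rely on).
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = config.truth
    g = genetic_values(panel, truth)
    R = config.replicate_count
    draws = g[:, :, None] + rng.normal(
        0.0, config.residual_sd_pheno, size=(panel.n_lines, 2, R)
    )
    if config.bound_phenotype:
        draws = np.clip(draws, 0.0, 45.0)
    elif g.min() < 0.0 or g.max() > 45.0:
        warnings.warn(
            "truth implies phenotypic means outside the [0, 45] s assay "
            "window; values are left unbounded", stacklevel=2,
        )
    rows = []
    for k, line in enumerate(panel.line_ids):
        for h, sex in enumerate(SEXES):
            for r in range(R):
                rows.append((line, sex, r + 1, draws[k, h, r]))
    table = PhenotypeTable(
        pd.DataFrame(rows, columns=["line", "sex", "replicate", "value"]),
        bounded=config.bound_phenotype,
    )
    return table, truth


def implied_phenotypic_variance(panel: GenotypePanel, config: SimConfig) -> float:
    """Analytic plug-in phenotypic variance over line x sex replicate draws.

    Population variance of the genetic means over the realised panel plus
    the residual replicate variance.
    """
    g = genetic_values(panel, config.truth)
    return float(g.var()) + config.residual_sd_pheno ** 2


# ---------------------------------------------------------------------------
# Truth serialization and panel writing
# ---------------------------------------------------------------------------

_SEP = "|"


def truth_to_dict(truth: SimulationTruth) -> dict:
    return {
        "mu": float(truth.mu),
        "sex_effects": {"male": float(truth.sex_effects[0]),
                        "female": float(truth.sex_effects[1])},
        "qts_effects": {k: float(v) for k, v in truth.qts_effects.items()},
        "epistasis_effects": {
            _SEP.join(k): float(v) for k, v in truth.epistasis_effects.items()
        },
        "qe_effects": {
            _SEP.join(k): float(v) for k, v in truth.qe_effects.items()
        },
        "qqe_effects": {
            _SEP.join((*pair, sex)): float(v)
            for (pair, sex), v in truth.qqe_effects.items()
        },
        "cis_trans_effects": {
            _SEP.join(k): float(v) for k, v in truth.cis_trans_effects.items()
        },
        "tt_effects": {
            _SEP.join(k): float(v) for k, v in truth.tt_effects.items()
        },
        "expr_sex_effects": {
            _SEP.join(k): float(v) for k, v in truth.expr_sex_effects.items()
        },
    }


def truth_from_dict(d: dict) -> SimulationTruth:
    def unkey2(m):
        return {tuple(k.split(_SEP)): v for k, v in m.items()}
    qqe = {}
    for k, v in d.get("qqe_effects", {}).items():
        i, j, sex = k.split(_SEP)
        qqe[((i, j), sex)] = v
    return SimulationTruth(
        mu=d["mu"],
        sex_effects=(d["sex_effects"]["male"], d["sex_effects"]["female"]),
        qts_effects=dict(d.get("qts_effects", {})),
        epistasis_effects=unkey2(d.get("epistasis_effects", {})),
        qe_effects=unkey2(d.get("qe_effects", {})),
        qqe_effects=qqe,
        cis_trans_effects=unkey2(d.get("cis_trans_effects", {})),
        tt_effects=unkey2(d.get("tt_effects", {})),
        expr_sex_effects=unkey2(d.get("expr_sex_effects", {})),
    )


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth_to_dict(truth), fh, sort_keys=True)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        return truth_from_dict(yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_panel(config: SimConfig, out_dir) -> dict:
    """Simulate a full panel and write it to ``out_dir``.

    Writes genotype TSV and VCF, expression TSV, phenotype TSV, the truth
    file, and a ``manifest.json`` listing SHA-256 checksums; returns the
    manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = simulate_genotypes(config)
    expr = simulate_expression(panel, config)
    pheno, truth = simulate_phenotype(panel, config)
    files = {
        "genotypes_tsv": "genotypes.tsv",
        "genotypes_vcf": "genotypes.vcf",
        "expression_tsv": "expression.tsv",
        "phenotypes_tsv": "phenotypes.tsv",
        "truth_yaml": "truth.yaml",
    }
    write_genotypes_tsv(panel, out / files["genotypes_tsv"])
    write_genotypes_vcf(panel, out / files["genotypes_vcf"])
    write_expression(expr, out / files["expression_tsv"])
    write_phenotypes(pheno, out / files["phenotypes_tsv"])
    write_truth(truth, out / files["truth_yaml"])
    manifest = {
        "seed": config.seed,
        "n_lines": config.n_lines,
        "n_snps": config.n_snps,
        "n_transcripts": config.n_transcripts,
        "files": {
            key: {"path": name, "sha256": _sha256(out / name)}
            for key, name in files.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
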