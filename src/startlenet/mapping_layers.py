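"""The four association layers: QTS, QTT, tQTS, tQTT.

Each layer runs the same two-step machinery — nominal prescreen,
permutation-calibrated experiment-wise threshold, 1D and 2D scans, joint
model selection, Gibbs effect estimation, and heritability decomposition —
with layer-specific responses and predictor sets:

* QTS:  SNP codes -> startle phenotype (line x sex replicate means)
* QTT:  per-sex standardized transcript abundance -> startle phenotype
* tQTS: SNP codes -> abundance of each significant QTT
* tQTT: standardized transcripts (target excluded) -> each significant QTT

SNP hygiene follows the study's rules: minor allele in at least 4 lines,
called in at least 60 lines (when read-level call counts are available),
and the very short chromosome 4 excluded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    LAYERS,
    ExpressionPanel,
    GenotypePanel,
    PhenotypeTable,
    write_association_table,
)
from .model_core import (
    DesignSpec,
    FittedModel,
    GibbsConfig,
    PredictorSet,
    encode_design,
    fit_fixed_model,
    gibbs_estimate,
    heritability,
    predict_and_r2,
    variance_components,
)
from .scan import (
    PermutationNull,
    ScanConfig,
    ScanResult,
    candidate_pairs,
    permutation_critical_f,
    prescreen_candidates,
    scan_epistasis,
    scan_main_effects,
    select_model,
)

logger = logging.getLogger(__name__)

#: Autosomal chromosome arms of the mapping panel.
AUTOSOMES = ("2L", "2R", "3L", "3R")


@dataclass
class AssociationRecord:
    """One retained association: a typed, signed, sex-annotated edge.

    ``source`` holds one id for main effects and exactly two for epistatic
    terms.  ``effect`` is the posterior-mean main (or epistasis) effect;
    the per-sex effects fold in the sex-interaction component
    (female = effect + qe, male = effect - qe under the +1/-1 contrast).
    ``h2`` is the term's share of phenotypic (or transcript) variance.
    """

    layer: str
    source: tuple
    target: str
    effect: float
    effect_female: float
    effect_male: float
    neglog10_p_ew: float
    tier: str
    h2: float

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        self.source = tuple(self.source)
        if len(self.source) not in (1, 2):
            raise ValueError("source must hold one id or an epistatic pair")

    @property
    def is_epistatic(self) -> bool:
        return len(self.source) == 2

    def as_row(self) -> tuple:
        return (
            self.layer, self.source[0],
            self.source[1] if self.is_epistatic else "",
            self.target, self.effect, self.effect_female, self.effect_male,
            self.neglog10_p_ew, self.tier, self.h2,
        )


@dataclass
class StudyConfig:
    """Settings for a full four-layer run."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    gibbs: GibbsConfig = field(default_factory=GibbsConfig)
    trait: str = "startle"
    min_minor_lines: int = 4
    min_called_lines: int = 60
    exclude_chroms: tuple = ("4",)
    autosomes_only: bool = False       # restrict the prescreen panel to autosomes
    scan_pairs: bool = True
    tqtt_target_tier: str | None = None  # None = all significant QTTs
    seed: int = 0


# ---------------------------------------------------------------------------
# SNP hygiene filters
# ---------------------------------------------------------------------------

def apply_snp_filters(
    panel: GenotypePanel,
    min_minor_lines: int = 4,
    min_called_lines: int = 60,
    exclude_chroms=("4",),
    autosomes_only: bool = False,
) -> tuple[GenotypePanel, dict]:
    """Remove SNPs violating the study's hygiene rules.

    Rules, applied in order (each removed SNP is counted under the first
    rule it violates): excluded chromosome (the very short chromosome 4 by
    default, optionally everything non-autosomal), minor allele present in
    fewer than ``min_minor_lines`` lines, and — when the metadata carries a
    ``called_lines`` column — called in fewer than ``min_called_lines``
    lines.  Returns the filtered panel and a per-rule removal report.
    """
    report = {"excluded_chrom": 0, "min_minor_lines": 0, "min_called_lines": 0}
    excluded = set(exclude_chroms)
    n2 = (panel.calls == 2).sum(axis=0)
    minor_lines = np.minimum(n2, panel.n_lines - n2)
    if "called_lines" in panel.snps.columns:
        called = panel.snps["called_lines"].to_numpy()
    else:
        called = np.full(panel.n_snps, panel.n_lines)
    keep = []
    for j, (sid, row) in enumerate(panel.snps.iterrows()):
        chrom = str(row["chrom"])
        if chrom in excluded or (autosomes_only and chrom not in AUTOSOMES):
            report["excluded_chrom"] += 1
        elif minor_lines[j] < min_minor_lines:
            report["min_minor_lines"] += 1
        elif called[j] < min_called_lines:
            report["min_called_lines"] += 1
        else:
            keep.append(sid)
    if not keep:
        raise ValueError("all SNPs removed by hygiene filters")
    out = panel.subset(keep) if len(keep) < panel.n_snps else panel
    report["input_snps"] = panel.n_snps
    report["output_snps"] = len(keep)
    return out, report


# ---------------------------------------------------------------------------
# One layer
# ---------------------------------------------------------------------------

def _tier_label(neglog10_p_ew: float, config: ScanConfig) -> str:
    if neglog10_p_ew >= config.tier_high:
        return "high"
    if neglog10_p_ew >= config.tier_report:
        return "report"
    return "significant"


def two_step_scan(
    response: np.ndarray,
    predictors: PredictorSet,
    config: ScanConfig,
    do_pairs: bool = True,
):
    """Prescreen, permutation threshold, 1D/2D scans, model selection.

    Returns ``(candidates, null, main_result, epi_result, spec)``; the
    null and results are ``None`` when no candidate survives the
    prescreen (the fast path on a null panel).
    """
    degenerate = predictors.degenerate_ids()
    if degenerate:
        warnings.warn(
            f"excluding {len(degenerate)} zero-variance predictors", stacklevel=2
        )
        predictors = predictors.subset(
            [p for p in predictors.ids if p not in set(degenerate)]
        )
    cands = prescreen_candidates(response, predictors, config)
    if cands.empty:
        return cands, None, None, None, DesignSpec(response="selected")
    pairs = candidate_pairs(list(cands["id"]), predictors, config) if do_pairs else []
    null = permutation_critical_f(response, predictors, config, pairs=pairs)
    main_result = scan_main_effects(response, predictors, list(cands["id"]), null)
    epi_result = scan_epistasis(response, predictors, pairs, null) if pairs else None
    spec = select_model(main_result, epi_result, predictors, response, config)
    return cands, null, main_result, epi_result, spec


def _records_from_fit(
    layer: str,
    target: str,
    model: FittedModel,
    main_result: ScanResult,
    epi_result: ScanResult | None,
    config: ScanConfig,
) -> list[AssociationRecord]:
    h2 = model.heritabilities
    per_term = h2.get("per_term", {})
    post = model.posterior

    def estimate(label: tuple) -> float:
        if label not in model.labels:
            return 0.0
        i = model.labels.index(label)
        return float(post.mean[i]) if post is not None else float(model.beta[i])

    records = []
    mt = main_result.table.set_index("id1")
    for locus in model.design.spec.loci:
        if locus not in mt.index or not bool(mt.loc[locus, "passed"]):
            continue   # pair-member locus not significant on its own
        q = estimate(("q", locus))
        qe = estimate(("qe", locus))
        nlp = float(mt.loc[locus, "neglog10_p_ew"])
        records.append(AssociationRecord(
            layer=layer, source=(locus,), target=target,
            effect=q, effect_female=q + qe, effect_male=q - qe,
            neglog10_p_ew=nlp, tier=_tier_label(nlp, config),
            h2=float(per_term.get(("q", locus), 0.0)
                     + per_term.get(("qe", locus), 0.0)),
        ))
    if epi_result is not None and model.design.spec.pairs:
        et = epi_result.table.set_index(["id1", "id2"])
        for pair in model.design.spec.pairs:
            key = tuple(pair)
            if key not in et.index:
                continue
            qq = estimate(("qq", *key))
            qqe = estimate(("qqe", *key))
            nlp = float(et.loc[key, "neglog10_p_ew"])
            records.append(AssociationRecord(
                layer=layer, source=key, target=target,
                effect=qq, effect_female=qq + qqe, effect_male=qq - qqe,
                neglog10_p_ew=nlp, tier=_tier_label(nlp, config),
                h2=float(per_term.get(("qq", *key), 0.0)
                         + per_term.get(("qqe", *key), 0.0)),
            ))
    return records


def map_layer(
    layer: str,
    response: np.ndarray,
    predictors: PredictorSet,
    config: StudyConfig,
    target: str,
    scan_seed: int | None = None,
    gibbs_seed: int | None = None,
) -> tuple[list[AssociationRecord], FittedModel | None]:
    """Run the full two-step pipeline for one response and predictor set.

    Returns the retained association records and the final joint fitted
    model (``None`` when nothing is retained).
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    scfg = config.scan if scan_seed is None else dataclasses.replace(
        config.scan, seed=scan_seed)
    _, null, main_result, epi_result, spec = two_step_scan(
        response, predictors, scfg, do_pairs=config.scan_pairs
    )
    if not spec.loci:
        return [], None
    design = encode_design(spec, predictors.subset(spec.loci), np.asarray(response))
    model = fit_fixed_model(design)
    variance_components(model)
    heritability(model)
    predict_and_r2(model)
    gcfg = config.gibbs if gibbs_seed is None else dataclasses.replace(
        config.gibbs, seed=gibbs_seed)
    model.posterior = gibbs_estimate(design, gcfg)
    records = _records_from_fit(layer, target, model, main_result, epi_result, scfg)
    return records, model


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    records: dict                      # layer -> list[AssociationRecord]
    models: dict                       # (layer, target) -> FittedModel
    heritability_table: pd.DataFrame
    filter_report: dict
    manifest: dict

    def all_records(self) -> list[AssociationRecord]:
        return [r for layer in LAYERS for r in self.records.get(layer, [])]


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _h2_row(layer, target, model: FittedModel) -> dict:
    h2 = model.heritabilities
    return {
        "layer": layer, "target": target,
        "h2_Q": h2["h2_Q"], "h2_QQ": h2["h2_QQ"],
        "h2_QE": h2["h2_QE"], "h2_QQE": h2["h2_QQE"], "h2_T": h2["h2_T"],
        "r2_ghat_y": model.r2_ghat_y,
        "n_terms": len(model.design.spec.loci) + len(model.design.spec.pairs),
    }


def run_full_study(
    genotypes: GenotypePanel,
    expression: ExpressionPanel,
    phenotype: PhenotypeTable,
    config: StudyConfig | None = None,
    out_dir=None,
) -> StudyResult:
    """Run all four association layers and assemble the results.

    Inputs are cross-validated on line ids (the genotype panel's order is
    canonical).  Outputs, when ``out_dir`` is given: ``qts.tsv``,
    ``qtt.tsv``, ``tqts.tsv``, ``tqtt.tsv``, ``heritability.tsv`` and a
    machine-readable ``manifest.yaml``.  The run is deterministic under
    ``config.seed``.
    """
    if config is None:
        config = StudyConfig()
    lines = genotypes.line_ids
    stage = "line cross-validation"
    missing_e = [l for l in lines if l not in set(expression.line_ids)]
    missing_p = [l for l in lines if l not in set(phenotype.line_ids)]
    if missing_e or missing_p:
        raise ValueError(
            f"stage {stage!r}: lines missing from "
            f"expression={missing_e[:5]} phenotype={missing_p[:5]}"
        )
    order = [expression.line_ids.index(l) for l in lines]
    expression = ExpressionPanel(
        lines, expression.transcript_ids, expression.values[order]
    )

    filtered, report = apply_snp_filters(
        genotypes,
        min_minor_lines=config.min_minor_lines,
        min_called_lines=config.min_called_lines,
        exclude_chroms=config.exclude_chroms,
        autosomes_only=config.autosomes_only,
    )
    y_pheno = phenotype.line_sex_means(lines)
    snp_predictors = PredictorSet.from_genotypes(filtered)
    ss = np.random.SeedSequence(config.seed)

    records: dict = {layer: [] for layer in LAYERS}
    models: dict = {}
    h2_rows = []

    def run_stage(layer, response, predictors, target):
        s1, s2 = ss.spawn(2)
        try:
            recs, model = map_layer(
                layer, response, predictors, config, target,
                scan_seed=_stage_seed(s1), gibbs_seed=_stage_seed(s2),
            )
        except Exception as e:
            raise RuntimeError(f"stage {layer}:{target} failed: {e}") from e
        records[layer].extend(recs)
        if model is not None:
            models[(layer, target)] = model
            h2_rows.append(_h2_row(layer, target, model))

    run_stage("QTS", y_pheno, snp_predictors, config.trait)
    run_stage("QTT", y_pheno, PredictorSet.from_expression(expression), config.trait)

    qtt_targets = []
    for rec in records["QTT"]:
        if rec.is_epistatic:
            continue
        if config.tqtt_target_tier == "high" and rec.tier != "high":
            continue
        if config.tqtt_target_tier == "report" and rec.tier == "significant":
            continue
        qtt_targets.append(rec.source[0])
    if not qtt_targets:
        warnings.warn("no significant QTTs; tQTS/tQTT layers are empty",
                      stacklevel=2)
    for t in qtt_targets:
        y_t = expression.transcript(t)
        run_stage("tQTS", y_t, snp_predictors, t)
        run_stage(
            "tQTT", y_t, PredictorSet.from_expression(expression, exclude=(t,)), t
        )

    h2_table = pd.DataFrame(
        h2_rows, columns=["layer", "target", "h2_Q", "h2_QQ", "h2_QE",
                          "h2_QQE", "h2_T", "r2_ghat_y", "n_terms"],
    )
    manifest = {
        "seed": config.seed,
        "trait": config.trait,
        "n_lines": len(lines),
        "n_snps_input": genotypes.n_snps,
        "n_snps_mapped": filtered.n_snps,
        "n_transcripts": expression.n_transcripts,
        "scan": dataclasses.asdict(config.scan),
        "gibbs": dataclasses.asdict(config.gibbs),
        "filter_report": report,
        "qtt_targets": qtt_targets,
        "records_per_layer": {layer: len(records[layer]) for layer in LAYERS},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {}
        for layer, name in (("QTS", "qts.tsv"), ("QTT", "qtt.tsv"),
                            ("tQTS", "tqts.tsv"), ("tQTT", "tqtt.tsv")):
            write_association_table(records[layer], out / name)
            files[name] = _sha256(out / name)
        h2_table.to_csv(out / "heritability.tsv", sep="\t", index=False,
                        float_format="%.10g")
        files["heritability.tsv"] = _sha256(out / "heritability.tsv")
        manifest["files"] = files
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return StudyResult(records, models, h2_table, report, manifest)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
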