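"""Data containers and file formats for inbred-panel multi-omics studies.

The three primary containers mirror the structure of the DGRP resource:
fully homozygous biallelic genotype calls with no missing data
(:class:`GenotypePanel`), sex-stratified transcript abundance
(:class:`ExpressionPanel`), and replicated startle scores bounded by the
45-second assay window (:class:`PhenotypeTable`).  Readers enforce the
study's data-hygiene rules at parse time: a heterozygous or missing call,
a multi-allelic site, or an out-of-range phenotype is a parse error that
names the offending file, record, and rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sex slice order used throughout the package.  The sex contrast used in
#: design encoding is +1 for females and -1 for males.
SEXES: tuple[str, str] = ("female", "male")
SEX_CONTRAST: dict[str, int] = {"female": +1, "male": -1}

#: Startle assay bounds in seconds (activity within a 45 s window).
PHENOTYPE_BOUNDS: tuple[float, float] = (0.0, 45.0)

#: Canonical ordering of the four association layers.
LAYERS: tuple[str, ...] = ("QTS", "QTT", "tQTS", "tQTT")


class FormatError(ValueError):
    """A file violated a structural or data-hygiene rule.

    The message always names the file, the offending record, and the rule.
    """


def _err(path, record: str, rule: str) -> FormatError:
    return FormatError(f"{path}: {record}: {rule}")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Homozygous biallelic SNP calls for a panel of inbred lines.

    Parameters
    ----------
    line_ids
        Ordered line labels.
    snps
        Per-SNP metadata indexed by SNP id (``chrom_pos_minorallele``),
        with columns ``chrom``, ``pos`` (1-based bp), ``major``, ``minor``
        and optionally ``called_lines`` (read-level call count, used by the
        coverage filter when available).
    calls
        ``(n_lines, n_snps)`` minor-allele dosage matrix with values in
        {0, 2}: inbred lines are fully homozygous, so the heterozygous
        dosage 1 never occurs.
    """

    line_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.calls = np.asarray(self.calls)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        if self.calls.shape != (len(self.line_ids), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snps)} SNPs"
            )
        if np.isnan(self.calls.astype(float)).any():
            raise ValueError("genotype calls contain missing values")
        bad = ~np.isin(self.calls, (0, 2))
        if bad.any():
            k, j = np.argwhere(bad)[0]
            raise ValueError(
                f"call for line {self.line_ids[k]} at SNP "
                f"{self.snps.index[j]} is {self.calls[k, j]!r}; homozygous "
                "dosage must be 0 or 2"
            )
        for col in ("chrom", "pos", "major", "minor"):
            if col not in self.snps.columns:
                raise ValueError(f"SNP metadata lacks column {col!r}")
        same = self.snps["major"] == self.snps["minor"]
        if same.any():
            raise ValueError(
                f"SNP {self.snps.index[same.argmax()]} has identical alleles"
            )
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- convenience --------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    def codes(self) -> np.ndarray:
        """Design codes: +1 for the major-allele homozygote, -1 for minor."""
        return (1 - self.calls).astype(float)

    def subset(self, snp_ids) -> "GenotypePanel":
        idx = [self.snps.index.get_loc(s) for s in snp_ids]
        return GenotypePanel(
            self.line_ids, self.snps.iloc[idx].copy(), self.calls[:, idx].copy()
        )


@dataclass
class ExpressionPanel:
    """Sex-stratified transcript abundance for a panel of lines.

    ``values`` has shape ``(n_lines, n_transcripts, 2)`` with the last axis
    ordered as :data:`SEXES` (female, male).  Units are arbitrary
    continuous abundance.
    """

    line_ids: list[str]
    transcript_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.transcript_ids = list(self.transcript_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        want = (len(self.line_ids), len(self.transcript_ids), 2)
        if self.values.shape != want:
            raise ValueError(
                f"expression values shape {self.values.shape} != {want} "
                "(both sex slices required for every line)"
            )
        if not np.isfinite(self.values).all():
            k, t, h = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite abundance for line {self.line_ids[k]}, "
                f"transcript {self.transcript_ids[t]}, sex {SEXES[h]}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def transcript(self, transcript_id: str) -> np.ndarray:
        """Abundance of one transcript as a ``(n_lines, 2)`` array."""
        t = self.transcript_ids.index(transcript_id)
        return self.values[:, t, :]


@dataclass
class PhenotypeTable:
    """Startle scores per line x sex x replicate.

    ``records`` has columns ``line``, ``sex``, ``replicate``, ``value``
    (seconds active in the 45 s post-disturbance window).
    """

    records: pd.DataFrame
    bounded: bool = True

    def __post_init__(self) -> None:
        self.records = pd.DataFrame(self.records).reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        for col in ("line", "sex", "replicate", "value"):
            if col not in self.records.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        bad_sex = ~self.records["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValueError(
                f"unknown sex label {self.records.loc[bad_sex.idxmax(), 'sex']!r}"
            )
        if self.bounded:
            lo, hi = PHENOTYPE_BOUNDS
            v = self.records["value"]
            bad = (v < lo) | (v > hi)
            if bad.any():
                i = bad.idxmax()
                r = self.records.loc[i]
                raise ValueError(
                    f"record {i} (line {r['line']}, {r['sex']}, replicate "
                    f"{r['replicate']}): value {r['value']} outside "
                    f"[{lo}, {hi}] s"
                )
        # replicate indices complete per line x sex
        reps = self.records.groupby(["line", "sex"])["replicate"].apply(
            lambda s: tuple(sorted(s))
        )
        if len(set(reps)) > 1:
            raise ValueError(
                "replicate indices are not complete for every line x sex: "
                f"found patterns {sorted(set(reps))}"
            )

    @property
    def line_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["line"]))

    def line_sex_means(self, line_ids=None) -> np.ndarray:
        """Replicate-averaged scores as ``(n_lines, 2)`` (female, male)."""
        if line_ids is None:
            line_ids = self.line_ids
        m = self.records.groupby(["line", "sex"])["value"].mean()
        out = np.empty((len(line_ids), 2))
        for k, line in enumerate(line_ids):
            for h, sex in enumerate(SEXES):
                try:
                    out[k, h] = m[(line, sex)]
                except KeyError:
                    raise ValueError(f"line {line} lacks a {sex} slice") from None
        return out


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

def snp_id(chrom: str, pos: int, minor: str) -> str:
    """Canonical SNP name, e.g. ``2R_1441701_T`` (1-based position)."""
    return f"{chrom}_{pos}_{minor}"


def write_genotypes_tsv(panel: GenotypePanel, path) -> None:
    """Write a genotype matrix: rows = SNPs, columns = line ids, cells in {0, 2}.

    A ``major_allele`` column is included so the file round-trips losslessly
    (the SNP id carries only the minor allele).
    """
    df = pd.DataFrame(
        panel.calls.T, index=panel.snps.index, columns=panel.line_ids
    )
    df.insert(0, "major_allele", panel.snps["major"].to_numpy())
    df.index.name = "snp_id"
    df.to_csv(path, sep="\t")


def read_genotypes(path, format: str | None = None) -> GenotypePanel:
    """Read a genotype panel from TSV or VCF.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` or ``"vcf"``; inferred from the extension when omitted.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _parse_snp_id(sid: str, path) -> tuple[str, int, str]:
    parts = sid.rsplit("_", 2)
    if len(parts) != 3:
        raise _err(path, f"SNP {sid!r}", "id must be chrom_pos_allele")
    chrom, pos, allele = parts
    try:
        return chrom, int(pos), allele
    except ValueError:
        raise _err(path, f"SNP {sid!r}", "position must be an integer") from None


def _read_genotypes_tsv(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise _err(path, "header", "no line columns found")
    if "major_allele" in df.columns:
        major = df.pop("major_allele").to_list()
    else:
        major = ["N"] * len(df)
    line_ids = list(df.columns)
    calls = np.empty((len(line_ids), len(df)), dtype=np.int64)
    for j, (sid, row) in enumerate(df.iterrows()):
        for k, line in enumerate(line_ids):
            cell = row[line]
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise _err(path, f"SNP {sid}, line {line}",
                           f"call {cell!r} is not an integer dosage")
            if v == 1:
                raise _err(path, f"SNP {sid}, line {line}",
                           "heterozygous dosage 1 (all calls must be homozygous)")
            if v not in (0, 2):
                raise _err(path, f"SNP {sid}, line {line}",
                           f"dosage {v} outside {{0, 2}}")
            calls[k, j] = v
    meta = []
    for sid, maj in zip(df.index, major):
        chrom, pos, minor = _parse_snp_id(str(sid), path)
        meta.append((str(sid), chrom, pos, maj, minor))
    snps = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "major", "minor"]
    ).set_index("snp_id")
    try:
        return GenotypePanel(line_ids, snps, calls)
    except ValueError as e:
        raise _err(path, "panel", str(e)) from e


def _read_genotypes_vcf(path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        rec = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise _err(path, rec,
                       f"multi-allelic site (ALT={var.ALT}); only biallelic "
                       "SNPs are supported")
        dosages = np.empty(len(line_ids), dtype=np.int64)
        for k, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise _err(path, f"{rec}, line {line_ids[k]}",
                           "missing call ./. (no missing data allowed)")
            if a != b:
                raise _err(path, f"{rec}, line {line_ids[k]}",
                           f"heterozygous call {a}/{b} (all calls must be "
                           "homozygous)")
            dosages[k] = 2 * int(a == 1)
        rows.append(dosages)
        meta.append((snp_id(var.CHROM, var.POS, var.ALT[0]),
                     var.CHROM, var.POS, var.REF, var.ALT[0]))
    if not rows:
        raise _err(path, "file", "no variant records")
    snps = pd.DataFrame(
        meta, columns=["snp_id", "chrom", "pos", "major", "minor"]
    ).set_index("snp_id")
    try:
        return GenotypePanel(line_ids, snps, np.stack(rows, axis=1))
    except ValueError as e:
        raise _err(path, "panel", str(e)) from e


def write_genotypes_vcf(panel: GenotypePanel, path) -> None:
    """Write a minimal VCF 4.2 with homozygous GT calls (REF=major, ALT=minor)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.line_ids) + "\n")
        for j, (sid, row) in enumerate(panel.snps.iterrows()):
            gts = "\t".join(
                "1/1" if panel.calls[k, j] == 2 else "0/0"
                for k in range(panel.n_lines)
            )
            fh.write(f"{row['chrom']}\t{row['pos']}\t{sid}\t{row['major']}\t"
                     f"{row['minor']}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Expression and phenotype I/O
# ---------------------------------------------------------------------------

def write_expression(panel: ExpressionPanel, path) -> None:
    """Write expression as TSV: rows = transcripts, columns = ``line:sex``."""
    cols = [f"{line}:{sex}" for line in panel.line_ids for sex in SEXES]
    flat = panel.values.transpose(0, 2, 1).reshape(
        panel.n_lines * 2, panel.n_transcripts
    ).T
    df = pd.DataFrame(flat, index=panel.transcript_ids, columns=cols)
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression(path, lines=None) -> ExpressionPanel:
    """Read a ``transcript x line:sex`` abundance TSV.

    Parameters
    ----------
    lines
        Optional reference line-id collection; any expression line absent
        from it is a parse error (cross-check against the genotype panel).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    pairs = []
    for col in df.columns:
        if ":" not in col:
            raise _err(path, f"column {col!r}", "expected 'line:sex' header")
        line, sex = col.rsplit(":", 1)
        if sex not in SEXES:
            raise _err(path, f"column {col!r}", f"unknown sex label {sex!r}")
        pairs.append((line, sex))
    line_ids = list(dict.fromkeys(line for line, _ in pairs))
    have = set(pairs)
    for line in line_ids:
        for sex in SEXES:
            if (line, sex) not in have:
                raise _err(path, f"line {line}", f"missing {sex} slice")
    if lines is not None:
        known = set(lines)
        for line in line_ids:
            if line not in known:
                raise _err(path, f"line {line}",
                           "not present in the reference line set")
    tids = [str(t) for t in df.index]
    values = np.empty((len(line_ids), len(tids), 2))
    for k, line in enumerate(line_ids):
        for h, sex in enumerate(SEXES):
            values[k, :, h] = df[f"{line}:{sex}"].to_numpy()
    try:
        return ExpressionPanel(line_ids, tids, values)
    except ValueError as e:
        raise _err(path, "panel", str(e)) from e


def write_phenotypes(table: PhenotypeTable, path) -> None:
    df = table.records.rename(columns={"value": "value_seconds"})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_phenotypes(path, bounded: bool = True, lines=None) -> PhenotypeTable:
    """Read a phenotype TSV (columns line, sex, replicate, value_seconds).

    ``bounded`` enforces the [0, 45] s assay window (on by default for real
    data; synthetic unbounded data may switch it off).
    """
    df = pd.read_csv(path, sep="\t", dtype={"line": str},
                     float_precision="round_trip")
    if "value_seconds" in df.columns:
        df = df.rename(columns={"value_seconds": "value"})
    if lines is not None:
        known = set(lines)
        for line in dict.fromkeys(df["line"]):
            if line not in known:
                raise _err(path, f"line {line}",
                           "not present in the reference line set")
    try:
        return PhenotypeTable(df, bounded=bounded)
    except ValueError as e:
        raise _err(path, "table", str(e)) from e


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = [
    "layer", "source", "source2", "target", "effect",
    "effect_female", "effect_male", "neglog10_p_ew", "tier", "h2",
]


def _assoc_sort_key(df: pd.DataFrame) -> pd.DataFrame:
    order = {layer: i for i, layer in enumerate(LAYERS)}
    def pos_key(s):
        try:
            chrom, pos, _ = s.rsplit("_", 2)
            return (0, chrom, int(pos), s)
        except (ValueError, AttributeError):
            return (1, str(s), 0, str(s))
    key = df.assign(
        _layer=df["layer"].map(order),
        _src=[pos_key(s) for s in df["source"]],
        _tgt=df["target"].astype(str),
    )
    return key.sort_values(["_layer", "_src", "_tgt"], kind="mergesort").index


def write_association_table(records, path) -> None:
    """Write association records to TSV with a stable column and row order.

    ``records`` is an iterable of :class:`~startlenet.mapping_layers.AssociationRecord`
    or an equivalent DataFrame.  Rows are ordered by layer, then genomic
    position or transcript id; ``neglog10_p_ew`` is printed with 2 decimals.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.as_row() for r in records], columns=ASSOC_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=ASSOC_COLUMNS)
    else:
        df = df.loc[_assoc_sort_key(df), ASSOC_COLUMNS]
        df["neglog10_p_ew"] = df["neglog10_p_ew"].map(lambda v: f"{v:.2f}")
        for col in ("effect", "effect_female", "effect_male", "h2"):
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.6g}"
            )
    df.to_csv(path, sep="\t", index=False)


def read_association_table(path) -> pd.DataFrame:
    """Read an association TSV back into a DataFrame (layer rows typed)."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    if df.empty:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    bad = ~df["layer"].isin(LAYERS)
    if bad.any():
        raise _err(path, f"row {bad.idxmax()}",
                   f"unknown layer {df.loc[bad.idxmax(), 'layer']!r}")
    return df
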