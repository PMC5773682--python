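"""File I/O for every format the pipeline touches.

Strict dialects throughout: tab-separated text, ``.`` for missing values, no
quoting, 1-based VCF-convention coordinates.  Readers reject out-of-domain
values instead of coercing them; writers are deterministic (byte-identical
output for identical inputs).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig

HLA_ALLELE_RE = re.compile(r"^\d{2,3}:\d{2,3}$")
HLA_LOCI = ("DRB1", "DQB1", "DPB1")

PHENO_COLUMNS = ("subject_id", "sampleset", "food", "response")
RESPONSES = ("none", "mild", "severe")

SUMMARY_COLUMNS = ("chrom", "pos", "id", "effect_allele", "other_allele",
                   "n_cases", "n_controls", "beta", "se", "p")


class FormatError(ValueError):
    """A file violated its dialect contract."""


@dataclass
class GenotypeMatrix:
    """Subjects x variants alternate-allele dosage matrix.

    ``dosages`` is float with ``nan`` for missing calls; non-missing entries
    of hard-called data are in {0, 1, 2} (imputed fractional dosages in
    [0, 2] are tolerated by the container but not produced by the readers
    here).  ``variants`` carries chrom / 1-based pos / id / ref / alt.
    """

    subjects: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    sampleset: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sampleset is None:
            self.sampleset = np.array([""] * len(self.subjects))
        self.sampleset = np.asarray(self.sampleset, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        ids = list(self.variants["id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        if self.dosages.shape != (len(self.subjects), len(self.variants)):
            raise ValueError("dosage matrix shape does not match subjects x variants")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not present")
        return int(self.variants.index.get_indexer(idx)[0])

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_index(variant_id)]

    def subset_subjects(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.subjects)}
            idx = np.array([pos[s] for s in keep])
        return GenotypeMatrix(
            subjects=[self.subjects[i] for i in idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx],
            sampleset=self.sampleset[idx],
        )

    def subset_variants(self, variant_ids: list[str]) -> "GenotypeMatrix":
        order = [self.variant_index(v) for v in variant_ids]
        return GenotypeMatrix(
            subjects=list(self.subjects),
            variants=self.variants.iloc[order].reset_index(drop=True),
            dosages=self.dosages[:, order],
            sampleset=self.sampleset,
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sampleset: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load a biallelic GT-only VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are rejected with a message listing their ids;
    half-calls (``./1`` etc.) are treated as missing.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error paths
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    subjects = list(vcf.samples)
    rows, meta, multi = [], [], []
    for recno, var in enumerate(vcf, 1):
        if len(var.ALT) != 1:
            multi.append(var.ID or f"{var.CHROM}:{var.POS}")
            continue
        dos = np.full(len(subjects), np.nan)
        for i, g in enumerate(var.genotypes):
            a = g[:-1]  # trailing element is phase flag
            if len(a) != 2 or a[0] < 0 or a[1] < 0:
                continue  # missing or half-call
            dos[i] = a[0] + a[1]
        rows.append(dos)
        meta.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                     var.REF, var.ALT[0]))
    if multi:
        raise FormatError(
            f"multi-allelic records not supported: {', '.join(multi[:20])}"
            + ("..." if len(multi) > 20 else ""))
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = (np.array(rows).T if rows
               else np.empty((len(subjects), 0)))
    ss = None
    if sampleset is not None:
        ss = np.array([sampleset.get(s, "") for s in subjects], dtype=object)
    return GenotypeMatrix(subjects, variants, dosages, ss)


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write hard-called genotypes as a minimal VCF 4.2 (GT only)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(geno.subjects),
    ]
    for j, row in geno.variants.iterrows():
        gts = []
        for d in geno.dosages[:, j]:
            if np.isnan(d):
                gts.append("./.")
            else:
                gts.append(_GT[int(round(d))])
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
            f"{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Dosage TSV (variants x subjects)
# ---------------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    header = ["chrom", "pos", "id", "ref", "alt"] + list(geno.subjects)
    lines = ["\t".join(header),
             "#sampleset\t.\t.\t.\t.\t" + "\t".join(map(str, geno.sampleset))]
    for j, row in geno.variants.iterrows():
        vals = ["." if np.isnan(d) else f"{d:.12g}" for d in geno.dosages[:, j]]
        lines.append(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                     f"{row['ref']}\t{row['alt']}\t" + "\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:5] != ["chrom", "pos", "id", "ref", "alt"]:
        raise FormatError(f"{path}: bad header {header[:5]}")
    subjects = header[5:]
    sampleset = None
    body_start = 1
    if len(lines) > 1 and lines[1].startswith("#sampleset"):
        sampleset = np.array(lines[1].split("\t")[5:], dtype=object)
        body_start = 2
    meta, rows = [], []
    for lineno, line in enumerate(lines[body_start:], body_start + 1):
        parts = line.split("\t")
        if len(parts) != 5 + len(subjects):
            raise FormatError(f"{path}: line {lineno} has {len(parts)} fields")
        meta.append((parts[0], int(parts[1]), parts[2], parts[3], parts[4]))
        vals = np.full(len(subjects), np.nan)
        for i, tok in enumerate(parts[5:]):
            if tok == ".":
                continue
            v = float(tok)
            if not 0.0 <= v <= 2.0:
                raise FormatError(f"{path}: line {lineno}: dosage {tok} outside [0, 2]")
            vals[i] = v
        rows.append(vals)
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = np.array(rows).T if rows else np.empty((len(subjects), 0))
    return GenotypeMatrix(subjects, variants, dosages, sampleset)


# ---------------------------------------------------------------------------
# Phenotype questionnaire TSV (long form)
# ---------------------------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    df = pheno[list(PHENO_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = ~df["response"].isin(RESPONSES)
    if bad.any():
        row = df.index[bad][0] + 2  # 1-based, header line
        raise FormatError(
            f"{path}: row {row}: response {df.loc[bad, 'response'].iloc[0]!r} "
            f"not in {RESPONSES}")
    return df


# ---------------------------------------------------------------------------
# HLA call table
# ---------------------------------------------------------------------------

def write_hla_table(hla: pd.DataFrame, path: str | Path) -> None:
    hla[["subject_id", "locus", "allele1", "allele2", "ct"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_hla_table(path: str | Path,
                   config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Read HLA calls, dropping rows with call-threshold ``ct <= ct_min``.

    The call-threshold filter is strict (``ct > ct_min`` kept), matching the
    post-imputation QC convention.  The number of excluded rows is reported
    in ``df.attrs['n_ct_excluded']``.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path, sep="\t",
                     dtype={"subject_id": str, "locus": str,
                            "allele1": str, "allele2": str, "ct": float})
    required = ["subject_id", "locus", "allele1", "allele2", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("allele1", "allele2"):
        bad = ~df[col].astype(str).str.match(HLA_ALLELE_RE)
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise FormatError(
                f"{path}: row {row}: malformed allele code "
                f"{df.loc[df.index[bad][0], col]!r}")
    if ((df["ct"] < 0) | (df["ct"] > 1)).any():
        raise FormatError(f"{path}: ct outside [0, 1]")
    keep = df["ct"] > config.ct_min
    out = df[keep].reset_index(drop=True)
    out.attrs["n_ct_excluded"] = int((~keep).sum())
    return out


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def write_summary_stats(records: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SUMMARY_COLUMNS if c not in records.columns]
    if missing:
        raise FormatError(f"summary stats missing required column(s) {missing}")
    df = records[list(SUMMARY_COLUMNS)]
    lines = ["\t".join(SUMMARY_COLUMNS)]
    for _, r in df.iterrows():
        lines.append("\t".join(
            "." if (isinstance(v, float) and np.isnan(v))
            else (f"{v:.17g}" if isinstance(v, float) else str(v))
            for v in r))
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."],
                     dtype={"chrom": str, "id": str,
                            "effect_allele": str, "other_allele": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    p = df["p"].dropna()
    if ((p < 0) | (p > 1)).any():
        raise FormatError(f"{path}: p-values outside [0, 1]")
    return df
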