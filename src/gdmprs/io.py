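"""Readers and writers for genotype and phenotype data.

Genotypes are exchanged as PLINK 1 binary triples (``.bed``/``.bim``/``.fam``,
SNP-major, magic bytes ``0x6c 0x1b 0x01``) or as plain-text VCF (only the GT
field is required).  Phenotypes travel as CSV/TSV with a header row.

On read, dosages are re-oriented to count the minor allele, so the in-memory
matrix always satisfies MAF <= 0.5 regardless of how the source file coded its
alleles.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    GenotypeMatrix,
    PhenotypeTable,
    VariantRecord,
    categorize_income,
    derive_t2dm_status,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_plink",
    "write_plink",
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
]

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> dosage of allele A1 (00 hom-A1, 01 missing, 10 het, 11 hom-A2)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


class GenotypeFormatError(ValueError):
    """Malformed genotype file (bad magic bytes, header or record)."""


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from a PLINK triple or a VCF.

    ``path`` is the ``.bed`` file (or bare stem) for PLINK, or the ``.vcf``
    file.  ``format`` may be ``"plink"`` or ``"vcf"``; when omitted it is
    inferred from the extension.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in {".bed", ".bim", ".fam"} or suffix == "":
            format = "plink"
        elif suffix in {".vcf", ".gz", ".bcf"}:
            format = "vcf"
        else:
            raise GenotypeFormatError(f"cannot infer genotype format from {path.name!r}")
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str = "plink") -> None:
    if format == "plink":
        write_plink(gm, path)
    elif format == "vcf":
        write_vcf(gm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def _plink_stem(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in {".bed", ".bim", ".fam"} else path


def read_plink(path: str | Path) -> GenotypeMatrix:
    """Read a SNP-major PLINK ``.bed``/``.bim``/``.fam`` triple."""
    stem = _plink_stem(Path(path))
    bed, bim, fam = (stem.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)

    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    n, m = len(fam_df), len(bim_df)

    raw = bed.read_bytes()
    if raw[:2] != _PLINK_MAGIC[:2]:
        raise GenotypeFormatError(f"{bed}: bad PLINK magic bytes {raw[:2].hex()}")
    if raw[2:3] != _PLINK_MAGIC[2:3]:
        raise GenotypeFormatError(f"{bed}: not in SNP-major mode")
    bytes_per_variant = math.ceil(n / 4)
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_variant * m:
        raise GenotypeFormatError(
            f"{bed}: expected {bytes_per_variant * m} genotype bytes, got {body.size}"
        )
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, least-significant pair first
    codes = np.stack(
        [(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # subjects x variants, counting A1

    variants = []
    for j, row in enumerate(bim_df.itertuples(index=False)):
        d = dosages[:, j]
        variants.append(
            _orient_variant(
                row.id, str(row.chrom), int(row.pos), row.a1, row.a2, d, dosages, j
            )
        )
    return GenotypeMatrix(variants, dosages, list(fam_df["iid"]))


def write_plink(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a SNP-major PLINK triple; A1 is the minor allele."""
    stem = _plink_stem(Path(path))
    stem.parent.mkdir(parents=True, exist_ok=True)
    with open(stem.with_suffix(".fam"), "w") as fh:
        for sid in gm.subject_ids:
            fh.write(f"{sid} {sid} 0 0 2 -9\n")
    with open(stem.with_suffix(".bim"), "w") as fh:
        for v in gm.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.minor_allele}\t{v.major_allele}\n")

    n = gm.n_subjects
    bytes_per_variant = math.ceil(n / 4)
    with open(stem.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        for j in range(gm.n_variants):
            codes = np.empty(bytes_per_variant * 4, dtype=np.uint8)
            codes[:] = 0b01  # missing padding
            col = gm.dosages[:, j]
            for i in range(n):
                codes[i] = 0b01 if np.isnan(col[i]) else _DOSAGE_TO_CODE[col[i]]
            packed = (
                codes.reshape(-1, 4)
                * np.array([1, 4, 16, 64], dtype=np.uint8)
            ).sum(axis=1, dtype=np.uint8)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _orient_variant(vid, chrom, pos, a1, a2, dosage, dosages, j) -> VariantRecord:
    """Flip dosage column in place if a1 is actually the major allele."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage) / 2.0
    if np.isnan(freq):
        freq = 0.0
    if freq > 0.5:
        dosages[:, j] = 2.0 - dosage
        a1, a2 = a2, a1
        freq = 1.0 - freq
    return VariantRecord(
        id=vid, chrom=chrom, pos=pos, minor_allele=a1, major_allele=a2, maf=float(freq)
    )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes (GT field) from a VCF via cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    cols: list[np.ndarray] = []
    meta: list[tuple] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeFormatError(
                f"{rec.ID or rec.POS}: only biallelic sites are supported"
            )
        gts = np.asarray(rec.genotypes, dtype=object)
        alt_dosage = np.empty(len(subject_ids))
        for i, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            alt_dosage[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        cols.append(alt_dosage)
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS,
                     rec.ALT[0], rec.REF))
    if not cols:
        raise GenotypeFormatError(f"{path}: no variant records")
    dosages = np.column_stack(cols)
    variants = [
        _orient_variant(vid, chrom, pos, alt, ref, dosages[:, j], dosages, j)
        for j, (vid, chrom, pos, alt, ref) in enumerate(meta)
    ]
    return GenotypeMatrix(variants, dosages, subject_ids)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF; REF is the major allele, ALT the minor."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {2.0: "1/1", 1.0: "0/1", 0.0: "0/0"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.subject_ids) + "\n"
        )
        for j, v in enumerate(gm.variants):
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.major_allele}\t{v.minor_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _parse_income(value) -> str:
    if isinstance(value, str):
        stripped = value.replace("$", "").replace(",", "").strip()
        try:
            value = float(stripped)
        except ValueError:
            return value  # already a level label; validated downstream
    return categorize_income(float(value))


def read_phenotypes(
    path: str | Path,
    schema: Mapping[str, object] | None = None,
) -> PhenotypeTable:
    """Read a phenotype/covariate/lifestyle table from CSV or TSV.

    ``schema`` keys (all optional):

    - ``columns``: mapping of canonical name -> source column name
    - ``subject_id``: source column holding subject ids (default first column)
    - ``derive_t2dm``: derive ``t2dm_status`` from fasting glucose
      (> 126 mg/dL), HbA1c (>= 6.5 %) and a ``hypoglycemic_agent`` flag
    - ``income_numeric``: parse income from dollar amounts into the three
      survey levels
    """
    schema = dict(schema or {})
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)

    renames = {src: dst for dst, src in dict(schema.get("columns", {})).items()}
    df = df.rename(columns=renames)

    id_col = schema.get("subject_id", df.columns[0])
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    df.index.name = "subject_id"

    if schema.get("income_numeric") and "income" in df.columns:
        df["income"] = df["income"].map(_parse_income)

    if schema.get("derive_t2dm"):
        missing = {"fasting_glucose", "hba1c"} - set(df.columns)
        if missing:
            raise ValueError(f"cannot derive t2dm_status without columns {missing}")
        agent = df["hypoglycemic_agent"] if "hypoglycemic_agent" in df.columns else None
        df["t2dm_status"] = derive_t2dm_status(df["fasting_glucose"], df["hba1c"], agent)

    return PhenotypeTable(df)
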