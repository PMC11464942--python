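"""Readers/writers for PLINK binary triplets, VCF and phenotype TSVs.

The PLINK 1 ``.bed`` codec is implemented here (SNP-major, mode byte
0x01, two bits per call with the first sample in the lowest-order
bits): numeric two-bit values 0 -> homozygous A1 (dosage 2),
1 -> missing, 2 -> heterozygous, 3 -> homozygous A2 (dosage 0). A1 in
the ``.bim`` is the counted (dosage) allele. VCF reading goes through
cyvcf2; dosages count the ALT allele, so on write REF = A2 and
ALT = A1. Coordinates are 1-based throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .core import (
    COHORT_COLUMNS,
    MISSING,
    GenotypeMatrix,
    SNP_META_COLUMNS,
    standardize,
    validate_cohort,
)
from .exceptions import FormatError, SchemaError

log = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = bytes([0x01])

# numeric 2-bit code -> A1 dosage (-1 missing)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# A1 dosage (index 0,1,2; 3 used for missing) -> 2-bit code
_DOSAGE_TO_CODE = np.array([3, 2, 0, 1], dtype=np.uint8)

_SEX_TO_FAM = {"male": 1, "female": 2}


def _p(prefix, ext):
    """prefix + ext (PLINK prefixes may contain dots)."""
    return Path(str(prefix) + ext)
_FAM_TO_SEX = {1: "male", 2: "female"}


# ----------------------------------------------------------------------
# PLINK bed/bim/fam
# ----------------------------------------------------------------------
def write_bed(
    genotypes: GenotypeMatrix,
    prefix: Union[str, Path],
    sex: Optional[pd.Series] = None,
) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major mode).

    ``sex`` (optional) maps sample_id -> 'male'/'female' for the .fam
    sex column; unknown samples get code 0. Output bytes are a pure
    function of the inputs.
    """
    prefix = Path(prefix)
    n, m = genotypes.n_samples, genotypes.n_snps
    n_pad = (4 - n % 4) % 4

    codes = np.empty((m, n + n_pad), dtype=np.uint8)
    dosage_idx = genotypes.calls.T.astype(np.int64)
    dosage_idx[dosage_idx == MISSING] = 3
    codes[:, :n] = _DOSAGE_TO_CODE[dosage_idx]
    codes[:, n:] = 0  # padding bits are zero by convention
    if m == 0 or n == 0:
        packed = np.zeros((m, (n + 3) // 4), dtype=np.uint8)
    else:
        packed = (
            codes.reshape(m, -1, 4)
            @ np.array([1, 4, 16, 64], dtype=np.uint8)
        ).astype(np.uint8)

    with open(_p(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())

    bim = genotypes.snp_meta
    with open(_p(prefix, ".bim"), "w") as fh:
        for row in bim.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n"
            )

    sex_map = {} if sex is None else dict(sex)
    with open(_p(prefix, ".fam"), "w") as fh:
        for sid in genotypes.sample_ids:
            code = _SEX_TO_FAM.get(sex_map.get(sid), 0)
            fh.write(f"{sid}\t{sid}\t0\t0\t{code}\t-9\n")
    log.info("wrote %d samples x %d SNPs to %s.{bed,bim,fam}", n, m, prefix)


def read_bed(prefix: Union[str, Path]) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK triplet; returns ``(matrix, fam_table)``.

    The fam table is a cohort-table skeleton: ``sample_id`` and ``sex``
    (None where unknown). Raises :class:`FormatError` on bad magic/mode
    bytes or on a payload whose size disagrees with .fam x .bim.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not _p(prefix, ext).exists():
            raise FileNotFoundError(_p(prefix, ext))

    fam = pd.read_csv(
        _p(prefix, ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex_code", "pheno"],
        dtype={"iid": str, "fid": str},
    )
    bim = pd.read_csv(
        _p(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = _p(prefix, ".bed").read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(
            f"{_p(prefix, '.bed')}: bad magic bytes {raw[:2]!r}"
        )
    if raw[2:3] != _BED_SNP_MAJOR:
        raise FormatError(f"unsupported .bed mode byte {raw[2:3]!r}")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"{_p(prefix, '.bed')}: expected {expected} bytes "
            f"({n} samples x {m} SNPs), found {len(raw)}"
        )

    if m == 0 or n == 0:
        calls = np.zeros((n, m), dtype=np.int8)
    else:
        packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(
            m, bytes_per_snp
        )
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        codes = (packed[:, :, None] >> shifts[None, None, :]) & 3
        codes = codes.reshape(m, -1)[:, :n]
        calls = _CODE_TO_DOSAGE[codes].T

    meta = pd.DataFrame(
        {
            "chrom": bim["chrom"].to_numpy(),
            "pos": bim["pos"].to_numpy(),
            "snp_id": bim["snp_id"].to_numpy(),
            "a1": bim["a1"].to_numpy(),
            "a2": bim["a2"].to_numpy(),
        },
        columns=SNP_META_COLUMNS,
    )
    gm = GenotypeMatrix(calls, meta, fam["iid"].tolist())
    skeleton = pd.DataFrame(
        {
            "sample_id": fam["iid"],
            "sex": fam["sex_code"].map(_FAM_TO_SEX),
        }
    )
    return gm, skeleton


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------
def write_vcf(genotypes: GenotypeMatrix, path: Union[str, Path]) -> None:
    """Write a minimal GT-only VCF 4.2 (REF = A2, ALT = A1)."""
    path = Path(path)
    gt_strings = np.array(["1/1", "./.", "0/1", "0/0"], dtype=object)
    # index by 2-bit code so dosage 2 -> "1/1", missing -> "./."
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(genotypes.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        dosage_idx = genotypes.calls.astype(np.int64)
        dosage_idx[dosage_idx == MISSING] = 3
        codes = _DOSAGE_TO_CODE[dosage_idx]  # samples x snps
        for j, row in enumerate(genotypes.snp_meta.itertuples(index=False)):
            gts = "\t".join(gt_strings[codes[:, j]])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.a2}\t{row.a1}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    log.info("wrote %d variants to %s", genotypes.n_snps, path)


def read_vcf(path: Union[str, Path], with_stats: bool = False):
    """Read bi-allelic sites from a (plain or bgzipped) VCF.

    GT fields map to ALT dosage ('./.' -> missing, phase irrelevant);
    multi-allelic rows are skipped with a logged count. Returns the
    matrix, or ``(matrix, stats)`` when ``with_stats`` is true.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, meta_rows = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(variant.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # gts012: 3 = unknown
        rows.append(gt)
        meta_rows.append(
            (variant.CHROM, variant.POS, variant.ID or f"{variant.CHROM}:{variant.POS}",
             variant.ALT[0], variant.REF)
        )
    vcf.close()
    if n_multi:
        log.warning("skipped %d multi-allelic rows in %s", n_multi, path)
    calls = (
        np.vstack(rows).T if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    meta = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    gm = GenotypeMatrix(calls, meta, samples)
    if with_stats:
        return gm, {"skipped_multiallelic": n_multi}
    return gm


# ----------------------------------------------------------------------
# phenotype TSV
# ----------------------------------------------------------------------
def write_pheno(cohort: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the cohort table as a headered TSV."""
    cols = [c for c in COHORT_COLUMNS + ["true_group"] if c in cohort.columns]
    cohort[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pheno(path: Union[str, Path], zscore_outcome: bool = False) -> pd.DataFrame:
    """Read a phenotype TSV into a typed cohort table.

    Requires columns ``sample_id``, ``ctq_total`` and an outcome column
    (``outcome_z`` or ``outcome``). ``zscore_outcome=True`` replaces the
    outcome with its z-score (the analysis convention for raw scores).
    Raises :class:`SchemaError` naming any missing column, duplicated
    ids, or the 1-based data line of a non-numeric trauma score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "ctq_total"]
    missing = [c for c in required if c not in df.columns]
    outcome_col = next((c for c in ("outcome_z", "outcome") if c in df.columns), None)
    if outcome_col is None:
        missing.append("outcome")
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise SchemaError(f"{path}: duplicated sample ids {dups[:5]}")

    ctq = pd.to_numeric(df["ctq_total"], errors="coerce")
    bad = ctq.isna() & df["ctq_total"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 1  # 1-based data line (after header)
        raise SchemaError(f"{path}: non-numeric ctq_total at data line {line}")
    df["ctq_total"] = ctq

    out = pd.to_numeric(df[outcome_col], errors="coerce")
    df["outcome_z"] = standardize(out.to_numpy()) if zscore_outcome else out
    if outcome_col != "outcome_z":
        df = df.drop(columns=[outcome_col])

    for col, default in (
        ("sex", None),
        ("age", np.nan),
        ("education", np.nan),
        ("env_stratum", "unassigned"),
    ):
        if col not in df.columns:
            df[col] = default
    complete = df["ctq_total"].notna()
    df["ctq_z"] = np.nan
    if complete.sum() >= 2:
        df.loc[complete, "ctq_z"] = standardize(df.loc[complete, "ctq_total"].to_numpy())
    validate_cohort(df)
    return df
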