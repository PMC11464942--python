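"""Core in-memory containers.

Genotypes live in a :class:`GenotypeMatrix`: a samples x SNPs array of
hard-call allele dosages (count of the A1 allele) with ``-1`` marking a
missing call, plus per-SNP metadata. Phenotypes and covariates live in a
plain :class:`pandas.DataFrame` ("cohort table") with a fixed column
schema; :func:`validate_cohort` checks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError

#: sentinel for a missing genotype call
MISSING: int = -1

SNP_META_COLUMNS = ["chrom", "pos", "snp_id", "a1", "a2"]

#: required columns of a cohort table
COHORT_COLUMNS = [
    "sample_id",
    "sex",
    "age",
    "education",
    "ctq_total",
    "ctq_z",
    "outcome_z",
    "env_stratum",
]

SEX_LEVELS = ("male", "female")
ENV_STRATA = ("control", "case", "excluded", "unassigned")


def standardize(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score ``x`` (sample SD, ddof=1 by convention throughout)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-dosage calls with per-SNP metadata.

    Parameters
    ----------
    calls:
        ``(n_samples, n_snps)`` int8 array with values in ``{0, 1, 2, -1}``
        counting copies of the A1 allele (-1 = missing).
    snp_meta:
        DataFrame with columns ``chrom, pos, snp_id, a1, a2`` (1-based bp
        positions, PLINK convention: A1 is the counted allele).
    sample_ids:
        list of unique sample identifiers, row order of ``calls``.
    related_pairs:
        optional bookkeeping table of simulated relative pairs
        (``sample_i, sample_j, relationship, expected_phi``).
    """

    calls: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list
    related_pairs: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.ascontiguousarray(np.asarray(self.calls, dtype=np.int8))
        if self.calls.ndim != 2:
            raise SchemaError("calls must be a 2-D samples x SNPs array")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> list:
        return list(self.snp_meta["snp_id"])

    def validate(self) -> None:
        n, m = self.calls.shape
        if len(self.sample_ids) != n:
            raise SchemaError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise SchemaError("sample ids are not unique")
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise SchemaError(f"snp_meta lacks columns: {missing_cols}")
        if len(self.snp_meta) != m:
            raise SchemaError(f"{len(self.snp_meta)} meta rows for {m} SNPs")
        if m and self.snp_meta["snp_id"].duplicated().any():
            dups = self.snp_meta.loc[self.snp_meta["snp_id"].duplicated(), "snp_id"]
            raise SchemaError(f"duplicate snp ids: {sorted(set(dups))[:5]}")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise SchemaError("calls contain values outside {0, 1, 2, missing}")
        # positions non-decreasing within each chromosome (order of appearance)
        if m:
            pos = self.snp_meta["pos"].to_numpy()
            chrom = self.snp_meta["chrom"].to_numpy()
            same = chrom[1:] == chrom[:-1]
            if np.any(same & (np.diff(pos) < 0)):
                raise SchemaError("positions decrease within a chromosome")

    # ------------------------------------------------------------------
    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_meta["snp_id"].to_numpy() == snp_id)
        if idx.size == 0:
            raise KeyError(snp_id)
        return int(idx[0])

    def dosage(self, snp_id: str) -> np.ndarray:
        """Per-sample dosage of one SNP (int8, -1 missing)."""
        return self.calls[:, self.snp_index(snp_id)].copy()

    def take_samples(self, keep) -> "GenotypeMatrix":
        """Subset samples by boolean mask, integer index, or id list."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([lookup[str(s)] for s in keep], dtype=int)
        return GenotypeMatrix(
            self.calls[idx], self.snp_meta.copy(), [self.sample_ids[i] for i in idx]
        )

    def take_snps(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep.astype(int)
        return GenotypeMatrix(
            self.calls[:, idx],
            self.snp_meta.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
        )

    # ------------------------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def a1_freq(self) -> np.ndarray:
        """Per-SNP sample frequency of the counted (A1) allele, NaN if no calls."""
        valid = self.valid_mask()
        n_called = valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(valid, self.calls, 0).sum(axis=0)
            return np.where(n_called > 0, s / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.a1_freq()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.full(self.n_snps, np.nan)
        return self.valid_mask().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros(self.n_samples)
        return (~self.valid_mask()).mean(axis=1)


# ----------------------------------------------------------------------
def validate_cohort(cohort: pd.DataFrame, require_z: bool = True) -> None:
    """Check the cohort-table schema and value ranges.

    Raises :class:`SchemaError` on a missing column, duplicated sample id,
    out-of-range CTQ total or unknown sex / stratum label.
    """
    cols = list(COHORT_COLUMNS)
    if not require_z:
        cols = [c for c in cols if c not in ("ctq_z", "outcome_z")]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table lacks columns: {missing}")
    if cohort["sample_id"].duplicated().any():
        dups = cohort.loc[cohort["sample_id"].duplicated(), "sample_id"]
        raise SchemaError(f"duplicated sample ids: {sorted(set(dups))[:5]}")
    sex_ok = cohort["sex"].isin(SEX_LEVELS) | cohort["sex"].isna()
    if not sex_ok.all():
        raise SchemaError("sex must be 'male' or 'female'")
    if "env_stratum" in cohort.columns:
        if not cohort["env_stratum"].isin(ENV_STRATA).all():
            raise SchemaError(f"env_stratum outside {ENV_STRATA}")


def ctq_bounds(item_count: int = 14, item_levels: int = 5) -> tuple:
    """Valid range of a summed trauma score (items scored 1..levels)."""
    return item_count, item_count * item_levels
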