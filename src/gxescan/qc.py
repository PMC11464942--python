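"""Genotype and sample quality control.

Implements the QC cascade the scan assumes: per-sample missingness and
heterozygosity-based inbreeding (|F| > 0.2), relatedness pruning from
pairwise robust kinship (second-degree cut), then per-SNP missingness,
minor-allele frequency and an exact Hardy-Weinberg test. Default
thresholds: sample missingness > 0.05, |F| > 0.2, kinship through 2nd
degree, SNP missingness > 0.02, MAF < 0.01, HWE p < 1e-5.

The HWE test is the exact conditional test on heterozygote counts given
allele counts (two-sided by probability-mass ordering, no mid-p),
computed with a numerically stable log-space recurrence. Kinship uses
the robust within-pair estimator
``phi = (N_het,het - 2*N_opposite_hom) / (N_het(i) + N_het(j))`` over
pairwise-complete SNPs, with the standard powers-of-two degree cuts
(duplicate > 0.354, 1st degree (0.177, 0.354], 2nd (0.0884, 0.177]).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import MISSING, GenotypeMatrix
from .exceptions import QCError

log = logging.getLogger(__name__)

#: kinship cut points at powers of two: > 2^-1.5 duplicate/MZ,
#: (2^-2.5, 2^-1.5] first degree, (2^-3.5, 2^-2.5] second degree
KINSHIP_CUTS = {"duplicate": 0.5 ** 1.5, "1st": 0.5 ** 2.5, "2nd": 0.5 ** 3.5}


@dataclass
class QCThresholds:
    sample_missing: float = 0.05
    het_f_abs: float = 0.2
    relatedness_degree: str = "2nd"  # prune through this degree
    snp_missing: float = 0.02
    maf_min: float = 0.01
    hwe_p: float = 1e-5
    kinship_min_snps: int = 100

    def validate(self) -> None:
        for name in ("sample_missing", "snp_missing", "maf_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise QCError(f"{name} must be a proportion, got {v}")
        if not (0 < self.hwe_p <= 1):
            raise QCError("hwe_p must lie in (0, 1]")
        if self.relatedness_degree not in ("1st", "2nd"):
            raise QCError("relatedness_degree must be '1st' or '2nd'")


@dataclass
class QCReport:
    """Removal audit: one row per removed entity plus step counts."""

    removed: pd.DataFrame  # id, kind, step, statistic, threshold
    summary: dict

    def to_tsv(self, path) -> None:
        self.removed.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------
def hwe_het_distribution(n: int, n_rare: int) -> Tuple[np.ndarray, np.ndarray]:
    """Exact conditional distribution of the heterozygote count.

    Given ``n`` diploid genotypes and ``n_rare`` copies of the rarer
    allele (``n_rare <= n``), returns the possible heterozygote counts
    (sharing the parity of ``n_rare``) and their probabilities, from a
    log-space ratio recurrence normalised at the end.
    """
    if not (0 <= n_rare <= n):
        raise ValueError("need 0 <= n_rare <= n")
    if n_rare == 0:
        return np.array([0]), np.array([1.0])
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # successive ratio P(h+2)/P(h) = 4*hom_rare(h)*hom_common(h) / ((h+1)(h+2))
    h = hets[:-1].astype(float)
    hom_rare = (n_rare - h) / 2.0
    hom_common = n - h - hom_rare
    log_ratio = (
        np.log(4.0) + np.log(hom_rare) + np.log(hom_common)
        - np.log(h + 1.0) - np.log(h + 2.0)
    )
    log_p = np.concatenate([[0.0], np.cumsum(log_ratio)])
    log_p -= logsumexp(log_p)
    return hets, np.exp(log_p)


def hwe_exact_pvalues(n: int, n_rare: int) -> Tuple[np.ndarray, np.ndarray]:
    """P-values for every possible heterozygote count at (n, n_rare).

    p(h) = sum of probabilities of all heterozygote counts whose
    conditional probability is <= that of ``h`` (two-sided mass
    ordering; a tiny relative tolerance guards float ties).
    """
    hets, probs = hwe_het_distribution(n, n_rare)
    order = np.argsort(probs, kind="stable")
    sorted_probs = probs[order]
    cum = np.cumsum(sorted_probs)
    # for each h: total mass of outcomes with prob <= prob(h)*(1+eps)
    idx = np.searchsorted(sorted_probs, probs * (1 + 1e-10), side="right")
    pvals = np.minimum(cum[idx - 1], 1.0)
    return hets, pvals


def hwe_exact_test(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Exact HWE p-value from the three genotype counts.

    Monomorphic sites return 1.0 by convention.
    """
    counts = (int(n_hom_a1), int(n_het), int(n_hom_a2))
    if min(counts) < 0:
        raise ValueError(f"negative genotype count {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes")
    n_a1 = 2 * counts[0] + counts[1]
    n_rare = min(n_a1, 2 * n - n_a1)
    if n_rare == 0:
        log.debug("monomorphic site, HWE p = 1 by convention")
        return 1.0
    hets, pvals = hwe_exact_pvalues(n, n_rare)
    return float(pvals[np.searchsorted(hets, counts[1])])


# ----------------------------------------------------------------------
# per-SNP and per-sample statistics
# ----------------------------------------------------------------------
def snp_qc_table(genotypes: GenotypeMatrix, thresholds: QCThresholds = None) -> pd.DataFrame:
    """Call rate, MAF and exact-HWE p per SNP with a pass flag.

    ``pass_rule`` names the first failing rule (missingness, then MAF,
    then HWE) or is empty for passing SNPs.
    """
    thresholds = thresholds or QCThresholds()
    valid = genotypes.valid_mask()
    calls = genotypes.calls
    call_rate = genotypes.snp_call_rate()
    maf = genotypes.maf()
    n_hom2 = ((calls == 2) & valid).sum(axis=0)
    n_het = ((calls == 1) & valid).sum(axis=0)
    n_hom0 = ((calls == 0) & valid).sum(axis=0)
    hwe_p = np.ones(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        n = n_hom0[j] + n_het[j] + n_hom2[j]
        if n == 0:
            hwe_p[j] = np.nan
            continue
        hwe_p[j] = hwe_exact_test(n_hom2[j], n_het[j], n_hom0[j])
    rules = np.full(genotypes.n_snps, "", dtype=object)
    miss_fail = (1 - call_rate) > thresholds.snp_missing
    maf_fail = ~miss_fail & (np.nan_to_num(maf, nan=0.0) < thresholds.maf_min)
    hwe_fail = ~miss_fail & ~maf_fail & (np.nan_to_num(hwe_p, nan=1.0) < thresholds.hwe_p)
    rules[miss_fail] = "missingness"
    rules[maf_fail] = "maf"
    rules[hwe_fail] = "hwe"
    return pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass": rules == "",
            "fail_rule": rules,
        }
    )


def sample_heterozygosity_f(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample inbreeding coefficient F = 1 - observed/expected het.

    Expected heterozygosity sums ``2 p_j (1 - p_j)`` (sample allele
    frequencies) over each sample's non-missing SNPs. Samples with no
    usable SNP (all missing, or only monomorphic sites) get F = NaN and
    a flag.
    """
    if genotypes.n_snps < 2:
        raise QCError("need >= 2 SNPs for heterozygosity F")
    valid = genotypes.valid_mask()
    p = genotypes.a1_freq()
    exp_site = np.where(np.isnan(p), 0.0, 2.0 * p * (1.0 - p))
    o_het = ((genotypes.calls == 1) & valid).sum(axis=1).astype(float)
    e_het = valid.astype(float) @ exp_site
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(e_het > 0, 1.0 - o_het / e_het, np.nan)
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "missing_rate": genotypes.sample_missing_rate(),
            "het_f": f,
            "defined": e_het > 0,
        }
    )


# ----------------------------------------------------------------------
# kinship
# ----------------------------------------------------------------------
def _degree_call(phi: np.ndarray) -> np.ndarray:
    out = np.full(phi.shape, "unrelated", dtype=object)
    out[phi > KINSHIP_CUTS["2nd"]] = "2nd"
    out[phi > KINSHIP_CUTS["1st"]] = "1st"
    out[phi > KINSHIP_CUTS["duplicate"]] = "mz/dup"
    return out


def king_kinship(
    genotypes: GenotypeMatrix, min_snps: int = 100
) -> pd.DataFrame:
    """All pairwise robust kinship coefficients.

    Pairs with fewer than ``min_snps`` pairwise-complete SNPs (or no
    heterozygous calls in either member) are skipped with a log entry.
    Identical genotype vectors with at least one het give phi = 0.5
    exactly.
    """
    n = genotypes.n_samples
    if n < 2:
        raise QCError("need >= 2 samples for kinship")
    valid = genotypes.valid_mask().astype(np.float64)
    het = ((genotypes.calls == 1) & (valid > 0)).astype(np.float64)
    hom0 = ((genotypes.calls == 0) & (valid > 0)).astype(np.float64)
    hom2 = ((genotypes.calls == 2) & (valid > 0)).astype(np.float64)

    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_in_pair = het @ valid.T  # het calls of i at SNPs called in j
    denom = het_in_pair + het_in_pair.T
    n_complete = valid @ valid.T

    iu, ju = np.triu_indices(n, k=1)
    usable = (n_complete[iu, ju] >= min_snps) & (denom[iu, ju] > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.warning(
            "skipped %d sample pairs with < %d complete SNPs or no hets",
            n_skipped,
            min_snps,
        )
    iu, ju = iu[usable], ju[usable]
    phi = (n_hethet[iu, ju] - 2.0 * n_opp[iu, ju]) / denom[iu, ju]
    ids = np.asarray(genotypes.sample_ids, dtype=object)
    return pd.DataFrame(
        {
            "sample_i": ids[iu],
            "sample_j": ids[ju],
            "phi": phi,
            "n_snps_used": n_complete[iu, ju].astype(int),
            "degree_call": _degree_call(phi),
        }
    )


def prune_related(pairs: pd.DataFrame, threshold_degree: str = "2nd") -> List[str]:
    """Greedy removal set breaking every pair at/closer than the cut.

    Iteratively drops the sample in the most flagged pairs (ties:
    lexicographically smaller id) until no flagged pair remains.
    """
    if threshold_degree not in ("1st", "2nd"):
        raise QCError("threshold_degree must be '1st' or '2nd'")
    flagged_calls = {"mz/dup", "1st"} | ({"2nd"} if threshold_degree == "2nd" else set())
    live = [
        (str(r.sample_i), str(r.sample_j))
        for r in pairs.itertuples(index=False)
        if r.degree_call in flagged_calls
    ]
    removed: List[str] = []
    while live:
        counts: dict = {}
        for a, b in live:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        # most pairs first; ties -> lexicographically smaller id
        victim = min(counts, key=lambda s: (-counts[s], s))
        removed.append(victim)
        live = [p for p in live if victim not in p]
    return removed


# ----------------------------------------------------------------------
# full cascade
# ----------------------------------------------------------------------
def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: Optional[QCThresholds] = None,
) -> Tuple[GenotypeMatrix, QCReport]:
    """Run the declared QC order and return the filtered matrix + report.

    Order: sample missingness -> heterozygosity |F| -> relatedness
    pruning -> SNP missingness -> MAF -> HWE. Raises :class:`QCError`
    if any step empties the matrix.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    gm = genotypes
    removed_rows = []
    summary = {"n_samples_in": gm.n_samples, "n_snps_in": gm.n_snps}

    def note(ids: Iterable, kind: str, step: str, stats: dict, thr: float):
        for sid in ids:
            removed_rows.append(
                {
                    "id": sid,
                    "kind": kind,
                    "step": step,
                    "statistic": stats.get(sid, np.nan),
                    "threshold": thr,
                }
            )

    def check_nonempty(step: str):
        if gm.n_samples == 0 or gm.n_snps == 0:
            raise QCError(f"all samples or SNPs filtered at step {step!r}")

    # 1. sample missingness
    miss = gm.sample_missing_rate()
    drop = miss > thresholds.sample_missing
    note(
        np.asarray(gm.sample_ids, dtype=object)[drop],
        "sample",
        "sample_missingness",
        dict(zip(gm.sample_ids, miss)),
        thresholds.sample_missing,
    )
    summary["removed_sample_missingness"] = int(drop.sum())
    gm = gm.take_samples(~drop)
    check_nonempty("sample_missingness")

    # 2. heterozygosity F
    ftab = sample_heterozygosity_f(gm)
    fvals = ftab["het_f"].to_numpy()
    drop = (~ftab["defined"].to_numpy()) | (np.abs(np.nan_to_num(fvals)) > thresholds.het_f_abs)
    note(
        ftab.loc[drop, "sample_id"],
        "sample",
        "heterozygosity_f",
        dict(zip(ftab["sample_id"], fvals)),
        thresholds.het_f_abs,
    )
    summary["removed_heterozygosity"] = int(drop.sum())
    gm = gm.take_samples(~drop)
    check_nonempty("heterozygosity_f")

    # 3. relatedness
    pairs = king_kinship(gm, min_snps=thresholds.kinship_min_snps)
    to_remove = prune_related(pairs, thresholds.relatedness_degree)
    phi_by_id = {}
    for r in pairs.itertuples(index=False):
        for sid in (r.sample_i, r.sample_j):
            phi_by_id[sid] = max(phi_by_id.get(sid, -np.inf), r.phi)
    note(to_remove, "sample", "relatedness", phi_by_id, KINSHIP_CUTS[
        "2nd" if thresholds.relatedness_degree == "2nd" else "1st"
    ])
    summary["removed_relatedness"] = len(to_remove)
    keep = ~np.isin(np.asarray(gm.sample_ids, dtype=object), to_remove)
    gm = gm.take_samples(keep)
    check_nonempty("relatedness")

    # 4-6. SNP filters (missingness, MAF, HWE — attribution order)
    snp_tab = snp_qc_table(gm, thresholds)
    for step, col in (
        ("snp_missingness", "missingness"),
        ("snp_maf", "maf"),
        ("snp_hwe", "hwe"),
    ):
        fail = snp_tab["fail_rule"] == col
        stat_col = {"missingness": "call_rate", "maf": "maf", "hwe": "hwe_p"}[col]
        thr = {
            "missingness": thresholds.snp_missing,
            "maf": thresholds.maf_min,
            "hwe": thresholds.hwe_p,
        }[col]
        note(
            snp_tab.loc[fail, "snp_id"],
            "snp",
            step,
            dict(zip(snp_tab["snp_id"], snp_tab[stat_col])),
            thr,
        )
        summary[f"removed_{step}"] = int(fail.sum())
    gm = gm.take_snps(snp_tab["pass"].to_numpy())
    check_nonempty("snp_filters")

    summary["n_samples_out"] = gm.n_samples
    summary["n_snps_out"] = gm.n_snps
    report = QCReport(
        removed=pd.DataFrame(
            removed_rows, columns=["id", "kind", "step", "statistic", "threshold"]
        ),
        summary=summary,
    )
    log.info(
        "QC: %d/%d samples, %d/%d SNPs survive",
        gm.n_samples,
        summary["n_samples_in"],
        gm.n_snps,
        summary["n_snps_in"],
    )
    return gm, report
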