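"""Genome-wide gene x environment interaction scan.

The environment (trauma total) is dichotomized into lower/upper tail
strata; within each stratum the outcome is regressed on allele dosage
per SNP (ordinary least squares, complete cases per SNP); the
interaction statistic compares the two slopes,

    Z = (beta_case - beta_control) / sqrt(SE1^2 + SE2^2),

with a two-sided standard-normal p-value. The default scan is
unadjusted (covariate adjustment is available behind a flag as a
declared extension). Inflation is summarised by the genomic control
factor ``lambda = median(Z^2) / median(chi^2_1)``.

Output schema (one row per SNP): SNP, CHR, BP, BETA1, SE1, NMISS1
(controls), BETA2, SE2, NMISS2 (cases), Z, P. Not-testable SNPs (a
stratum with < 3 calls or zero dosage variance) keep their row with
NaN statistics rather than being dropped silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix
from .exceptions import ModelError

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.454936...

SCAN_COLUMNS = [
    "SNP", "CHR", "BP",
    "BETA1", "SE1", "NMISS1",
    "BETA2", "SE2", "NMISS2",
    "Z", "P",
]


@dataclass
class StratumAssignment:
    """Per-sample environment stratum with the realized cut scores."""

    strata: pd.Series  # index sample_id -> {control, case, excluded}
    lower_cut: float
    upper_cut: float
    q: float

    def ids(self, stratum: str) -> np.ndarray:
        return self.strata.index[self.strata == stratum].to_numpy()

    def counts(self) -> dict:
        return self.strata.value_counts().to_dict()


def dichotomize_env(cohort: pd.DataFrame, q: float = 0.27) -> StratumAssignment:
    """Lower-q tail -> controls, upper-q tail -> cases, middle excluded.

    Cuts are inclusive at tied scores: the lower cut is the smallest
    score whose cumulative proportion reaches ``q`` and every sample at
    or below it is a control (so realized tail fractions can exceed
    ``q``); symmetric at the top. Raises :class:`ModelError` when the
    score distribution cannot form disjoint strata.
    """
    if not (0 < q < 0.5):
        raise ModelError(f"tail proportion q must lie in (0, 0.5), got {q}")
    scores = cohort["ctq_total"].to_numpy(dtype=float)
    if scores.size < 10:
        raise ModelError("need >= 10 samples to form strata")
    uniq, counts = np.unique(scores, return_counts=True)
    if uniq.size < 2:
        raise ModelError("cannot form strata: all trauma scores identical")
    cdf = np.cumsum(counts) / scores.size
    surv = np.cumsum(counts[::-1])[::-1] / scores.size  # P(score >= v)
    lower_cut = float(uniq[np.argmax(cdf >= q)])
    upper_candidates = np.flatnonzero(surv >= q)
    upper_cut = float(uniq[upper_candidates[-1]])
    if lower_cut >= upper_cut:
        raise ModelError(
            f"cannot form strata: tails overlap (cuts {lower_cut} >= {upper_cut})"
        )
    strata = np.where(
        scores <= lower_cut, "control", np.where(scores >= upper_cut, "case", "excluded")
    )
    out = StratumAssignment(
        strata=pd.Series(strata, index=cohort["sample_id"].to_numpy(), name="env_stratum"),
        lower_cut=lower_cut,
        upper_cut=upper_cut,
        q=q,
    )
    log.info(
        "dichotomized at [%g, %g]: %s", lower_cut, upper_cut, out.counts()
    )
    return out


# ----------------------------------------------------------------------
# per-stratum allelic regression
# ----------------------------------------------------------------------
def _stratum_slopes(
    dosages: np.ndarray, y: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-SNP OLS slope of y on dosage (complete cases).

    ``dosages``: (n_samples, n_snps) with -1 missing; returns
    ``(beta, se, n_used)`` with NaN where not testable (< 3 calls or
    zero dosage variance).
    """
    valid = dosages != MISSING
    x = np.where(valid, dosages, 0).astype(np.float64)
    w = valid.astype(np.float64)
    n = w.sum(axis=0)
    sx = x.sum(axis=0)
    sy = w.T @ y
    sxx = (x * x).sum(axis=0)
    sxy = x.T @ y
    syy = w.T @ (y * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_adj_xx = sxx - sx * sx / n
        mean_adj_xy = sxy - sx * sy / n
        mean_adj_yy = syy - sy * sy / n
        beta = mean_adj_xy / mean_adj_xx
        rss = mean_adj_yy - beta * mean_adj_xy
        sigma2 = rss / (n - 2)
        se = np.sqrt(np.maximum(sigma2, 0.0) / mean_adj_xx)
    testable = (n >= 3) & (mean_adj_xx > 1e-12)
    beta = np.where(testable, beta, np.nan)
    se = np.where(testable, se, np.nan)
    return beta, se, n.astype(int)


def _stratum_slopes_adjusted(
    dosages: np.ndarray, y: np.ndarray, covs: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP dosage slope adjusted for covariate columns (loop path)."""
    n_samp, m = dosages.shape
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    nmiss = np.zeros(m, dtype=int)
    for j in range(m):
        valid = dosages[:, j] != MISSING
        nj = int(valid.sum())
        nmiss[j] = nj
        xj = dosages[valid, j].astype(float)
        if nj < covs.shape[1] + 3 or xj.var() <= 1e-12:
            continue
        design = np.column_stack([np.ones(nj), xj, covs[valid]])
        coef, _, rank, _ = np.linalg.lstsq(design, y[valid], rcond=None)
        if rank < design.shape[1]:
            continue
        resid = y[valid] - design @ coef
        dof = nj - design.shape[1]
        if dof <= 0:
            continue
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(design.T @ design)
        beta[j] = coef[1]
        se[j] = np.sqrt(sigma2 * xtx_inv[1, 1])
    return beta, se, nmiss


def stratified_allelic_fit(
    dosage: np.ndarray,
    outcome_z: np.ndarray,
    stratum_labels: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> dict:
    """Slope, SE and n for one SNP in each stratum.

    Returns ``{"control": (beta, se, n), "case": (beta, se, n)}`` with
    NaN statistics where a stratum is not testable.
    """
    dosage = np.asarray(dosage).reshape(-1, 1)
    out = {}
    for name in ("control", "case"):
        sel = stratum_labels == name
        if covariates is None:
            b, s, n = _stratum_slopes(dosage[sel], outcome_z[sel])
        else:
            b, s, n = _stratum_slopes_adjusted(
                dosage[sel], outcome_z[sel], covariates[sel]
            )
        out[name] = (float(b[0]), float(s[0]), int(n[0]))
    return out


def gxe_z_test(beta1: float, se1: float, beta2: float, se2: float) -> Tuple[float, float]:
    """Slope-difference Z (cases minus controls) and two-sided normal p."""
    if not (se1 > 0 and se2 > 0) or not np.all(np.isfinite([beta1, se1, beta2, se2])):
        return np.nan, np.nan
    z = (beta2 - beta1) / np.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def genome_scan(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    assignment: StratumAssignment,
    covariates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One interaction test per SNP; returns the scan table.

    ``covariates`` (e.g. ``["sex", "age"]``) switches on the adjusted
    per-stratum regression — an extension beyond the canonical
    unadjusted allelic scan.
    """
    cohort_idx = cohort.set_index("sample_id")
    common = [s for s in genotypes.sample_ids if s in cohort_idx.index]
    if len(common) < genotypes.n_samples:
        log.warning(
            "%d genotyped samples lack phenotypes and are dropped",
            genotypes.n_samples - len(common),
        )
    gm = genotypes.take_samples(common) if len(common) < genotypes.n_samples else genotypes
    y = cohort_idx.loc[gm.sample_ids, "outcome_z"].to_numpy(dtype=float)
    labels = assignment.strata.reindex(gm.sample_ids).to_numpy()

    cov_mat = None
    if covariates:
        cov_cols = []
        sub = cohort_idx.loc[gm.sample_ids]
        for c in covariates:
            col = (
                (sub["sex"] == "female").astype(float)
                if c == "sex"
                else sub[c].astype(float)
            )
            cov_cols.append(col.to_numpy())
        cov_mat = np.column_stack(cov_cols)

    results = {}
    for name in ("control", "case"):
        sel = labels == name
        if cov_mat is None:
            results[name] = _stratum_slopes(gm.calls[sel], y[sel])
        else:
            results[name] = _stratum_slopes_adjusted(gm.calls[sel], y[sel], cov_mat[sel])

    b1, s1, n1 = results["control"]
    b2, s2, n2 = results["case"]
    with np.errstate(invalid="ignore"):
        z = (b2 - b1) / np.sqrt(s1**2 + s2**2)
        z = np.where((s1 > 0) & (s2 > 0), z, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "SNP": gm.snp_ids,
            "CHR": gm.snp_meta["chrom"].to_numpy(),
            "BP": gm.snp_meta["pos"].to_numpy(),
            "BETA1": b1, "SE1": s1, "NMISS1": n1,
            "BETA2": b2, "SE2": s2, "NMISS2": n2,
            "Z": z, "P": p,
        },
        columns=SCAN_COLUMNS,
    )
    n_testable = int(np.isfinite(z).sum())
    if n_testable == 0:
        log.warning("no testable SNPs in scan")
    log.info("scanned %d SNPs (%d testable)", len(table), n_testable)
    return table


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
def genomic_lambda(records: pd.DataFrame, min_snps: int = 100) -> float:
    """Genomic-control inflation factor from the scan Z statistics."""
    z = records["Z"].to_numpy(dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_snps:
        log.warning("lambda undefined: only %d testable SNPs (< %d)", z.size, min_snps)
        return np.nan
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def scan_summary(records: pd.DataFrame) -> dict:
    p = records["P"].to_numpy(dtype=float)
    finite = np.isfinite(p)
    return {
        "n_snps_tested": int(finite.sum()),
        "n_not_testable": int((~finite).sum()),
        "n_significant": int((p[finite] <= GENOME_WIDE_P).sum()),
        "n_suggestive": int((p[finite] <= SUGGESTIVE_P).sum()),
        "lambda_gc": genomic_lambda(records),
        "sign_convention": "Z = case slope minus control slope",
    }


def plot_tables(records: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Manhattan and QQ tables ready for plotting.

    Manhattan rows carry a genome-cumulative coordinate and
    ``-log10(P)``; QQ rows pair the sorted observed ``-log10(P)`` with
    uniform order-statistic expectations ``-log10((i - 0.5) / m)``.
    """
    ok = records[np.isfinite(records["P"].to_numpy(dtype=float))].copy()
    if ok.empty:
        empty_m = pd.DataFrame(columns=["SNP", "CHR", "BP", "cum_pos", "mlog10p"])
        empty_q = pd.DataFrame(columns=["expected", "observed"])
        return empty_m, empty_q
    offset = 0
    cum = np.empty(len(ok))
    chroms = list(pd.unique(ok["CHR"]))
    for c in chroms:
        sel = (ok["CHR"] == c).to_numpy()
        bp = ok.loc[sel, "BP"].to_numpy(dtype=float)
        cum[sel] = bp + offset
        offset += bp.max() + 1
    manhattan = pd.DataFrame(
        {
            "SNP": ok["SNP"].to_numpy(),
            "CHR": ok["CHR"].to_numpy(),
            "BP": ok["BP"].to_numpy(),
            "cum_pos": cum,
            "mlog10p": -np.log10(ok["P"].to_numpy(dtype=float)),
        }
    )
    obs = np.sort(-np.log10(ok["P"].to_numpy(dtype=float)))[::-1]
    m = obs.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    qq = pd.DataFrame({"expected": expected, "observed": obs})
    return manhattan, qq


def save_plots(records: pd.DataFrame, manhattan_png, qq_png) -> None:
    """Render Manhattan/QQ PNGs with the 5e-8 and 1e-5 threshold lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    manhattan, qq = plot_tables(records)
    fig, ax = plt.subplots(figsize=(9, 3.5))
    for i, (_, grp) in enumerate(manhattan.groupby("CHR", sort=False)):
        ax.scatter(grp["cum_pos"], grp["mlog10p"], s=4,
                   color="#3b6ea5" if i % 2 == 0 else "#8aa8c7")
    ax.axhline(-np.log10(GENOME_WIDE_P), color="red", lw=0.8)
    ax.axhline(-np.log10(SUGGESTIVE_P), color="black", lw=0.8)
    ax.set_xlabel("chromosomal position")
    ax.set_ylabel("-log10 P")
    fig.tight_layout()
    fig.savefig(manhattan_png, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.scatter(qq["expected"], qq["observed"], s=4, color="#3b6ea5")
    lim = max(qq["expected"].max(), qq["observed"].max()) if len(qq) else 1.0
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("expected -log10 P")
    ax.set_ylabel("observed -log10 P")
    fig.tight_layout()
    fig.savefig(qq_png, dpi=120)
    plt.close(fig)


def write_scan_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
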