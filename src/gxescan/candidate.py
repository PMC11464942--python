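"""Candidate-SNP cubic G x E analysis.

The candidate model regresses the outcome on a (centered) genotype
code, the linear/quadratic/cubic powers of the standardized trauma
score, their genotype interactions, the covariates, and any covariate
interaction retained by a screening step (covariate x gene and
covariate x trauma products tested one at a time, so the G x E term is
not confounded by covariate effects). Follow-ups:

* simple slopes — an independent cubic fit per genotype group on the
  shared z scale (the trauma z-score is computed once on the full
  analysis sample so curves and turning points are comparable);
* turning points — real roots of the fitted curve's first derivative,
  classified by the second-derivative sign and mapped back to raw
  trauma units;
* split-half cross-validation — a seeded 50/50 split stratified by
  genotype group, the per-group pattern re-checked in each half
  (non-carrier U-shape: positive quadratic with a non-significant
  cubic; carrier cubic decline: negative significant cubic).

Genotype coding defaults to dominant carrier (A-carrier vs GG);
additive dosage coding is available for cross-checks against the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import MISSING
from .curvilinear import (
    ALPHA,
    DEFAULT_COVARIATES,
    PolyFitResult,
    _fit_ols,
    _result_from_sm,
    _zname,
    build_design,
    fit_poly,
)
from .exceptions import ModelError

log = logging.getLogger(__name__)

GROUP_NONCARRIER = "GG"
GROUP_CARRIER = "A_carrier"


# ----------------------------------------------------------------------
@dataclass
class TurningPoint:
    location_z: float
    location_raw: float
    kind: str  # minimum | maximum
    in_range: bool


@dataclass
class SplitHalfResult:
    seed: int
    halves: List[dict]
    full_pattern: dict
    replicated: bool

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "halves": self.halves,
            "full_pattern": self.full_pattern,
            "replicated": self.replicated,
        }


@dataclass
class GxEResult:
    """Joint-model coefficient table plus the follow-up analyses."""

    table: pd.DataFrame
    n: int
    group_sizes: Dict[str, int]
    retained_interactions: List[str]
    simple_slopes: Dict[str, PolyFitResult]
    turning_points: Dict[str, List[TurningPoint]]
    split_half: Optional[SplitHalfResult] = None

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "group_sizes": self.group_sizes,
            "retained_interactions": self.retained_interactions,
            "coefficients": self.table.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "turning_points": {
                g: [vars(tp) for tp in tps] for g, tps in self.turning_points.items()
            },
            "simple_slopes": {
                g: f.table.reset_index()
                .rename(columns={"index": "term"})
                .to_dict(orient="records")
                for g, f in self.simple_slopes.items()
            },
            "split_half": self.split_half.to_dict() if self.split_half else None,
        }


# ----------------------------------------------------------------------
def code_genotype(
    dosage: np.ndarray, mode: str = "dominant_carrier"
) -> Tuple[np.ndarray, np.ndarray]:
    """Genotype code and validity mask from hard-call dosages.

    dominant_carrier: 1 for carriers (dosage >= 1) else 0; additive:
    the dosage unchanged. Missing calls are excluded via the mask (and
    logged).
    """
    dosage = np.asarray(dosage)
    valid = dosage != MISSING
    n_missing = int((~valid).sum())
    if n_missing:
        log.info("excluding %d samples with a missing candidate genotype", n_missing)
    coded = np.where(valid, dosage, 0).astype(float)
    if mode == "dominant_carrier":
        coded = (coded >= 1).astype(float)
    elif mode != "additive_dosage":
        raise ModelError(f"unknown genotype coding mode {mode!r}")
    return coded, valid


def _analysis_frame(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    mode: str,
    covariates: Sequence[str],
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Complete-case cohort slice with a carrier/additive code attached."""
    coded, valid = code_genotype(dosage, mode)
    sub = cohort.copy()
    sub["_g"] = np.where(valid, coded, np.nan)
    needed = ["ctq_total", "outcome_z", "_g"] + list(covariates)
    complete = sub[needed].notna().all(axis=1)
    sub = sub[complete].reset_index(drop=True)
    return sub, sub["_g"].to_numpy(dtype=float)


def _joint_design(
    sub: pd.DataFrame,
    g: np.ndarray,
    covariates: Sequence[str],
    retained: Sequence[str],
    center_g: bool = True,
    ctq_mean: Optional[float] = None,
    ctq_sd: Optional[float] = None,
) -> Tuple[np.ndarray, pd.DataFrame, dict]:
    y, X, info = build_design(sub, 3, covariates, ctq_mean, ctq_sd)
    gc = g - g.mean() if center_g else g
    X["G"] = gc
    for k in (1, 2, 3):
        X[f"G_x_{_zname(k)}"] = gc * X[_zname(k)].to_numpy()
    for term in retained:
        cov, _, target = term.partition(":")
        col = "sex_female" if cov == "sex" else f"{cov}_z"
        base = gc if target == "G" else X["z"].to_numpy()
        X[f"{col}_x_{target}"] = X[col].to_numpy() * base
    return y, X, info


def screen_covariate_interactions(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    mode: str = "dominant_carrier",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> List[str]:
    """Keller-style screen of covariate x gene and covariate x trauma terms.

    Each candidate product (``cov:G`` and ``cov:z`` for every
    covariate) is added alone to the base G x E model and retained when
    its coefficient is significant at alpha = 0.05. Deterministic given
    the data.
    """
    sub, g = _analysis_frame(cohort, dosage, mode, covariates)
    retained = []
    for cov in covariates:
        for target in ("G", "z"):
            term = f"{cov}:{target}"
            y, X, _ = _joint_design(sub, g, covariates, [term])
            res = _fit_ols(y, X)
            col = ("sex_female" if cov == "sex" else f"{cov}_z") + f"_x_{target}"
            if res.pvalues[col] < ALPHA:
                retained.append(term)
    log.info("retained covariate interactions: %s", retained or "none")
    return retained


# ----------------------------------------------------------------------
def fit_gxe_model(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    retained: Optional[Sequence[str]] = None,
    mode: str = "dominant_carrier",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_floor: int = 100,
    force: bool = False,
) -> GxEResult:
    """Single OLS with the full G x E term set plus follow-ups.

    ``retained`` lists covariate interactions (``"age:z"`` style) to
    include; pass the output of :func:`screen_covariate_interactions`.
    Refuses (unless ``force``) when either genotype group falls below
    ``group_floor``.
    """
    if retained is None:
        retained = []
    sub, g = _analysis_frame(cohort, dosage, mode, covariates)
    groups = _group_labels(g, mode)
    sizes = {k: int(v) for k, v in pd.Series(groups).value_counts().items()}
    small = {k: v for k, v in sizes.items() if v < group_floor}
    if small and not force:
        raise ModelError(
            f"genotype group(s) below floor {group_floor}: {small}; "
            "pass force=True to fit anyway"
        )
    if len(sizes) < 2:
        raise ModelError("only one genotype group present; interaction inestimable")

    y, X, info = _joint_design(sub, g, covariates, retained)
    res = _fit_ols(y, X)
    fit = _result_from_sm(res, 3, info)

    slopes = simple_slopes(
        sub, sub["_g"].to_numpy(), mode=mode, covariates=covariates,
        ctq_mean=info["ctq_mean"], ctq_sd=info["ctq_sd"], group_floor=group_floor,
    )
    quad = simple_slopes(
        sub, sub["_g"].to_numpy(), mode=mode, covariates=covariates,
        ctq_mean=info["ctq_mean"], ctq_sd=info["ctq_sd"], group_floor=group_floor,
        degree=2,
    )
    tps = group_turning_points(slopes, quad)
    return GxEResult(
        table=fit.table,
        n=fit.n,
        group_sizes=sizes,
        retained_interactions=list(retained),
        simple_slopes=slopes,
        turning_points=tps,
    )


def _group_labels(g: np.ndarray, mode: str) -> np.ndarray:
    if mode == "dominant_carrier":
        return np.where(g >= 1, GROUP_CARRIER, GROUP_NONCARRIER)
    return np.where(g >= 1, GROUP_CARRIER, GROUP_NONCARRIER)  # carriers vs 0 copies


def simple_slopes(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    mode: str = "dominant_carrier",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    ctq_mean: Optional[float] = None,
    ctq_sd: Optional[float] = None,
    group_floor: int = 100,
    degree: int = 3,
) -> Dict[str, PolyFitResult]:
    """Independent per-group polynomial fits on a shared z scale.

    The trauma mean/SD default to the full analysis sample so the two
    group curves live on the same axis. Groups below ``group_floor``
    are skipped with a warning.
    """
    sub, g = _analysis_frame(cohort, dosage, mode, covariates)
    if ctq_mean is None:
        ctq_mean = float(sub["ctq_total"].mean())
    if ctq_sd is None:
        ctq_sd = float(sub["ctq_total"].std(ddof=1))
    labels = _group_labels(g, mode)
    out: Dict[str, PolyFitResult] = {}
    for grp in (GROUP_NONCARRIER, GROUP_CARRIER):
        sel = labels == grp
        if int(sel.sum()) < group_floor:
            log.warning("group %s below floor (%d); skipped", grp, int(sel.sum()))
            continue
        out[grp] = fit_poly(
            sub[sel], degree, covariates, ctq_mean=ctq_mean, ctq_sd=ctq_sd
        )
    return out


# ----------------------------------------------------------------------
def turning_points(
    coefficients: Sequence[float],
    z_range: Tuple[float, float],
    ctq_mean: float,
    ctq_sd: float,
) -> List[TurningPoint]:
    """Stationary points of a fitted quadratic/cubic curve.

    ``coefficients`` are (b1, b2) or (b1, b2, b3) on the z scale. Real
    roots of the first derivative are classified by the second
    derivative and mapped to raw trauma units; complex roots (monotone
    cubic) yield an empty list.
    """
    b = np.asarray(coefficients, dtype=float)
    if b.size == 3 and b[2] != 0:
        b1, b2, b3 = b
        disc = 4 * b2**2 - 12 * b3 * b1  # (2 b2)^2 - 4 (3 b3) b1
        if disc < 0:
            log.info("monotone cubic: no real stationary point")
            return []
        roots = np.array(
            [(-2 * b2 - np.sqrt(disc)) / (6 * b3), (-2 * b2 + np.sqrt(disc)) / (6 * b3)]
        )
        second = 6 * b3 * roots + 2 * b2
    elif b.size >= 2 and b[1] != 0:
        roots = np.array([-b[0] / (2 * b[1])])
        second = np.array([2 * b[1]])
    else:
        return []  # linear: no stationary point
    out = []
    for z0, s in sorted(zip(roots, second)):
        if s == 0:
            continue  # saddle / degenerate
        out.append(
            TurningPoint(
                location_z=float(z0),
                location_raw=float(ctq_mean + z0 * ctq_sd),
                kind="minimum" if s > 0 else "maximum",
                in_range=bool(z_range[0] <= z0 <= z_range[1]),
            )
        )
    return out


def group_turning_points(
    slopes: Dict[str, PolyFitResult],
    quadratic_refits: Optional[Dict[str, PolyFitResult]] = None,
) -> Dict[str, List[TurningPoint]]:
    """Turning points per group from each group's supported curve.

    A group keeps its cubic curve when the cubic term is significant at
    alpha = 0.05; otherwise the group is summarised by a quadratic
    curve — the dedicated quadratic refit when supplied, else the
    quadratic part of the cubic fit.
    """
    quadratic_refits = quadratic_refits or {}
    out = {}
    for grp, fit in slopes.items():
        coefs = fit.poly_coefficients()
        if fit.degree >= 3 and fit.pvalue(_zname(3)) >= ALPHA:
            quad = quadratic_refits.get(grp)
            coefs = quad.poly_coefficients() if quad is not None else coefs[:2]
        out[grp] = turning_points(coefs, fit.z_range, fit.ctq_mean, fit.ctq_sd)
    return out


# ----------------------------------------------------------------------
def _pattern_verdict(slopes: Dict[str, PolyFitResult]) -> dict:
    """Qualitative replication pattern from per-group cubic fits."""
    out = {"noncarrier_u_shape": False, "carrier_cubic_decline": False}
    if GROUP_NONCARRIER in slopes:
        f = slopes[GROUP_NONCARRIER]
        out["noncarrier_u_shape"] = bool(
            f.coef(_zname(2)) > 0 and f.pvalue(_zname(3)) >= ALPHA
        )
    if GROUP_CARRIER in slopes:
        f = slopes[GROUP_CARRIER]
        out["carrier_cubic_decline"] = bool(
            f.coef(_zname(3)) < 0 and f.pvalue(_zname(3)) < ALPHA
        )
    out["pattern"] = out["noncarrier_u_shape"] and out["carrier_cubic_decline"]
    return out


def split_half_cv(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    seed: int,
    mode: str = "dominant_carrier",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_floor: int = 100,
    min_n: int = 1000,
) -> SplitHalfResult:
    """Seeded, genotype-stratified 50/50 split with per-half re-analysis.

    Each half gets the full simple-slope analysis on the shared z scale
    of the complete sample; the replication flag is true when the
    qualitative pattern (non-carrier U-shape, carrier cubic decline)
    holds in both halves.
    """
    sub, g = _analysis_frame(cohort, dosage, mode, covariates)
    if len(sub) < min_n:
        raise ModelError(f"split-half needs n >= {min_n}, got {len(sub)}")
    ctq_mean = float(sub["ctq_total"].mean())
    ctq_sd = float(sub["ctq_total"].std(ddof=1))

    rng = np.random.default_rng(seed)
    labels = _group_labels(g, mode)
    half_idx = [[], []]
    for grp in np.unique(labels):
        idx = np.flatnonzero(labels == grp)
        idx = rng.permutation(idx)
        half = idx.size // 2
        half_idx[0].extend(idx[:half].tolist())
        half_idx[1].extend(idx[half:].tolist())

    full_slopes = simple_slopes(
        sub, sub["_g"].to_numpy(), mode, covariates,
        ctq_mean=ctq_mean, ctq_sd=ctq_sd, group_floor=group_floor,
    )
    full_pattern = _pattern_verdict(full_slopes)

    halves = []
    for h, idx in enumerate(half_idx):
        idx = sorted(idx)
        part = sub.iloc[idx]
        for grp in (GROUP_NONCARRIER, GROUP_CARRIER):
            if (labels[idx] == grp).sum() < group_floor:
                raise ModelError(
                    f"group {grp} too small in half {h + 1} after the split"
                )
        slopes_h = simple_slopes(
            part, part["_g"].to_numpy(), mode, covariates,
            ctq_mean=ctq_mean, ctq_sd=ctq_sd, group_floor=group_floor,
        )
        verdict = _pattern_verdict(slopes_h)
        verdict["n"] = len(part)
        verdict["coefficients"] = {
            grp: slopes_h[grp].poly_coefficients().tolist() for grp in slopes_h
        }
        halves.append(verdict)

    replicated = bool(all(h["pattern"] for h in halves))
    return SplitHalfResult(
        seed=seed, halves=halves, full_pattern=full_pattern, replicated=replicated
    )


def run_candidate_analysis(
    cohort: pd.DataFrame,
    dosage: np.ndarray,
    mode: str = "dominant_carrier",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    split_seed: int = 0,
    group_floor: int = 100,
    do_split_half: bool = True,
) -> GxEResult:
    """Screen -> joint model -> simple slopes -> turning points -> split-half."""
    retained = screen_covariate_interactions(cohort, dosage, mode, covariates)
    result = fit_gxe_model(
        cohort, dosage, retained, mode=mode, covariates=covariates,
        group_floor=group_floor,
    )
    if do_split_half:
        try:
            result.split_half = split_half_cv(
                cohort, dosage, split_seed, mode, covariates, group_floor
            )
        except ModelError as exc:
            log.warning("split-half skipped: %s", exc)
    return result
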