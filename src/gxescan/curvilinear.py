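"""Polynomial trauma -> outcome cascade with covariates.

Fits nested OLS models of the outcome on the linear..quartic powers of
the standardized trauma score (standardize-then-power convention, which
matches the generator's coefficient scale and limits collinearity),
with sex (female indicator), age and education (z-scored) as
covariates. Nested models are compared by incremental F tests — against
the linear model (F1) and against the previous degree (F2) — and by
AIC computed from the Gaussian likelihood with the error variance
counted as a free parameter (``aic = 2k - 2 logL``).

Degree selection uses the smallest AIC with the usual parsimony margin:
the lowest degree whose AIC lies within 2 units of the minimum (models
closer than one parameter's penalty are treated as equivalent and the
simpler one is preferred).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import ModelError

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("sex", "age", "education")
AIC_PARSIMONY_MARGIN = 2.0
ALPHA = 0.05


@dataclass
class PolyFitResult:
    """One fitted polynomial model.

    ``table`` has one row per term (index: z, z2, ..., covariates,
    const) with estimate, SE, t, two-sided p and the 95% CI. ``aic``
    counts the intercept and the error variance among the k free
    parameters.
    """

    degree: int
    table: pd.DataFrame
    r2: float
    log_likelihood: float
    aic: float
    n: int
    rss: float
    tss: float
    ctq_mean: float
    ctq_sd: float
    z_range: Tuple[float, float]

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def se(self, term: str) -> float:
        return float(self.table.loc[term, "se"])

    def poly_coefficients(self) -> np.ndarray:
        """(b1..b_degree) on the z scale."""
        return np.array([self.coef(_zname(k)) for k in range(1, self.degree + 1)])


@dataclass
class CascadeResult:
    fits: Dict[int, PolyFitResult]
    comparison: pd.DataFrame
    selected_degree: int
    aic_argmin_degree: int

    def to_dict(self) -> dict:
        return {
            "selected_degree": self.selected_degree,
            "aic_argmin_degree": self.aic_argmin_degree,
            "comparison": self.comparison.to_dict(orient="records"),
            "fits": {
                d: {
                    "r2": f.r2,
                    "aic": f.aic,
                    "log_likelihood": f.log_likelihood,
                    "n": f.n,
                    "terms": f.table.reset_index()
                    .rename(columns={"index": "term"})
                    .to_dict(orient="records"),
                }
                for d, f in self.fits.items()
            },
        }


def _zname(k: int) -> str:
    return "z" if k == 1 else f"z{k}"


# ----------------------------------------------------------------------
def build_design(
    cohort: pd.DataFrame,
    degree: int,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    ctq_mean: Optional[float] = None,
    ctq_sd: Optional[float] = None,
) -> Tuple[np.ndarray, pd.DataFrame, dict]:
    """Complete-case design matrix for one polynomial degree.

    The trauma score is standardized on the analysis sample (or with a
    caller-supplied mean/SD when fits must share a z scale) and then
    powered. Returns ``(y, X, info)`` where X includes the intercept
    and info records the dropped-row count and the z-scale parameters.
    """
    if not (1 <= degree <= 4):
        raise ModelError(f"degree must be 1..4, got {degree}")
    needed = ["ctq_total", "outcome_z"] + [c for c in covariates]
    for c in needed:
        if c not in cohort.columns:
            raise ModelError(f"cohort lacks column {c!r}")
    sub = cohort[needed].copy()
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropping %d incomplete rows from the fit", n_dropped)
    sub = sub[complete]
    if len(sub) <= degree + len(covariates) + 2:
        raise ModelError("too few complete cases for the requested model")

    ctq = sub["ctq_total"].to_numpy(dtype=float)
    if ctq_mean is None:
        ctq_mean = float(ctq.mean())
    if ctq_sd is None:
        ctq_sd = float(ctq.std(ddof=1))
    if ctq_sd == 0:
        raise ModelError("trauma score is constant; cannot standardize")
    z = (ctq - ctq_mean) / ctq_sd

    cols = {"const": np.ones(len(sub))}
    for k in range(1, degree + 1):
        cols[_zname(k)] = z**k
    for c in covariates:
        if c == "sex":
            cols["sex_female"] = (sub["sex"] == "female").to_numpy(dtype=float)
        else:
            v = sub[c].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            if sd == 0:
                raise ModelError(f"covariate {c!r} is constant")
            cols[f"{c}_z"] = (v - v.mean()) / sd
    X = pd.DataFrame(cols, index=sub.index)
    info = {
        "n": len(sub),
        "n_dropped": n_dropped,
        "ctq_mean": ctq_mean,
        "ctq_sd": ctq_sd,
        "z_range": (float(z.min()), float(z.max())),
        "complete_index": sub.index,
    }
    return sub["outcome_z"].to_numpy(dtype=float), X, info


def _fit_ols(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResultsWrapper:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ModelError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"columns: {list(X.columns)}"
        )
    return sm.OLS(y, X).fit()


def _result_from_sm(res, degree: int, info: dict) -> PolyFitResult:
    ci = res.conf_int(alpha=ALPHA)
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_low": ci[0] if isinstance(ci, pd.DataFrame) else ci[:, 0],
            "ci_high": ci[1] if isinstance(ci, pd.DataFrame) else ci[:, 1],
        }
    )
    k = len(res.params) + 1  # + error variance
    return PolyFitResult(
        degree=degree,
        table=table,
        r2=float(res.rsquared),
        log_likelihood=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        n=int(res.nobs),
        rss=float(res.ssr),
        tss=float(res.centered_tss),
        ctq_mean=info["ctq_mean"],
        ctq_sd=info["ctq_sd"],
        z_range=info["z_range"],
    )


def fit_poly(
    cohort: pd.DataFrame,
    degree: int,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    ctq_mean: Optional[float] = None,
    ctq_sd: Optional[float] = None,
) -> PolyFitResult:
    """Fit one polynomial model of the given degree."""
    y, X, info = build_design(cohort, degree, covariates, ctq_mean, ctq_sd)
    return _result_from_sm(_fit_ols(y, X), degree, info)


# ----------------------------------------------------------------------
def nested_f(rss_small: float, rss_big: float, df_diff: int, n: int, k_big: int):
    """Incremental F for nested OLS models (classical RSS form)."""
    df2 = n - k_big
    if df2 <= 0 or rss_big <= 0:
        return np.nan, (df_diff, df2), np.nan
    f = ((rss_small - rss_big) / df_diff) / (rss_big / df2)
    p = float(stats.f.sf(f, df_diff, df2))
    return float(f), (df_diff, df2), p


def fit_cascade(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> CascadeResult:
    """Fit degrees 1..4 on the same complete-case sample and compare.

    All four designs are built on the rows complete for the quartic
    model so that the nested comparisons share one sample.
    """
    if len(cohort) <= 50:
        raise ModelError("cascade needs n > 50")
    y4, X4, info = build_design(cohort, 4, covariates)
    fits: Dict[int, PolyFitResult] = {}
    sm_results = {}
    for d in range(1, 5):
        keep = ["const"] + [_zname(k) for k in range(1, d + 1)] + [
            c for c in X4.columns if not (c == "const" or c.startswith("z"))
        ]
        res = _fit_ols(y4, X4[keep])
        sm_results[d] = res
        fits[d] = _result_from_sm(res, d, info)

    rows = []
    n = fits[1].n
    for d in range(1, 5):
        row = {
            "degree": d,
            "r2": fits[d].r2,
            "aic": fits[d].aic,
            "log_likelihood": fits[d].log_likelihood,
        }
        k_big = len(sm_results[d].params)
        if d > 1:
            row["delta_r2_vs_linear"] = fits[d].r2 - fits[1].r2
            f1, df1, p1 = nested_f(fits[1].rss, fits[d].rss, d - 1, n, k_big)
            row.update({"F1": f1, "F1_df": df1, "F1_p": p1})
            row["delta_r2_vs_prev"] = fits[d].r2 - fits[d - 1].r2
            f2, df2, p2 = nested_f(fits[d - 1].rss, fits[d].rss, 1, n, k_big)
            row.update({"F2": f2, "F2_df": df2, "F2_p": p2})
        rows.append(row)
    comparison = pd.DataFrame(rows)

    aics = np.array([fits[d].aic for d in range(1, 5)])
    argmin_degree = int(np.argmin(aics)) + 1
    within = np.flatnonzero(aics <= aics.min() + AIC_PARSIMONY_MARGIN)
    selected = int(within[0]) + 1
    log.info("cascade selected degree %d (argmin AIC %d)", selected, argmin_degree)
    return CascadeResult(
        fits=fits,
        comparison=comparison,
        selected_degree=selected,
        aic_argmin_degree=argmin_degree,
    )


# ----------------------------------------------------------------------
def demographic_moderation(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    degree: Optional[int] = None,
) -> pd.DataFrame:
    """Moderator x polynomial interactions, one moderator at a time.

    For each covariate, adds its product with every power of z to the
    selected (or given) polynomial model and reports the interaction
    estimates with CIs, p-values and an alpha = 0.05 flag. Raises
    :class:`ModelError` for a constant moderator (interaction
    inestimable).
    """
    if degree is None:
        degree = fit_cascade(cohort, covariates).selected_degree
    y, X, info = build_design(cohort, degree, covariates)
    mod_cols = {
        "sex": "sex_female",
        "age": "age_z",
        "education": "education_z",
    }
    rows = []
    for mod in covariates:
        col = mod_cols.get(mod, f"{mod}_z")
        if col not in X.columns:
            raise ModelError(f"moderator {mod!r} not in the design")
        mvals = X[col].to_numpy()
        if np.std(mvals) == 0:
            raise ModelError(f"moderator {mod!r} is constant; interaction inestimable")
        Xm = X.copy()
        for k in range(1, degree + 1):
            Xm[f"{col}_x_{_zname(k)}"] = mvals * X[_zname(k)].to_numpy()
        res = _fit_ols(y, Xm)
        ci = res.conf_int(alpha=ALPHA)
        for k in range(1, degree + 1):
            term = f"{col}_x_{_zname(k)}"
            rows.append(
                {
                    "moderator": mod,
                    "term": _zname(k),
                    "estimate": float(res.params[term]),
                    "se": float(res.bse[term]),
                    "t": float(res.tvalues[term]),
                    "p": float(res.pvalues[term]),
                    "ci_low": float(ci.loc[term, 0]),
                    "ci_high": float(ci.loc[term, 1]),
                    "significant": bool(res.pvalues[term] < ALPHA),
                }
            )
    return pd.DataFrame(rows)


def curve_table(
    fit: PolyFitResult, n_points: int = 101
) -> pd.DataFrame:
    """Fitted-curve grid (z, raw CTQ, fitted value) for plotting."""
    z = np.linspace(fit.z_range[0], fit.z_range[1], n_points)
    coefs = fit.poly_coefficients()
    yhat = fit.coef("const") + sum(c * z ** (k + 1) for k, c in enumerate(coefs))
    return pd.DataFrame(
        {
            "z": z,
            "ctq_total": fit.ctq_mean + z * fit.ctq_sd,
            "fitted": yhat,
        }
    )
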