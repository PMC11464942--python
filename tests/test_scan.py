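"""Interaction-scan behaviour: stratification, slope fits vs closed
forms, the slope-difference Z test, oracle equivalence and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxescan import (
    SimulationConfig,
    dichotomize_env,
    genome_scan,
    genomic_lambda,
    gxe_z_test,
    plot_tables,
    simulate_cohort,
    stratified_allelic_fit,
)
from gxescan.core import MISSING
from gxescan.exceptions import ModelError
from gxescan.scan import CHI2_1_MEDIAN, scan_summary
from conftest import make_matrix
from _oracles import ols_slope_se


def _toy_cohort(scores):
    n = len(scores)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "ctq_total": scores,
            "outcome_z": np.zeros(n),
        }
    )


# ----------------------------------------------------------------------
# dichotomization
# ----------------------------------------------------------------------
def test_dichotomize_distinct_scores_quantile_forced():
    cohort = _toy_cohort(np.arange(1, 101))
    a = dichotomize_env(cohort, q=0.27)
    assert a.lower_cut == 27 and a.upper_cut == 74
    assert (a.strata == "control").sum() == 27
    assert (a.strata == "case").sum() == 27
    assert (a.strata == "excluded").sum() == 46


def test_dichotomize_ties_assigned_inclusively():
    scores = np.array([14] * 40 + list(range(15, 75)))  # 40% floor mass
    a = dichotomize_env(_toy_cohort(scores), q=0.27)
    assert a.lower_cut == 14
    assert (a.strata == "control").sum() == 40  # exceeds q, ties in the tail


def test_dichotomize_degenerate_raises():
    with pytest.raises(ModelError, match="cannot form strata"):
        dichotomize_env(_toy_cohort(np.full(50, 20)), q=0.27)
    with pytest.raises(ModelError):
        dichotomize_env(_toy_cohort(np.arange(100)), q=0.7)


# ----------------------------------------------------------------------
# per-stratum fits
# ----------------------------------------------------------------------
def _labels(n_ctrl, n_case):
    return np.array(["control"] * n_ctrl + ["case"] * n_case)


def test_noiseless_slope_recovered_with_zero_se():
    rng = np.random.default_rng(0)
    dosage = rng.integers(0, 3, 40).astype(np.int8)
    y = 0.5 * dosage
    res = stratified_allelic_fit(dosage, y, _labels(20, 20))
    for stratum in ("control", "case"):
        beta, se, n = res[stratum]
        assert beta == pytest.approx(0.5, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)
        assert n == 20


def test_six_point_slopes_match_textbook_ols():
    dosage = np.array([0, 1, 2, 0, 1, 2, 0, 0, 1, 2, 2, 1], dtype=np.int8)
    y = np.array([0.1, 0.4, 0.9, -0.2, 0.5, 1.1, 0.0, 0.3, 0.2, 0.8, 1.0, 0.6])
    res = stratified_allelic_fit(dosage, y, _labels(6, 6))
    for stratum, sl in (("control", slice(0, 6)), ("case", slice(6, 12))):
        want_b, want_se = ols_slope_se(dosage[sl], y[sl])
        beta, se, n = res[stratum]
        assert beta == pytest.approx(want_b, abs=1e-12)
        assert se == pytest.approx(want_se, abs=1e-12)


def test_sample_order_invariance():
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, 60).astype(np.int8)
    dosage[rng.random(60) < 0.1] = MISSING
    y = rng.normal(size=60)
    labels = _labels(30, 30)
    base = stratified_allelic_fit(dosage, y, labels)
    perm = rng.permutation(60)
    permuted = stratified_allelic_fit(dosage[perm], y[perm], labels[perm])
    for s in ("control", "case"):
        assert base[s] == pytest.approx(permuted[s], nan_ok=True)


def test_monomorphic_stratum_flagged_not_testable():
    dosage = np.array([1] * 10 + [0, 1, 2, 0, 1, 2, 1, 1, 0, 2], dtype=np.int8)
    y = np.arange(20.0)
    res = stratified_allelic_fit(dosage, y, _labels(10, 10))
    assert np.isnan(res["control"][0])
    assert np.isfinite(res["case"][0])


# ----------------------------------------------------------------------
# Z test
# ----------------------------------------------------------------------
def test_z_zero_when_slopes_equal():
    z, p = gxe_z_test(0.3, 0.1, 0.3, 0.2)
    assert z == 0.0 and p == 1.0


def test_z_closed_form_value():
    z, p = gxe_z_test(0.0, 0.1, 0.3, 0.1)
    assert z == pytest.approx(0.3 / np.sqrt(0.02), rel=1e-12)  # 2.12132...
    assert p == pytest.approx(2 * stats.norm.sf(2.1213203435596424), rel=1e-12)
    assert p == pytest.approx(0.033894853524689295, rel=1e-9)


def test_z_antisymmetric_under_label_swap():
    z1, p1 = gxe_z_test(0.1, 0.05, -0.2, 0.07)
    z2, p2 = gxe_z_test(-0.2, 0.07, 0.1, 0.05)
    assert z1 == -z2 and p1 == p2


def test_z_nonpositive_se_not_testable():
    z, p = gxe_z_test(0.1, 0.0, 0.2, 0.1)
    assert np.isnan(z) and np.isnan(p)


# ----------------------------------------------------------------------
# genome scan
# ----------------------------------------------------------------------
def _loop_scan(gm, cohort, assignment):
    """Per-SNP brute-force oracle built from scipy.stats.linregress."""
    idx = cohort.set_index("sample_id")
    y = idx.loc[gm.sample_ids, "outcome_z"].to_numpy()
    labels = assignment.strata.reindex(gm.sample_ids).to_numpy()
    zs = []
    for j in range(gm.n_snps):
        stats_ = {}
        for name in ("control", "case"):
            sel = (labels == name) & (gm.calls[:, j] != MISSING)
            x = gm.calls[sel, j].astype(float)
            if sel.sum() < 3 or x.var() == 0:
                stats_[name] = (np.nan, np.nan)
                continue
            r = stats.linregress(x, y[sel])
            stats_[name] = (r.slope, r.stderr)
        (b1, s1), (b2, s2) = stats_["control"], stats_["case"]
        zs.append((b2 - b1) / np.sqrt(s1**2 + s2**2) if s1 > 0 and s2 > 0 else np.nan)
    return np.array(zs)


def test_vectorized_scan_equals_loop_oracle():
    cfg = SimulationConfig(n_samples=200, n_snps=50, seed=41, missing_rate=0.05,
                           maf_range=(0.1, 0.5))
    gm, cohort = simulate_cohort(cfg)
    assignment = dichotomize_env(cohort, q=0.3)
    records = genome_scan(gm, cohort, assignment)
    want = _loop_scan(gm, cohort, assignment)
    got = records["Z"].to_numpy()
    both = np.isfinite(want) & np.isfinite(got)
    assert np.array_equal(np.isfinite(want), np.isfinite(got))
    assert np.allclose(got[both], want[both], atol=1e-10)


def test_null_scan_type_one_error_calibrated():
    """No planted genotype effect: p < 0.05 fraction within 3 binomial
    SEs of 0.05 across 2,000 SNPs."""
    shared = (-0.20, 0.24, -0.12)
    cfg = SimulationConfig(
        n_samples=3000, n_snps=2000, seed=42, missing_rate=0.0,
        group_coefficients={"GG": shared, "A_carrier": shared},
        genotype_main_effect=0.0,
    )
    gm, cohort = simulate_cohort(cfg)
    records = genome_scan(gm, cohort, dichotomize_env(cohort, 0.27))
    p = records["P"].to_numpy()
    p = p[np.isfinite(p)]
    frac = (p < 0.05).mean()
    se3 = 3 * np.sqrt(0.05 * 0.95 / p.size)
    assert abs(frac - 0.05) < se3 + 0.005


def test_planted_interaction_is_top_hit():
    cfg = SimulationConfig(
        n_samples=8000, n_snps=200, seed=43, missing_rate=0.0,
        group_coefficients={"GG": (-0.1, 0.0, 0.0), "A_carrier": (-0.5, 0.0, 0.0)},
    )
    gm, cohort = simulate_cohort(cfg)
    records = genome_scan(gm, cohort, dichotomize_env(cohort, 0.27))
    top = records.loc[records["P"].idxmin(), "SNP"]
    assert top == cfg.causal_snp_id


# ----------------------------------------------------------------------
# lambda and plot tables
# ----------------------------------------------------------------------
def _records_from_z(z):
    z = np.asarray(z, float)
    return pd.DataFrame(
        {
            "SNP": [f"r{i}" for i in range(z.size)],
            "CHR": 1,
            "BP": np.arange(1, z.size + 1),
            "Z": z,
            "P": 2 * stats.norm.sf(np.abs(z)),
        }
    )


def test_lambda_one_when_z2_at_chi2_median():
    z = np.full(500, np.sqrt(CHI2_1_MEDIAN))
    assert genomic_lambda(_records_from_z(z)) == pytest.approx(1.0, rel=1e-12)


def test_lambda_standard_normal_draws_near_one():
    # sample-median asymptotics: sd(lambda) = 1/(2 f(m) sqrt(n)) / m
    # ~= 0.0074 at n = 1e5; assert within 3 sigma
    z = np.random.default_rng(44).standard_normal(100_000)
    assert genomic_lambda(_records_from_z(z)) == pytest.approx(1.0, abs=0.022)


def test_lambda_scale_equivariance():
    z = np.random.default_rng(45).standard_normal(5000)
    lam = genomic_lambda(_records_from_z(z))
    lam2 = genomic_lambda(_records_from_z(np.sqrt(2) * z))
    assert lam2 == pytest.approx(2 * lam, rel=1e-12)


def test_lambda_undefined_below_floor():
    assert np.isnan(genomic_lambda(_records_from_z(np.ones(10))))


def test_qq_expected_column_order_statistics():
    z = np.random.default_rng(46).standard_normal(10)
    _, qq = plot_tables(_records_from_z(z))
    want = -np.log10((np.arange(1, 11) - 0.5) / 10)
    assert np.allclose(qq["expected"], want)
    assert np.allclose(np.sort(qq["observed"])[::-1], qq["observed"])  # sorted desc


def test_exact_threshold_counted_significant():
    rec = _records_from_z([1.0])
    rec.loc[0, "P"] = 5e-8
    s = scan_summary(rec)
    assert s["n_significant"] == 1 and s["n_suggestive"] == 1


def test_empty_records_no_crash():
    rec = _records_from_z([])
    manhattan, qq = plot_tables(rec)
    assert manhattan.empty and qq.empty
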