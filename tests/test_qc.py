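"""QC statistics against enumeration/closed-form oracles, and the
filter cascade's behaviour on planted defects."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gxescan import (
    QCThresholds,
    RelatednessConfig,
    SimulationConfig,
    apply_qc,
    hwe_exact_test,
    king_kinship,
    prune_related,
    sample_heterozygosity_f,
    simulate_genotypes,
    inject_relatedness,
)
from gxescan.core import MISSING
from gxescan.exceptions import QCError
from gxescan.qc import hwe_exact_pvalues, snp_qc_table
from conftest import make_matrix
from _oracles import hwe_enumeration_pvalue, hwe_enumeration_pvalues


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------
def test_hwe_mode_observation_gives_p_one():
    # (25, 50, 25): the observed het count is the conditional mode, so
    # every outcome has probability <= it and the p-value is 1
    assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-12)


def test_hwe_monomorphic_is_one_by_convention():
    assert hwe_exact_test(100, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 57) == 1.0


def test_hwe_extreme_het_excess_is_tiny():
    p = hwe_exact_test(0, 100, 0)
    assert p < 1e-20
    assert p == pytest.approx(hwe_enumeration_pvalue(0, 100, 0), rel=1e-9)


def test_hwe_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_equals_enumeration_oracle_small_sweep():
    """Recurrence == closed-form enumeration for every triple, n <= 60."""
    for n in range(1, 61):
        for n_rare in range(0, n + 1):
            got = hwe_exact_pvalues(n, n_rare)[1]
            want = hwe_enumeration_pvalues(n, n_rare)
            assert np.allclose(got, want, atol=1e-12), (n, n_rare)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n_aa=st.integers(0, 300), n_ab=st.integers(0, 300), n_bb=st.integers(0, 300)
)
def test_hwe_matches_oracle_on_random_triples(n_aa, n_ab, n_bb):
    if n_aa + n_ab + n_bb == 0:
        return
    assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
        hwe_enumeration_pvalue(n_aa, n_ab, n_bb), abs=1e-12
    )


def test_hwe_symmetric_in_allele_labels():
    assert hwe_exact_test(10, 40, 80) == pytest.approx(
        hwe_exact_test(80, 40, 10), abs=1e-15
    )


def test_hwe_null_pvalues_roughly_uniform():
    """1,000 HWE-simulated SNPs: the rejection rate at 0.05 sits in
    [0.03, 0.07] (exact-test conservatism keeps it below nominal)."""
    cfg = SimulationConfig(
        n_samples=2000, n_snps=1000, seed=31, missing_rate=0.0,
        maf_range=(0.1, 0.5),
    )
    gm = simulate_genotypes(cfg)
    tab = snp_qc_table(gm)
    frac = float((tab["hwe_p"] < 0.05).mean())
    assert 0.01 <= frac <= 0.07


# ----------------------------------------------------------------------
# heterozygosity F
# ----------------------------------------------------------------------
def test_f_fully_heterozygous_at_half_freq_is_minus_one():
    # all samples het at every SNP -> p = 0.5, E_het = m/2, O = m -> F = -1
    gm = make_matrix(np.ones((6, 10), dtype=np.int8))
    tab = sample_heterozygosity_f(gm)
    assert np.allclose(tab["het_f"], -1.0)


def test_f_fully_homozygous_is_one():
    calls = np.ones((8, 12), dtype=np.int8)
    calls[0] = np.tile([0, 2], 6)  # all-homozygous sample at p=0.5-ish SNPs
    gm = make_matrix(calls)
    tab = sample_heterozygosity_f(gm)
    assert tab.loc[0, "het_f"] == pytest.approx(1.0)


def test_f_mean_near_zero_under_hwe():
    cfg = SimulationConfig(n_samples=3000, n_snps=400, seed=32, missing_rate=0.0,
                           maf_range=(0.1, 0.5))
    gm = simulate_genotypes(cfg)
    tab = sample_heterozygosity_f(gm)
    assert abs(tab["het_f"].mean()) < 0.01


def test_f_all_missing_sample_flagged():
    calls = np.tile([0, 1, 2, 1], (5, 3))[:, :12].astype(np.int8)
    calls[2] = MISSING
    gm = make_matrix(calls)
    tab = sample_heterozygosity_f(gm)
    assert not tab.loc[2, "defined"]
    assert np.isnan(tab.loc[2, "het_f"])


# ----------------------------------------------------------------------
# kinship
# ----------------------------------------------------------------------
def test_kinship_duplicate_is_exactly_half():
    rng = np.random.default_rng(33)
    row = rng.integers(0, 3, 300).astype(np.int8)
    gm = make_matrix(np.vstack([row, row]))
    tab = king_kinship(gm, min_snps=10)
    assert tab.loc[0, "phi"] == pytest.approx(0.5, abs=1e-15)
    assert tab.loc[0, "degree_call"] == "mz/dup"


def test_kinship_parent_offspring_near_quarter():
    cfg = SimulationConfig(
        n_samples=40, n_snps=5000, seed=34, missing_rate=0.0,
        maf_range=(0.2, 0.5),
        relatedness=RelatednessConfig(n_parent_offspring=10),
    )
    gm = inject_relatedness(simulate_genotypes(cfg), cfg)
    tab = king_kinship(gm, min_snps=100)
    key = tab.set_index(["sample_i", "sample_j"])
    phis = [
        key.loc[(r.sample_i, r.sample_j), "phi"]
        for r in gm.related_pairs.itertuples(index=False)
    ]
    assert abs(np.mean(phis) - 0.25) < 0.02


def test_kinship_unrelated_near_zero():
    cfg = SimulationConfig(n_samples=30, n_snps=4000, seed=35, missing_rate=0.0,
                           maf_range=(0.2, 0.5))
    gm = simulate_genotypes(cfg)
    tab = king_kinship(gm, min_snps=100)
    assert abs(tab["phi"].mean()) < 0.02
    assert (tab["degree_call"] == "unrelated").mean() > 0.95


def test_kinship_skips_sparse_pairs():
    calls = np.array([[1, 1, 1, 1], [1, 1, 1, 1], [MISSING] * 4], dtype=np.int8)
    gm = make_matrix(calls)
    tab = king_kinship(gm, min_snps=2)
    pairs = set(zip(tab["sample_i"], tab["sample_j"]))
    assert pairs == {("s0", "s1")}


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------
def _pairs(rows):
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "phi", "n_snps_used",
                                       "degree_call"])


def test_prune_no_flagged_pairs_is_empty():
    assert prune_related(_pairs([("a", "b", 0.01, 100, "unrelated")])) == []


def test_prune_single_duplicate_removes_one():
    removed = prune_related(_pairs([("a", "b", 0.5, 100, "mz/dup")]))
    assert len(removed) == 1 and removed[0] in {"a", "b"}


def test_prune_triangle_matches_exhaustive_search():
    """3 mutually related samples: greedy removes 2, the exhaustive
    minimum over all removal sets."""
    rows = [
        ("a", "b", 0.3, 100, "1st"),
        ("b", "c", 0.3, 100, "1st"),
        ("a", "c", 0.3, 100, "1st"),
    ]
    removed = prune_related(_pairs(rows))
    # exhaustive: smallest subset covering all three edges
    best = None
    for k in range(4):
        for combo in itertools.combinations("abc", k):
            if all(set(e[:2]) & set(combo) for e in rows):
                best = combo
                break
        if best is not None:
            break
    assert len(removed) == len(best) == 2


def test_prune_first_degree_threshold_ignores_second():
    rows = [("a", "b", 0.1, 100, "2nd")]
    assert prune_related(_pairs(rows), "1st") == []
    assert len(prune_related(_pairs(rows), "2nd")) == 1


# ----------------------------------------------------------------------
# cascade
# ----------------------------------------------------------------------
def test_apply_qc_clean_cohort_survives_and_is_idempotent():
    # enough SNPs that kinship noise (sd ~ 1/sqrt(m)) stays well below
    # the 2nd-degree cut across all ~45k pairs
    cfg = SimulationConfig(n_samples=300, n_snps=2000, seed=36, missing_rate=0.002,
                           maf_range=(0.1, 0.5))
    gm = simulate_genotypes(cfg)
    out, report = apply_qc(gm)
    assert out.n_samples / gm.n_samples >= 0.99
    assert out.n_snps / gm.n_snps >= 0.99
    again, _ = apply_qc(out)
    assert np.array_equal(again.calls, out.calls)
    assert again.sample_ids == out.sample_ids


def test_apply_qc_removes_high_missingness_snp():
    cfg = SimulationConfig(n_samples=1000, n_snps=50, seed=37, missing_rate=0.0,
                           maf_range=(0.2, 0.5))
    gm = simulate_genotypes(cfg)
    calls = gm.calls.copy()
    calls[:30, 5] = MISSING  # 3% missing at SNP 5
    gm2 = make_matrix(calls, ids=gm.snp_ids)
    out, report = apply_qc(gm2)
    assert gm.snp_ids[5] not in out.snp_ids
    row = report.removed[report.removed["id"] == gm.snp_ids[5]]
    assert row["step"].tolist() == ["snp_missingness"]


def test_apply_qc_removes_one_of_planted_duplicates():
    cfg = SimulationConfig(
        n_samples=150, n_snps=2500, seed=38, missing_rate=0.0,
        maf_range=(0.2, 0.5), relatedness=RelatednessConfig(n_duplicate=1),
    )
    gm = inject_relatedness(simulate_genotypes(cfg), cfg)
    dup = gm.related_pairs.iloc[0]
    out, report = apply_qc(gm)
    survivors = {dup["sample_i"], dup["sample_j"]} & set(out.sample_ids)
    assert len(survivors) == 1
    rel_rows = report.removed[report.removed["step"] == "relatedness"]
    assert len(rel_rows) == 1


def test_apply_qc_all_filtered_raises():
    gm = make_matrix(np.full((10, 5), MISSING, dtype=np.int8))
    with pytest.raises(QCError, match="all .* filtered|filtered at step"):
        apply_qc(gm)


def test_snp_filter_survivor_set_independent_of_attribution_order():
    """The surviving SNP set equals the intersection of the three
    independent per-SNP filters applied in any order."""
    cfg = SimulationConfig(n_samples=500, n_snps=300, seed=39, missing_rate=0.015,
                           maf_range=(0.005, 0.5))
    gm = simulate_genotypes(cfg)
    tab = snp_qc_table(gm)
    thr = QCThresholds()
    keep_miss = (1 - tab["call_rate"]) <= thr.snp_missing
    keep_maf = tab["maf"].fillna(0) >= thr.maf_min
    keep_hwe = tab["hwe_p"].fillna(1) >= thr.hwe_p
    assert (tab["pass"] == (keep_miss & keep_maf & keep_hwe)).all()
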