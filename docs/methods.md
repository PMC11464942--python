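# Methods

This note documents the models, conventions and numerical choices
behind `gxescan`, and what the synthetic-cohort generator does and does
not emulate.

## Generative model

A cohort of `n_samples` unrelated individuals is drawn as follows.

**Genotypes.** Each of `n_snps` bi-allelic SNPs gets an A1-allele
frequency sampled uniformly from `maf_range` (default (0.05, 0.5]);
hard-call dosages are Binomial(2, p), i.e. exact Hardy–Weinberg
proportions, independent across SNPs. One designated causal locus sits
at `causal_snp_maf` (default 0.3, carrier fraction ≈ 0.51 under HWE).
Missing calls are injected uniformly at random at `missing_rate`
(default 0.005, a realistic chip call-failure rate), except at the
causal locus, which stays fully called so the planted truth is defined
for every sample. Optional relative pairs (duplicates,
parent–offspring, full and half siblings) are appended by Mendelian
transmission; their expected kinship coefficients (0.5, 0.25, 0.25,
0.125) are recorded alongside.

**Trauma score.** 14 five-point ordinal items are generated from a
shared latent standard-normal factor (squared loading 0.45) plus unique
noise, thresholded at unequal cut points giving marginal level
probabilities (0.62, 0.20, 0.10, 0.05, 0.03); `trauma_skew` scales the
thresholds (larger → more floor mass). The resulting sum score is
bounded in [14, 70], right-skewed (skewness ≈ 1.4), and has mean ≈ 23,
SD ≈ 9. The factor loading was chosen so the implied mean inter-item
correlation (≈ 0.35) reproduces the internal consistency reported for
the scale (Cronbach's α ≈ 0.89 for 14 items); the unequal thresholds
reproduce the floor-heavy shape that makes 27% tail cuts meaningful.
No specific item content or per-item heterogeneity is modelled.

**Outcome.** With z the standardized (ddof = 1) trauma total and g the
carrier indicator at the causal locus,

```
y = g·main + b1(g)·z + b2(g)·z² + b3(g)·z³
    + β_sex·female + β_age·age_z + β_edu·edu_z
    + β_mod·age_z·z + ε,   ε ~ N(0, noise_sd²)
```

Defaults plant the published per-group curves — carrier
(−0.253, 0.133, −0.017), non-carrier (−0.145, 0.052, 0) — a genotype
main effect of 0.026, an age×trauma moderation of +0.032 (the trauma
penalty weakens with age), small covariate main effects
(−0.05, 0.05, 0.05), and `noise_sd = 1`. The non-carrier cubic
coefficient defaults to exactly 0 because the substantive model for
that group is quadratic (the corresponding published estimate is
non-significant). Coefficient convention: planted values act as *raw*
coefficients on (z, z², z³) with unit-variance noise, and the composed
outcome is emitted as-is. It is approximately standardized by
construction (SD ≈ 1.05) but deliberately not re-scaled: re-scaling
would shrink every planted coefficient by 1/SD(y) and make them
unrecoverable at their stated values. `read_pheno` offers a z-scoring
flag for external phenotype files.

Demographics are calibrated to the cohort the pipeline targets: 56.3%
women; age ~ N(28.17, 7.08²) truncated to [18, 65]; education ordinal
1–4 with probabilities (0.059, 0.109, 0.587, 0.245).

**What the generator does not emulate.** No linkage disequilibrium
(SNPs are independent), no population structure or ancestry gradients,
no X chromosome or sex-specific genetics, no imputation dosages, no
genotyping batch effects, no item-level measurement model beyond the
single factor, and no missingness in phenotypes. Passing tests
therefore demonstrate correctness of the estimators and calibration
under clean assumptions, not robustness to stratification, LD or
informative missingness.

## Quality control

Order of operations (the attribution order is a declared choice; for
the per-SNP filters the surviving set is order-independent):

1. sample missingness > 0.05;
2. heterozygosity-based inbreeding |F| > 0.2, with
   F = 1 − O_het/E_het and E_het = Σ 2p_j(1−p_j) over the sample's
   non-missing SNPs, p_j estimated from the sample itself;
3. relatedness: pairwise robust kinship
   φ = (N_het,het − 2·N_opposite_hom)/(N_het(i)+N_het(j)) over
   pairwise-complete SNPs (pairs with < 100 complete SNPs skipped),
   degree called at powers-of-two cuts (> 0.354 duplicate/MZ,
   (0.177, 0.354] first degree, (0.0884, 0.177] second degree), and a
   greedy prune (drop the sample in the most flagged pairs, ties to the
   lexicographically smaller id) through second degree;
4. SNP missingness > 0.02; 5. MAF < 0.01; 6. exact HWE p < 1e-5.

The HWE test is the exact conditional two-sided test by
probability-mass ordering (no mid-p correction): p = Σ of probabilities
of all heterozygote counts, given the allele counts, whose conditional
probability is ≤ that of the observed count. The distribution is built
from the log-space ratio recurrence
P(h+2)/P(h) = 4·hom_rare·hom_common/((h+1)(h+2)) normalised by
log-sum-exp; a relative tie tolerance of 1e-10 guards float ties in the
mass ordering. Monomorphic sites return p = 1 by convention.

A practical note on kinship: the estimator's sampling SD scales like
1/√m over m SNPs, so with only a few hundred SNPs the second-degree cut
(0.0884) sits within a few SDs of zero and unrelated pairs are flagged
at an appreciable rate across many pairs. Meaningful relatedness
pruning needs a few thousand informative SNPs, as the estimator's
originators assume.

## Interaction scan

Default scan: within each stratum, simple OLS of the (already
z-scored) outcome on allele dosage, complete cases per SNP, classical
analytic SE; no covariates (a covariate-adjusted variant is available
behind a flag as a declared extension). Strata come from quantile
dichotomization with inclusive ties: the lower cut is the smallest
score whose CDF reaches q, the upper cut the largest score whose
survival function reaches q; realized tail fractions may exceed q.
Sign convention: Z = case slope − control slope; p-values are standard
normal (asymptotic), two-sided. SNPs with < 3 called samples or zero
dosage variance in a stratum are reported as not-testable (NaN
statistics) rather than dropped. λ = median(Z²)/0.454936…; with 10,000
SNPs the sampling SD of λ is ≈ 0.023, so single-scan λ values
routinely land a few percent from 1 even for a perfectly calibrated
scan — the test suite checks mean Z² and tail rates alongside.

## Polynomial cascade

The trauma score is standardized on the analysis sample and then
powered (standardize-then-power): this keeps the generator's
coefficient convention self-consistent and reduces collinearity
relative to powering the raw score. Covariates: female indicator, age
and education z-scored; education is coded ordinally 1–4. All four
designs (degree 1–4) are fitted on the complete cases of the quartic
design so nested comparisons share one sample. Incremental F tests use
the classical RSS form with the larger model's residual df. AIC is
computed from the Gaussian log-likelihood with k counting the
intercept, slopes and the error variance (aic = 2k − 2logL; this is
the usual statsmodels value plus 2). The selected degree is the
smallest whose AIC lies within 2 units of the minimum — the standard
"models within ~2 AIC units are equivalent; prefer the simpler"
parsimony convention. A strict argmin would pick a spuriously improved
higher degree whenever the likelihood-ratio statistic of a truly null
term exceeds 2 (probability ≈ 0.16 per extra degree), which is why the
margin matters for stable selection. α = 0.05 two-sided throughout; no
multiplicity correction inside the cascade.

Demographic moderation adds, one moderator at a time, the moderator ×
each power of z to the selected model and reports every interaction
with CI and p; constant moderators raise an explicit error.

## Candidate-SNP model

Genotype coding defaults to dominant carrier (≥ 1 copy of the counted
allele), centered before interactions are formed; additive coding is
available for cross-checks against the scan. Covariate-interaction
screening adds each covariate×G and covariate×z product alone to the
full G×E model and retains those significant at α = 0.05. The final
model is one OLS with {G, z, z², z³, G×z, G×z², G×z³, covariates,
retained products}. Because G is centered, the G×zᵏ coefficients equal
the carrier-minus-non-carrier coefficient differences regardless of
carrier frequency.

Simple slopes refit the cubic independently per genotype group with the
trauma mean/SD fixed at the full-analysis-sample values, so both group
curves (and their turning points) live on one z axis; the same shared
scale is reused inside split halves. Turning points are the real roots
of the fitted curve's first derivative (quadratic formula), classified
by the second-derivative sign and mapped to raw trauma units via the
shared mean/SD; roots outside the observed z range are flagged. When a
group's cubic term is not significant, its turning point is taken from
a dedicated quadratic refit of that group (treating the curve as a
U-shape) rather than from the noisier quadratic part of the cubic fit.

Split-half cross-validation draws a seeded 50/50 split stratified by
genotype group and re-runs the per-group analysis in each half. The
qualitative pattern is operationalized as: non-carrier U-shape
(quadratic coefficient > 0 and cubic not significant) and carrier cubic
decline (cubic coefficient < 0 and significant); the replication flag
requires the pattern in both halves. Since the non-carrier cubic is a
true null tested at α = 0.05 independently per half, the flag's rate is
bounded above by 0.95² ≈ 0.90 even at infinite power, and at the
default effect sizes the carrier cubic t is ≈ 3 in the full sample
(≈ 2.2 per half), so the replication rate at defaults is modest
(≈ 0.2–0.3 across seeds, as the acceptance script's
`split_half_replication_rate` measures). This mirrors a real property
of split-half designs on borderline-powered cubic terms and is a known
limitation of the default conditions, not of the estimator.

## Problem sizes and runtime choices

Recovery checks run at the study size n = 14,675 with a single
simulated locus; scan calibration uses 10,000 null SNPs × 5,000
samples; oracle-equivalence sweeps cover every HWE count triple with
n ≤ 500, 1,000 random polynomials for the turning-point solver, and
100 random matrices for format round trips. Rates (degree selection,
significance patterns, replication) are estimated over 50 fixed seeds;
kinship simulations use 2,000–5,000 SNPs so the estimator's sampling
noise is small against the degree cuts. The full pipeline demo
(simulate → QC → scan → cascade → candidate) runs in seconds at
n = 1,500 × 150 SNPs and under a minute at n = 5,000 × 2,000 SNPs on
one CPU.

## Known limitations

- The scan's normal p-values are asymptotic; at stratum sizes below a
  few hundred, or MAF low enough that a stratum holds only a handful of
  minor-allele carriers, exact or permutation inference would be more
  appropriate.
- Greedy relatedness pruning is not guaranteed minimal on adversarial
  kinship graphs (it is optimal on the structures simulated here).
- QC is not idempotent in the strict sense on pathological inputs:
  allele frequencies and HWE are recomputed on the surviving samples,
  so a second pass can remove additional SNPs when the first pass
  removed many samples (on clean cohorts a second pass is a no-op, as
  tested).
- The candidate model assumes homoscedastic Gaussian errors; robust or
  quantile variants are out of scope.
- Raw-unit turning points depend on the cohort's trauma mean/SD and are
  therefore generator-calibration-dependent; only z-scale locations are
  checked against planted truth.
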