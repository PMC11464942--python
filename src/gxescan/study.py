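"""Planted study configurations used for end-to-end validation.

Each factory returns a :class:`SimulationConfig` whose generative truth
is one of the published effect structures the analysis is expected to
recover:

* ``full_sample_config`` — one shared cubic trauma curve
  (b1, b2, b3) = (-0.20, +0.24, -0.12) with no genotype effect, for the
  polynomial-cascade recovery check;
* ``interaction_config`` — genotype main effect 0.026 with carrier
  minus non-carrier coefficient deltas (+0.056, -0.040, +0.006), for
  the joint G x E model recovery check;
* ``simple_slope_config`` — the per-group printed curves (carrier
  cubic (-0.253, 0.133, -0.017); non-carrier quadratic
  (-0.145, 0.052)), i.e. the generator defaults;
* ``null_scan_config`` — a shared curve and no genotype dependence,
  for scan calibration (type-I error and genomic lambda).
"""

from __future__ import annotations

from .simulate import GROUP_CARRIER, GROUP_NONCARRIER, SimulationConfig

STUDY_N = 14_675

FULL_SAMPLE_CUBIC = (-0.20, 0.24, -0.12)
GENOTYPE_MAIN_EFFECT = 0.026
INTERACTION_DELTAS = (0.056, -0.040, 0.006)
CARRIER_CURVE = (-0.253, 0.133, -0.017)
NONCARRIER_CURVE = (-0.145, 0.052, 0.0)
AGE_MODERATION = 0.032


def full_sample_config(seed: int, n_samples: int = STUDY_N) -> SimulationConfig:
    return SimulationConfig(
        n_samples=n_samples,
        n_snps=1,
        seed=seed,
        missing_rate=0.0,
        genotype_main_effect=0.0,
        group_coefficients={
            GROUP_NONCARRIER: FULL_SAMPLE_CUBIC,
            GROUP_CARRIER: FULL_SAMPLE_CUBIC,
        },
    )


def interaction_config(seed: int, n_samples: int = STUDY_N) -> SimulationConfig:
    carrier = tuple(b + d for b, d in zip(NONCARRIER_CURVE, INTERACTION_DELTAS))
    return SimulationConfig(
        n_samples=n_samples,
        n_snps=1,
        seed=seed,
        missing_rate=0.0,
        genotype_main_effect=GENOTYPE_MAIN_EFFECT,
        group_coefficients={
            GROUP_NONCARRIER: NONCARRIER_CURVE,
            GROUP_CARRIER: carrier,
        },
    )


def simple_slope_config(seed: int, n_samples: int = STUDY_N) -> SimulationConfig:
    return SimulationConfig(n_samples=n_samples, n_snps=1, seed=seed, missing_rate=0.0)


def null_scan_config(
    seed: int, n_samples: int = 5_000, n_snps: int = 10_000
) -> SimulationConfig:
    return SimulationConfig(
        n_samples=n_samples,
        n_snps=n_snps,
        seed=seed,
        missing_rate=0.0,
        maf_range=(0.05, 0.5),
        genotype_main_effect=0.0,
        group_coefficients={
            GROUP_NONCARRIER: FULL_SAMPLE_CUBIC,
            GROUP_CARRIER: FULL_SAMPLE_CUBIC,
        },
    )
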