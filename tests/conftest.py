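import numpy as np
import pandas as pd
import pytest

from gxescan import SimulationConfig, simulate_cohort
from gxescan.core import GenotypeMatrix, SNP_META_COLUMNS


def make_matrix(calls, chrom=None, pos=None, ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw call array with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": pos if pos is not None else 1000 * (1 + np.arange(m)),
            "snp_id": ids if ids is not None else [f"snp{j}" for j in range(m)],
            "a1": "A",
            "a2": "G",
        },
        columns=SNP_META_COLUMNS,
    )
    return GenotypeMatrix(calls, meta, [f"s{i}" for i in range(n)])


def random_matrix(rng, n, m, missing_rate=0.1) -> GenotypeMatrix:
    calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    calls[rng.random((n, m)) < missing_rate] = -1
    return make_matrix(calls)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared by read-only tests (n=4000)."""
    cfg = SimulationConfig(n_samples=4000, n_snps=30, seed=424, missing_rate=0.0)
    gm, cohort = simulate_cohort(cfg)
    return cfg, gm, cohort
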