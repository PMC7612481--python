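import numpy as np
import pandas as pd
import pytest

from transprs import synthetic as syn
from transprs.io_formats import CohortTable, GenotypeMatrix, SummaryStats, WeightSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario():
    """Small two-ancestry study with known ground truth (shared across tests)."""
    return syn.two_ancestry_scenario(
        m=60, n_causal=8, fst=0.08, block_size=10, rho=0.35,
        n_gwas=30000, n_panel=300, seed=7,
    )


def make_weightset(m=5, label="PRS_test", seed=0, start=1_000_000, spacing=20_000):
    """Deterministic small weight set on unambiguous alleles."""
    rng = np.random.default_rng(seed)
    vt = syn.variant_table(m, start=start, spacing=spacing)
    vt["weight"] = rng.normal(0, 0.1, m)
    vt["eaf"] = rng.uniform(0.1, 0.9, m)
    return WeightSet(vt, label=label)


@pytest.fixture
def weightset():
    return make_weightset()


def make_sumstats(m=6, seed=0, pvals=None, positions=None, chrom="1"):
    rng = np.random.default_rng(seed)
    vt = syn.variant_table(m, chrom=chrom)
    if positions is not None:
        vt["pos"] = positions
    vt["eaf"] = rng.uniform(0.1, 0.9, m)
    vt["beta"] = rng.normal(0, 0.1, m)
    vt["se"] = rng.uniform(0.01, 0.05, m)
    vt["pval"] = pvals if pvals is not None else rng.uniform(1e-10, 1e-2, m)
    vt["info"] = 1.0
    vt["n"] = 10000
    return SummaryStats(vt)


@pytest.fixture
def binary_cohort(rng):
    """Simple balanced case/control cohort with two strata and 10 PCs."""
    n = 400
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "case": rng.integers(0, 2, n),
            "stratum": ["a" if i % 2 else "b" for i in range(n)],
        }
    )
    for k in range(1, 11):
        df[f"pc{k}"] = rng.standard_normal(n)
    return CohortTable(df)
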