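import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import stats

from popqtl.simulate import (
    SimulationConfig,
    default_genome_map,
    simulate_expression,
    simulate_genotypes,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_genome_map():
    return default_genome_map(
        n_snps=60, n_differentiated=2, planted_gene_offsets=(30_000, 250_000)
    )


@pytest.fixture(scope="session")
def small_config():
    """Compact cohort: 3 x 200 samples, 60 SNPs, 2 ancestry-enriched."""
    return SimulationConfig(
        n_snps=60,
        n_differentiated=2,
        samples_per_population=200,
        genome_map=small_genome_map(),
        low_r2_fraction=0.0,  # the r2 screen is exercised in its own tests
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    gm, panel, truth = simulate_genotypes(small_config)
    em = simulate_expression(gm, small_config)
    return gm, panel, truth, em


def batch_ols(x: np.ndarray, y: np.ndarray):
    """Row-wise simple OLS of y on x with intercept (vectorized).

    Returns (beta, p) arrays — an independent closed-form route used to
    generate large batches of regression p-values quickly in tests.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc**2).sum(axis=1)
    beta = (xc * yc).sum(axis=1) / sxx
    n = x.shape[1]
    rss = (yc**2).sum(axis=1) - beta**2 * sxx
    df = n - 2
    se = np.sqrt(np.maximum(rss, 0) / df / sxx)
    with np.errstate(divide="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, p


@pytest.fixture(scope="session")
def ols_batch():
    return batch_ols
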