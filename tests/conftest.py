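import numpy as np
import pytest

from bnkqtl.estimation import EMConfig

# cheap optimizer settings for tests that exercise pipeline mechanics rather
# than optimizer thoroughness; kernels and observed statistics always share
# one config, so calibration is preserved
FAST_EM = EMConfig(n_restarts=5, stage1_iters=15, n_keep=2, max_iter=80,
                   tol=1e-7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170)


@pytest.fixture(scope="session")
def null_dataset():
    """One null dataset: standard-normal phenotype, independent HWE marker."""
    r = np.random.default_rng(42)
    Y = r.normal(0.0, 1.0, 400)
    M = r.binomial(2, 0.5, 400)
    return Y, M


@pytest.fixture(scope="session")
def bivariate_cloud():
    """Correlated bivariate-normal points standing in for null statistic pairs."""
    r = np.random.default_rng(7)
    cov = np.array([[1.0, 0.5], [0.5, 2.0]])
    return r.multivariate_normal([1.0, 2.0], cov, size=800)
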