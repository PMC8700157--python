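import numpy as np
import pytest

from proxjgl import (
    CovarianceSet,
    MultiClassDataset,
    PrecisionSet,
    compute_class_covariances,
)


def random_pd_stack(K, p, rng, scale=1.0):
    """Random symmetric positive-definite (K, p, p) stack."""
    mats = np.empty((K, p, p))
    for k in range(K):
        a = rng.normal(size=(p, p))
        mats[k] = scale * (a @ a.T / p + np.eye(p))
    return mats


def random_cov_set(K, p, n_k, rng):
    """Empirical covariances of Gaussian draws (guaranteed PSD, PD if n_k > p)."""
    data = [rng.normal(size=(n, p)) for n in ([n_k] * K if np.isscalar(n_k) else n_k)]
    return compute_class_covariances(MultiClassDataset(data), center=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


@pytest.fixture
def small_cov(rng):
    """K=2, p=6 covariance set from 40 Gaussian samples per class."""
    return random_cov_set(2, 6, 40, rng)


@pytest.fixture
def pd_pair(rng):
    """A PrecisionSet / CovarianceSet pair with K=2, p=5."""
    theta = PrecisionSet(random_pd_stack(2, 5, rng))
    cov = CovarianceSet(random_pd_stack(2, 5, rng, scale=0.5), [12.0, 20.0])
    return theta, cov
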