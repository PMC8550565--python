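import numpy as np
import pytest

from dvmetric.data import LabeledDataset


def brute_force_mi(x, y, base="nats"):
    """Independent oracle: direct double sum of the discrete MI definition
    over the empirical joint table."""
    from collections import Counter

    x = [tuple(v) if isinstance(v, (list, np.ndarray)) else v for v in x]
    y = [tuple(v) if isinstance(v, (list, np.ndarray)) else v for v in y]
    n = len(x)
    pxy = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (xv, yv), c in pxy.items():
        pj = c / n
        total += pj * np.log(pj / ((px[xv] / n) * (py[yv] / n)))
    if base == "bits":
        total /= np.log(2.0)
    return total


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gaussian_pair():
    """Bivariate Gaussian sample with rho = 0.9; closed-form MI
    -0.5 * ln(1 - rho^2) = 0.830366 nats."""
    r = np.random.default_rng(7)
    rho = 0.9
    xy = r.multivariate_normal([0.0, 0.0], [[1, rho], [rho, 1]], size=5000)
    return xy[:, 0], xy[:, 1], -0.5 * np.log(1 - rho**2)


@pytest.fixture()
def discrete_dataset():
    """Small dataset whose label is a deterministic function of a
    3-valued discrete feature."""
    r = np.random.default_rng(3)
    x = r.integers(0, 3, 400).astype(float).reshape(-1, 1)
    return LabeledDataset(x, x[:, 0].astype(int))
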