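"""Seeded synthetic data generators for the validation experiments.

Three protocols are provided:

* Gaussian blob classification data: five isotropic clusters in 800
  dimensions with cluster standard deviation 20 (strong signal) or 40
  (weak signal).  Centers are drawn uniformly in the conventional
  (-10, 10) box, so each individual feature is only weakly informative
  and the class signal emerges from aggregating many features — the
  regime where classifier accuracy grows visibly with sample size.
* Cube-root regression data: rows drawn from a diagonal multivariate
  Gaussian whose mean entries are N(0, 25) and whose eigenvalues are
  Uniform(2, 12); the continuous target is the signed cube root of the
  row mean plus K * standard-normal noise (K = 10 strong, K = 50 weak).
* Cluster-square feature-selection data: four Gaussian clusters at the
  corners of a unit square living in 2 of d = 20 coordinates (placed at
  seeded random column positions); the other coordinates are pure
  standard-normal noise.

All generators are deterministic given their seed and record their full
configuration in ``LabeledDataset.meta``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.datasets import make_blobs

from .data import CATEGORICAL, CONTINUOUS, LabeledDataset
from .exceptions import ConfigError

__all__ = [
    "BlobConfig",
    "CubeRootConfig",
    "ClusterSquareConfig",
    "make_blobs_dataset",
    "make_cuberoot_dataset",
    "make_cluster_square_dataset",
]


@dataclass
class BlobConfig:
    """Isotropic Gaussian blob classification data."""

    n: int = 2000
    p: int = 800
    centers: int = 5
    cluster_std: float = 20.0
    center_box: tuple = (-10.0, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n < self.centers:
            raise ConfigError("need n >= centers")
        if self.cluster_std <= 0:
            raise ConfigError("cluster_std must be positive")


def make_blobs_dataset(cfg: BlobConfig | None = None, **kw) -> LabeledDataset:
    """Gaussian blobs around randomly placed centers; labels = blob id."""
    cfg = cfg or BlobConfig(**kw)
    X, y = make_blobs(n_samples=cfg.n, n_features=cfg.p, centers=cfg.centers,
                      cluster_std=cfg.cluster_std,
                      center_box=tuple(cfg.center_box),
                      random_state=np.random.RandomState(
                          np.random.SeedSequence(cfg.seed).generate_state(1)))
    return LabeledDataset(X, y.astype(int), None, CATEGORICAL,
                          meta={"generator": "blobs", **asdict(cfg)})


@dataclass
class CubeRootConfig:
    """Cube-root regression data with Gaussian features."""

    n: int = 2000
    p: int = 800
    K: float = 10.0
    mean_prior_var: float = 25.0
    eigenvalue_range: tuple = (2.0, 12.0)
    seed: int = 0

    def __post_init__(self):
        if self.K <= 0:
            raise ConfigError("K must be positive")
        lo, hi = self.eigenvalue_range
        if not (0 < lo < hi):
            raise ConfigError("eigenvalue_range must be positive and ordered")


def signed_cube_root(u: np.ndarray) -> np.ndarray:
    """Real cube root: sign(u) * |u|^(1/3)."""
    return np.sign(u) * np.abs(u) ** (1.0 / 3.0)


def make_cuberoot_dataset(cfg: CubeRootConfig | None = None, *,
                          signal_fn=None, **kw) -> LabeledDataset:
    """Continuous-label data: Y_i = s(mean_j X_ij) + K * eps_i.

    ``signal_fn`` replaces the default signed-cube-root-of-row-mean
    aggregation; it maps the n x p feature matrix to a length-n signal.
    """
    cfg = cfg or CubeRootConfig(**kw)
    rng = np.random.default_rng(cfg.seed)
    mean = rng.normal(0.0, np.sqrt(cfg.mean_prior_var), size=cfg.p)
    eig = rng.uniform(*cfg.eigenvalue_range, size=cfg.p)
    X = mean + rng.standard_normal((cfg.n, cfg.p)) * np.sqrt(eig)
    if signal_fn is None:
        signal = signed_cube_root(X.mean(axis=1))
    else:
        signal = np.asarray(signal_fn(X), dtype=float)
    y = signal + cfg.K * rng.standard_normal(cfg.n)
    ds = LabeledDataset(X, y, None, CONTINUOUS,
                        meta={"generator": "cuberoot", **asdict(cfg)})
    ds.meta["noiseless_signal"] = signal
    return ds


@dataclass
class ClusterSquareConfig:
    """Four clusters on a unit square inside a higher-dimensional space."""

    n: int = 1000
    d: int = 20
    n_clusters: int = 4
    square_edge: float = 1.0
    cluster_std: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.d < 2:
            raise ConfigError("need d >= 2")
        if self.n_clusters != 4:
            raise ConfigError("the square layout defines exactly 4 clusters")
        if self.cluster_std <= 0 or self.square_edge <= 0:
            raise ConfigError("cluster_std and square_edge must be positive")


def make_cluster_square_dataset(cfg: ClusterSquareConfig | None = None,
                                **kw) -> LabeledDataset:
    """4 Gaussian clusters at unit-square corners in 2 of d coordinates.

    Samples are split as evenly as possible across clusters (the first
    ``n % 4`` clusters receive one extra sample).  The two informative
    coordinates sit at seeded random positions among the d columns; the
    remaining columns are independent standard normal noise.
    """
    cfg = cfg or ClusterSquareConfig(**kw)
    rng = np.random.default_rng(cfg.seed)
    e = cfg.square_edge
    corners = np.array([[0, 0], [0, e], [e, 0], [e, e]], dtype=float)
    counts = [cfg.n // 4 + (1 if i < cfg.n % 4 else 0) for i in range(4)]
    labels = np.repeat(np.arange(4), counts)
    informative = corners[labels] + cfg.cluster_std * rng.standard_normal(
        (cfg.n, 2))
    X = rng.standard_normal((cfg.n, cfg.d))
    cols = rng.choice(cfg.d, size=2, replace=False)
    X[:, cols] = informative
    perm = rng.permutation(cfg.n)
    ds = LabeledDataset(X[perm], labels[perm].astype(int), None, CATEGORICAL,
                        meta={"generator": "cluster_square", **asdict(cfg)})
    ds.meta["informative_columns"] = [int(c) for c in cols]
    return ds
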