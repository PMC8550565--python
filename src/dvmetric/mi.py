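"""Mutual information and conditional mutual information estimators.

Three estimators are provided:

``plugin``
    Exact empirical (plug-in) MI on discrete samples: the double sum of
    ``p(x,y) log[p(x,y) / (p(x) p(y))]`` over the observed joint table.
``knn``
    The Kraskov–Stögbauer–Grassberger (KSG) k-nearest-neighbour estimator
    for continuous samples, built on Chebyshev-metric kd-trees.
``hash_ensemble``
    A hash/binning ensemble for mixed or high-dimensional data: at each
    of several resolutions, continuous coordinates are (optionally
    random-projected and) quantile-binned, categorical coordinates are kept
    as-is, the plug-in MI of the quantized table is bias-corrected
    (Miller–Madow), and the per-resolution estimates are combined by a
    weighting rule.  On purely discrete inputs quantization is the
    identity, so the ensemble reduces exactly to the plug-in estimate.

All values are computed in nats internally; ``MIEstimate.in_bits()``
converts.  Raw estimates can be slightly negative for the kNN and ensemble
estimators; they are clipped at zero because mutual information is
nonnegative.

Conditional MI is always computed through the chain rule
``I(X;Y|Z) = I(X;(Y,Z)) - I(X;Z)`` rather than with a dedicated estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .exceptions import (
    ConfigError,
    InputError,
    PairedSampleError,
    ParameterError,
)

__all__ = [
    "SampleVector",
    "MIEstimate",
    "EnsembleConfig",
    "as_sample_vector",
    "estimate_mi_plugin",
    "estimate_mi_knn",
    "estimate_mi_hash_ensemble",
    "estimate_mi",
    "estimate_cmi",
]

_LN2 = float(np.log(2.0))

DISCRETE = "discrete"
CONTINUOUS = "continuous"
MIXED = "mixed"


# ---------------------------------------------------------------------------
# containers


@dataclass
class SampleVector:
    """An ordered collection of paired per-sample observations.

    Parameters
    ----------
    values : ndarray, shape (n,) or (n, d)
        One observation per row; scalars or fixed-arity tuples.
    kind : {"discrete", "continuous", "mixed"}
    col_kinds : tuple of str, optional
        Per-column kinds; required only for ``kind="mixed"``.
    """

    values: np.ndarray
    kind: str
    col_kinds: tuple = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise InputError("SampleVector values must be 1- or 2-dimensional")
        if self.n == 0:
            raise InputError("SampleVector is empty (n = 0)")
        if self.kind not in (DISCRETE, CONTINUOUS, MIXED):
            raise InputError(f"unknown sample kind {self.kind!r}")
        if self.col_kinds is None:
            self.col_kinds = tuple([self.kind] * self.d)
        if len(self.col_kinds) != self.d:
            raise InputError("col_kinds arity does not match values")
        if self.kind == CONTINUOUS:
            arr = self.values.astype(float)
            if not np.all(np.isfinite(arr)):
                raise InputError("continuous sample contains non-finite values")
            self.values = arr

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def as_sample_vector(values, kind: str | None = None) -> SampleVector:
    """Coerce an array(-like) to a :class:`SampleVector`.

    If ``kind`` is omitted it is inferred from the dtype: integer, boolean
    and object/string arrays are treated as discrete, floating arrays as
    continuous.
    """
    if isinstance(values, SampleVector):
        return values
    arr = np.asarray(values)
    if kind is None:
        if arr.dtype.kind in "iub" or arr.dtype.kind in "OSU":
            kind = DISCRETE
        else:
            kind = CONTINUOUS
    return SampleVector(arr, kind)


@dataclass(frozen=True)
class MIEstimate:
    """A nonnegative mutual-information estimate with provenance.

    ``value`` is in the log base named by ``base`` ("nats" by default).
    """

    value: float
    estimator_id: str
    params: dict = field(default_factory=dict)
    n_used: int = 0
    base: str = "nats"

    def in_bits(self) -> "MIEstimate":
        if self.base == "bits":
            return self
        return MIEstimate(self.value / _LN2, self.estimator_id, self.params,
                          self.n_used, "bits")

    def in_nats(self) -> "MIEstimate":
        if self.base == "nats":
            return self
        return MIEstimate(self.value * _LN2, self.estimator_id, self.params,
                          self.n_used, "nats")

    def __float__(self) -> float:
        return float(self.value)


# ---------------------------------------------------------------------------
# helpers


def _check_paired(*vectors: SampleVector) -> int:
    lengths = {v.n for v in vectors}
    if len(lengths) != 1:
        raise PairedSampleError(
            f"sample vectors must be paired; got lengths {sorted(lengths)}")
    return lengths.pop()


def _row_codes(values: np.ndarray) -> np.ndarray:
    """Factorize rows of a 2-d array into integer codes 0..K-1."""
    if values.shape[1] == 1:
        codes, _ = pd.factorize(values[:, 0])
        return codes.astype(np.int64)
    if values.dtype.kind in "OSU":
        keys = pd.Series(map(tuple, values))
        codes, _ = pd.factorize(keys)
        return codes.astype(np.int64)
    _, codes = np.unique(values, axis=0, return_inverse=True)
    return codes.astype(np.int64).ravel()


def _pair_codes(cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    return cx.astype(np.int64) * (int(cy.max()) + 1) + cy.astype(np.int64)


def _plugin_mi_from_codes(cx: np.ndarray, cy: np.ndarray,
                          bias_correction: bool = False) -> float:
    """Plug-in MI (nats) between two integer code vectors.

    With ``bias_correction`` the Miller–Madow correction
    ``(K_xy - K_x - K_y + 1) / (2n)`` is subtracted, where the K's count
    occupied cells.
    """
    n = cx.shape[0]
    kx = int(cx.max()) + 1
    ky = int(cy.max()) + 1
    nxy = np.bincount(cx.astype(np.int64) * ky + cy,
                      minlength=kx * ky).astype(float)
    nx = np.bincount(cx, minlength=kx).astype(float)
    ny = np.bincount(cy, minlength=ky).astype(float)
    mask = nxy > 0
    prod = np.multiply.outer(nx, ny).ravel()[mask]
    terms = nxy[mask] / n * np.log(n * nxy[mask] / prod)
    # summing in sorted order makes the result invariant to argument swap
    value = float(np.sum(np.sort(terms)))
    if bias_correction:
        value -= (int(mask.sum()) - int((nx > 0).sum())
                  - int((ny > 0).sum()) + 1) / (2.0 * n)
    return value


# ---------------------------------------------------------------------------
# plug-in estimator


def estimate_mi_plugin(x, y, *, base: str = "nats") -> MIEstimate:
    """Plug-in mutual information between two discrete sample vectors.

    Deterministic; exact empirical MI over the observed joint table.
    """
    xv = as_sample_vector(x)
    yv = as_sample_vector(y)
    for v, name in ((xv, "x"), (yv, "y")):
        if v.kind != DISCRETE:
            raise InputError(
                f"plug-in estimator requires discrete samples; {name} is "
                f"{v.kind}")
    n = _check_paired(xv, yv)
    value = _plugin_mi_from_codes(_row_codes(xv.values), _row_codes(yv.values))
    value = max(value, 0.0)
    est = MIEstimate(value, "plugin", {}, n, "nats")
    return est.in_bits() if base == "bits" else est


# ---------------------------------------------------------------------------
# KSG k-nearest-neighbour estimator


def estimate_mi_knn(x, y, k: int = 5, *, seed: int = 0,
                    base: str = "nats") -> MIEstimate:
    """KSG (algorithm 1) kNN mutual information for continuous samples.

    Duplicate points are broken by an infinitesimal deterministic jitter
    derived from ``seed`` so that nearest-neighbour ranks are well defined
    and the estimate is reproducible.
    """
    xv = as_sample_vector(x)
    yv = as_sample_vector(y)
    for v, name in ((xv, "x"), (yv, "y")):
        if v.kind != CONTINUOUS:
            raise InputError(
                f"kNN estimator requires continuous samples; {name} is "
                f"{v.kind}")
    n = _check_paired(xv, yv)
    if not (1 <= k < n):
        raise ParameterError(f"k must satisfy 1 <= k < n; got k={k}, n={n}")

    rng = np.random.default_rng(seed)
    X = xv.values.copy()
    Y = yv.values.copy()
    for arr in (X, Y):
        scale = np.maximum(np.std(arr, axis=0), 1.0)
        arr += 1e-10 * scale * rng.standard_normal(arr.shape)

    Z = np.hstack([X, Y])
    tree_z = cKDTree(Z)
    dist, _ = tree_z.query(Z, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # strictly-inside counts: shrink radius to just below the kth distance
    radius = np.nextafter(eps, 0.0)
    nx = cKDTree(X).query_ball_point(X, radius, p=np.inf,
                                     return_length=True) - 1
    ny = cKDTree(Y).query_ball_point(Y, radius, p=np.inf,
                                     return_length=True) - 1
    value = (digamma(k) + digamma(n)
             - float(np.mean(digamma(nx + 1) + digamma(ny + 1))))
    value = max(value, 0.0)
    est = MIEstimate(value, "knn", {"k": k, "seed": seed}, n, "nats")
    return est.in_bits() if base == "bits" else est


# ---------------------------------------------------------------------------
# hash / binning ensemble estimator


@dataclass
class EnsembleConfig:
    """Configuration of the hash/binning ensemble estimator.

    Parameters
    ----------
    resolutions : strictly increasing list of >= 2 binning resolutions.
        A resolution ``r`` means "about r distinguishable levels per
        variable": a univariate continuous coordinate gets r quantile
        bins; a d-dimensional block gets ``max(2, round(r**(2/(d+1))))``
        bins per coordinate so the number of occupied cells stays
        comparable across dimensions.
    projection_dim : dimension that high-dimensional continuous blocks are
        reduced to before binning.
    max_direct_dim : continuous blocks with at most this many columns are
        binned directly on their raw coordinates (the standard epsilon-grid
        regime); only blocks beyond it are reduced to ``projection_dim``.
    projection : {"pca", "random"}
        Reduction used for high-dimensional continuous blocks.  PCA (the
        default) is variance-preserving and keeps low-dimensional cluster
        or regression structure visible to the binning stage; a seeded
        Gaussian random projection is available as a cheaper alternative
        but dilutes structure confined to a small subspace.
    weighting : "uniform" or an explicit sequence of weights summing to 1.
    seed : base seed for projections and hashing.
    bias_correction : subtract the Miller–Madow plug-in bias estimate at
        each resolution.
    discrete_bias_correction : also Miller–Madow-correct the purely
        discrete (identity-quantization) path.  Off by default so that
        discrete inputs reproduce the plug-in estimate exactly; the
        fidelity computation switches it on so numerator and denominator
        are corrected consistently.
    """

    resolutions: Sequence[int] = (8, 16, 32)
    projection_dim: int = 5
    max_direct_dim: int = 20
    projection: str = "pca"
    weighting: str | Sequence[float] = "uniform"
    seed: int = 0
    bias_correction: bool = True
    discrete_bias_correction: bool = False

    def __post_init__(self):
        res = [int(r) for r in self.resolutions]
        if len(res) < 2:
            raise ConfigError("EnsembleConfig needs at least 2 resolutions")
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ConfigError("resolutions must be strictly increasing")
        if any(r < 2 for r in res):
            raise ConfigError("resolutions must be >= 2")
        self.resolutions = tuple(res)
        if int(self.projection_dim) < 1:
            raise ConfigError("projection_dim must be positive")
        self.projection_dim = int(self.projection_dim)
        if self.projection not in ("pca", "random"):
            raise ConfigError(f"unknown projection {self.projection!r}")
        self.weights()  # validate the weighting rule eagerly

    def weights(self) -> np.ndarray:
        m = len(self.resolutions)
        if isinstance(self.weighting, str):
            if self.weighting != "uniform":
                raise ConfigError(f"unknown weighting {self.weighting!r}")
            return np.full(m, 1.0 / m)
        w = np.asarray(list(self.weighting), dtype=float)
        if w.shape != (m,) or not np.isclose(w.sum(), 1.0):
            raise ConfigError("explicit weights must match resolutions and "
                              "sum to 1")
        return w


def _quantile_codes(col: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning of one continuous column into <= bins codes."""
    edges = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, col, side="right").astype(np.int64)


def _reduce_block(Xc: np.ndarray, cfg: EnsembleConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Reduce a continuous block to ``projection_dim`` columns if it is
    too wide for direct binning."""
    if Xc.shape[1] <= max(cfg.projection_dim, cfg.max_direct_dim):
        return Xc
    if cfg.projection == "pca":
        from sklearn.decomposition import PCA

        k = min(cfg.projection_dim, Xc.shape[0] - 1)
        return PCA(n_components=k,
                   random_state=int(rng.integers(2**31))).fit_transform(Xc)
    proj = rng.standard_normal((Xc.shape[1], cfg.projection_dim))
    proj /= np.sqrt(Xc.shape[1])
    return Xc @ proj


def _ensemble_codes(cont_block: np.ndarray | None, disc_codes: np.ndarray | None,
                    resolution: int) -> np.ndarray:
    """Quantized integer codes of one sample vector at one resolution."""
    parts = []
    if cont_block is not None:
        d = cont_block.shape[1]
        if d == 1:
            bins = resolution
        else:
            # dyadic quantile partition: the per-coordinate bin count is a
            # power of two chosen so the joint cell count stays comparable
            # across dimensions (~ resolution^2 cells in total)
            k = max(1, int(round(2.0 * np.log2(resolution) / d)))
            bins = 2 ** k
        parts.append(np.column_stack(
            [_quantile_codes(cont_block[:, j], bins) for j in range(d)]))
    if disc_codes is not None:
        parts.append(disc_codes)
    return _row_codes(np.column_stack(parts))


def _split_blocks(sv: SampleVector):
    """Split a sample vector into its continuous block and discrete codes."""
    cont_cols = [j for j, k in enumerate(sv.col_kinds) if k == CONTINUOUS]
    disc_cols = [j for j, k in enumerate(sv.col_kinds) if k != CONTINUOUS]
    cont = sv.values[:, cont_cols].astype(float) if cont_cols else None
    disc = None
    if disc_cols:
        block = sv.values[:, disc_cols]
        disc = np.column_stack(
            [_row_codes(block[:, [j]]) for j in range(block.shape[1])])
    return cont, disc


def estimate_mi_hash_ensemble(x, y, config: EnsembleConfig | None = None, *,
                              base: str = "nats") -> MIEstimate:
    """Hash/binning ensemble MI estimate for samples of any kind.

    Purely discrete inputs pass through unquantized, so the result equals
    the plug-in estimate regardless of configuration.
    """
    if config is None:
        config = EnsembleConfig()
    xv = as_sample_vector(x)
    yv = as_sample_vector(y)
    n = _check_paired(xv, yv)
    weights = config.weights()

    if xv.kind == DISCRETE and yv.kind == DISCRETE:
        value = _plugin_mi_from_codes(
            _row_codes(xv.values), _row_codes(yv.values),
            bias_correction=config.discrete_bias_correction)
        value = max(value, 0.0)
        est = MIEstimate(value, "hash_ensemble",
                         {"resolutions": config.resolutions,
                          "reduced_to": "plugin"}, n, "nats")
        return est.in_bits() if base == "bits" else est

    ss = np.random.SeedSequence(config.seed)
    cont_x, disc_x = _split_blocks(xv)
    cont_y, disc_y = _split_blocks(yv)
    estimates = []
    for resolution, child in zip(config.resolutions,
                                 ss.spawn(len(config.resolutions))):
        rng = np.random.default_rng(child)
        bx = None if cont_x is None else _reduce_block(cont_x, config, rng)
        by = None if cont_y is None else _reduce_block(cont_y, config, rng)
        cx = _ensemble_codes(bx, disc_x, resolution)
        cy = _ensemble_codes(by, disc_y, resolution)
        estimates.append(_plugin_mi_from_codes(
            cx, cy, bias_correction=config.bias_correction))
    value = max(float(np.dot(weights, estimates)), 0.0)
    est = MIEstimate(value, "hash_ensemble",
                     {"resolutions": config.resolutions,
                      "projection_dim": config.projection_dim,
                      "seed": config.seed,
                      "per_resolution": [float(v) for v in estimates]},
                     n, "nats")
    return est.in_bits() if base == "bits" else est


# ---------------------------------------------------------------------------
# dispatch and conditional MI

_ESTIMATORS = ("plugin", "knn", "hash_ensemble")


def estimate_mi(x, y, estimator: str = "hash_ensemble", *,
                base: str = "nats", **params) -> MIEstimate:
    """Dispatch to a named MI estimator ('plugin', 'knn', 'hash_ensemble')."""
    if estimator == "plugin":
        return estimate_mi_plugin(x, y, base=base)
    if estimator == "knn":
        return estimate_mi_knn(x, y, base=base, **params)
    if estimator == "hash_ensemble":
        config = params.pop("config", None)
        if config is None and params:
            config = EnsembleConfig(**params)
        return estimate_mi_hash_ensemble(x, y, config, base=base)
    raise ConfigError(f"unknown estimator id {estimator!r}; "
                      f"expected one of {_ESTIMATORS}")


def _concat_vectors(a: SampleVector, b: SampleVector) -> SampleVector:
    values = np.column_stack([np.asarray(a.values, dtype=object),
                              np.asarray(b.values, dtype=object)])
    col_kinds = tuple(a.col_kinds) + tuple(b.col_kinds)
    kinds = set(col_kinds)
    if kinds == {DISCRETE}:
        kind, values = DISCRETE, values
    elif kinds == {CONTINUOUS}:
        kind = CONTINUOUS
        values = np.column_stack([a.values.astype(float),
                                  b.values.astype(float)])
    else:
        kind = MIXED
    return SampleVector(values, kind, col_kinds)


def estimate_cmi(x, y, z, estimator: str = "hash_ensemble", *,
                 base: str = "nats", **params) -> MIEstimate:
    """Conditional mutual information I(X;Y|Z) via the chain rule.

    Computed as ``I(X;(Y,Z)) - I(X;Z)`` with the named estimator, the pair
    (Y,Z) being the per-sample concatenation; clipped at zero.
    """
    xv, yv, zv = map(as_sample_vector, (x, y, z))
    _check_paired(xv, yv, zv)
    yz = _concat_vectors(yv, zv)
    joint = estimate_mi(xv, yz, estimator, base="nats", **params)
    marginal = estimate_mi(xv, zv, estimator, base="nats", **params)
    value = max(joint.value - marginal.value, 0.0)
    est = MIEstimate(value, f"cmi[{estimator}]",
                     {"chain_rule": True, **joint.params}, xv.n, "nats")
    return est.in_bits() if base == "bits" else est
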