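"""The Data Value Metric: fidelity, regularizer, and their combination.

The DVM of a dataset D under an inference method g is

    DVM(D) = F(D) - lambda * R(D)

where the fidelity F is an information-bottleneck-style ratio and R is the
[0, 1]-normalized training-complexity regularizer.  For supervised tasks
the fidelity is a cross-validation average over M random train/test
splits: on each split g is fitted on the training part, its held-out
representation T~ (predicted labels by default) is compared with the true
held-out labels Y~, and

    F_i = ( I(T~; Y~) - beta * I(X~; T~ | Y~) ) / I(X; Y),

with the denominator estimated once on the full dataset.  For unsupervised
tasks each of the M rounds draws a three-way split (X', X'', X~), fits g
separately on X' and X'', applies both fitted models to the common
held-out part X~ to obtain two paired labelings Y^ and T~, and scores
their agreement the same way, normalized by I(X; Y^_full) where Y^_full is
the clustering of the full dataset.  Cluster-label permutations leave the
score unchanged because mutual information is permutation invariant, so
the unsupervised fidelity measures stability of the clustering, not the
arbitrary label identities.

The user-facing entry point is :class:`DataValueModel` whose ``fit``
returns a :class:`DVMResult`; the module-level functions implement the
individual operations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .complexity import normalized_regularizer
from .data import CATEGORICAL, CONTINUOUS, LabeledDataset
from .exceptions import (
    ConfigError,
    DegenerateLabelError,
    DegenerateSignalError,
)
from .mi import (
    SampleVector,
    as_sample_vector,
    estimate_cmi,
    estimate_mi,
)
from .models import SUPERVISED, UNSUPERVISED, InferenceModel, make_model

__all__ = [
    "FidelityConfig",
    "DVMResult",
    "DataValueModel",
    "fidelity_supervised",
    "fidelity_unsupervised",
    "compute_dvm",
    "ib_score",
    "fidelity_exact",
]


@dataclass
class FidelityConfig:
    """Settings of the fidelity cross-validation average.

    beta : weight of the compression penalty I(X~; T~ | Y~); >= 0.
    n_splits : number M of random splits (>= 2 so a CI exists).
    train_fraction : train share of each supervised split.
    split_fractions : (train', train'', test) shares of each three-way
        unsupervised split; must sum to 1.
    estimator : MI estimator id used throughout ('plugin', 'knn',
        'hash_ensemble').
    estimator_params : extra keyword settings for the estimator.
    mi_floor : positive floor guarding the fidelity denominator (nats).
    """

    beta: float = 0.1
    n_splits: int = 10
    train_fraction: float = 0.7
    split_fractions: tuple = (0.4, 0.4, 0.2)
    estimator: str = "hash_ensemble"
    estimator_params: dict = field(default_factory=dict)
    mi_floor: float = 1e-3

    def __post_init__(self):
        if self.beta < 0:
            raise ConfigError("beta must be >= 0")
        if self.n_splits < 2:
            raise ConfigError("need n_splits >= 2 for a confidence interval")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        fr = tuple(float(f) for f in self.split_fractions)
        if len(fr) != 3 or any(f <= 0 for f in fr) or not np.isclose(
                sum(fr), 1.0):
            raise ConfigError("split_fractions must be 3 positive shares "
                              "summing to 1")
        self.split_fractions = fr
        if self.mi_floor <= 0:
            raise ConfigError("mi_floor must be positive")


def _ci95(values: np.ndarray) -> tuple[float, float]:
    m = len(values)
    mean = float(np.mean(values))
    if m < 2:
        return (mean, mean)
    half = (scipy.stats.t.ppf(0.975, m - 1)
            * float(np.std(values, ddof=1)) / np.sqrt(m))
    return (mean - half, mean + half)


def _estimator_kwargs(cfg: FidelityConfig, seed: int) -> dict:
    params = dict(cfg.estimator_params)
    if cfg.estimator in ("knn", "hash_ensemble"):
        params.setdefault("seed", seed)
    if cfg.estimator == "hash_ensemble":
        # correct the discrete path too, so the fidelity's numerator and
        # denominator carry the same small-sample bias treatment
        params.setdefault("discrete_bias_correction", True)
    return params


def _label_vector(values: np.ndarray, label_kind: str) -> SampleVector:
    kind = "discrete" if label_kind == CATEGORICAL else "continuous"
    return as_sample_vector(np.asarray(values), kind)


def _features_vector(features: np.ndarray, cfg: FidelityConfig
                     ) -> SampleVector:
    # the plug-in estimator treats feature rows as discrete symbols
    kind = "discrete" if cfg.estimator == "plugin" else "continuous"
    return as_sample_vector(features, kind)


def _full_mi(data: LabeledDataset, labels: np.ndarray, label_kind: str,
             cfg: FidelityConfig, seed: int) -> float:
    den = estimate_mi(_features_vector(data.features, cfg),
                      _label_vector(labels, label_kind),
                      cfg.estimator, **_estimator_kwargs(cfg, seed)).value
    if den <= cfg.mi_floor:
        raise DegenerateSignalError(
            f"full-data mutual information {den:.3g} nats is at or below "
            f"the floor {cfg.mi_floor:g}; the fidelity ratio is undefined "
            "for zero-signal data")
    return den


def make_supervised_splits(n: int, labels: np.ndarray | None,
                           label_kind: str, cfg: FidelityConfig,
                           seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """M seeded train/test index pairs (stratified for categorical labels)."""
    from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit

    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    if label_kind == CATEGORICAL and labels is not None:
        splitter = StratifiedShuffleSplit(
            n_splits=cfg.n_splits, train_size=cfg.train_fraction,
            random_state=rs)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n), labels)]
    splitter = ShuffleSplit(n_splits=cfg.n_splits,
                            train_size=cfg.train_fraction, random_state=rs)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n))]


def make_threeway_splits(n: int, cfg: FidelityConfig, seed: int
                         ) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """M seeded three-way partitions (X', X'', X~) of the row indices."""
    f1, f2, _ = cfg.split_fractions
    n1 = max(int(round(f1 * n)), 1)
    n2 = max(int(round(f2 * n)), 1)
    if n1 + n2 >= n:
        raise ConfigError(f"n = {n} leaves an empty held-out part under "
                          f"fractions {cfg.split_fractions}")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(cfg.n_splits):
        perm = rng.permutation(n)
        splits.append((perm[:n1], perm[n1:n1 + n2], perm[n1 + n2:]))
    return splits


def _check_test_coverage(labels, test_idx, label_kind):
    if label_kind == CATEGORICAL:
        _, counts = np.unique(labels[test_idx], return_counts=True)
        if counts.min() < 2:
            raise DegenerateLabelError(
                "a split's test set has fewer than 2 samples of an "
                "observed class; increase n or reduce n_splits")
    elif len(test_idx) < 20:
        raise DegenerateLabelError(
            "continuous-label fidelity needs >= 20 test samples per split")


@dataclass
class _FidelityParts:
    per_split: np.ndarray
    per_split_accuracy: np.ndarray | None
    denominator: float
    splits: list


def fidelity_supervised(data: LabeledDataset, model: InferenceModel,
                        cfg: FidelityConfig, seed: int = 0,
                        splits: Sequence | None = None,
                        compute_mi: bool = True,
                        denominator: float | None = None) -> _FidelityParts:
    """Per-split supervised fidelities (plus held-out accuracies).

    With ``compute_mi=False`` the MI estimation is skipped and only the
    held-out accuracies are produced, on exactly the same splits and model
    seeds as the fidelity computation with the same ``seed``.
    """
    labels = data.require_labels()
    if model.mode != SUPERVISED:
        raise ConfigError("fidelity_supervised needs a supervised model")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 + cfg.n_splits) % (2**31)
    if denominator is not None:
        den = float(denominator)
    else:
        den = (_full_mi(data, labels, data.label_kind, cfg, int(seeds[0]))
               if compute_mi else np.nan)
    if splits is None:
        splits = make_supervised_splits(data.n, labels, data.label_kind,
                                        cfg, int(seeds[1]))
    values, accuracies = [], []
    for i, (train, test) in enumerate(splits):
        _check_test_coverage(labels, test, data.label_kind)
        split_seed = int(seeds[2 + i])
        fitted = model.fit(data.features[train], labels[train],
                           random_state=split_seed,
                           label_kind=data.label_kind)
        t_rep = model.apply(fitted, data.features[test])
        y_test = labels[test]
        if compute_mi:
            est_kw = _estimator_kwargs(cfg, split_seed)
            num = estimate_mi(_label_vector(t_rep, data.label_kind),
                              _label_vector(y_test, data.label_kind),
                              cfg.estimator, **est_kw).value
            penalty = 0.0
            if cfg.beta > 0:
                penalty = estimate_cmi(
                    _features_vector(data.features[test], cfg),
                    _label_vector(t_rep, data.label_kind),
                    _label_vector(y_test, data.label_kind),
                    cfg.estimator, **est_kw).value
            values.append((num - cfg.beta * penalty) / den)
        if data.label_kind == CATEGORICAL:
            accuracies.append(float(np.mean(t_rep == y_test)))
    acc = np.asarray(accuracies) if accuracies else None
    return _FidelityParts(np.asarray(values), acc, den, list(splits))


def fidelity_unsupervised(data: LabeledDataset, model: InferenceModel,
                          cfg: FidelityConfig, seed: int = 0,
                          splits: Sequence | None = None,
                          denominator: float | None = None) -> _FidelityParts:
    """Per-split unsupervised (cluster-stability) fidelities.

    Each round fits the clusterer separately on X' and X'' and applies
    both to the shared held-out part, yielding paired labelings whose
    mutual information enters the fidelity.
    """
    if model.mode != UNSUPERVISED:
        raise ConfigError("fidelity_unsupervised needs an unsupervised model")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(3 + 3 * cfg.n_splits) % (2**31)
    if denominator is not None:
        den = float(denominator)
    else:
        full_fit = model.fit(data.features, random_state=int(seeds[0]))
        y_full = model.apply(full_fit, data.features)
        den = _full_mi(data, y_full, CATEGORICAL, cfg, int(seeds[1]))
    if splits is None:
        splits = make_threeway_splits(data.n, cfg, int(seeds[2]))
    values = []
    for i, (part1, part2, test) in enumerate(splits):
        s1, s2, s3 = (int(s) for s in seeds[3 + 3 * i: 6 + 3 * i])
        fit1 = model.fit(data.features[part1], random_state=s1)
        fit2 = model.fit(data.features[part2], random_state=s2)
        y_hat = model.apply(fit1, data.features[test])
        t_rep = model.apply(fit2, data.features[test])
        est_kw = _estimator_kwargs(cfg, s3)
        num = estimate_mi(as_sample_vector(t_rep.astype(int), "discrete"),
                          as_sample_vector(y_hat.astype(int), "discrete"),
                          cfg.estimator, **est_kw).value
        penalty = 0.0
        if cfg.beta > 0:
            penalty = estimate_cmi(
                _features_vector(data.features[test], cfg),
                as_sample_vector(t_rep.astype(int), "discrete"),
                as_sample_vector(y_hat.astype(int), "discrete"),
                cfg.estimator, **est_kw).value
        values.append((num - cfg.beta * penalty) / den)
    return _FidelityParts(np.asarray(values), None, den, list(splits))


@dataclass
class DVMResult:
    """Fitted Data Value Metric with per-split detail.

    Invariants: ``dvm = fidelity - lam * regularizer`` and
    ``fidelity = mean(per_split_fidelities)`` hold exactly.
    """

    fidelity: float
    per_split_fidelities: np.ndarray
    ci95: tuple[float, float]
    regularizer: float
    lam: float
    dvm: float
    denominator: float
    config: dict
    seed: int
    model_id: str
    n: int
    p: int
    accuracy: float | None = None
    per_split_accuracies: np.ndarray | None = None
    accuracy_ci95: tuple[float, float] | None = None
    splits: list | None = None

    def to_dict(self) -> dict:
        return {
            "fidelity": self.fidelity,
            "per_split_fidelities": [float(v)
                                     for v in self.per_split_fidelities],
            "ci95": [float(self.ci95[0]), float(self.ci95[1])],
            "regularizer": self.regularizer,
            "lambda": self.lam,
            "dvm": self.dvm,
            "denominator_mi_nats": self.denominator,
            "accuracy": self.accuracy,
            "config": self.config,
            "seed": self.seed,
            "model": self.model_id,
            "n": self.n,
            "p": self.p,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        rows = [
            ("Model", self.model_id),
            ("n samples / p features", f"{self.n} / {self.p}"),
            ("Splits (M)", len(self.per_split_fidelities)),
            ("Fidelity F", f"{self.fidelity:.4f}"),
            ("95% CI", f"[{self.ci95[0]:.4f}, {self.ci95[1]:.4f}]"),
            ("Regularizer R", f"{self.regularizer:.4f}"),
            ("lambda", f"{self.lam:.4g}"),
            ("DVM = F - lambda*R", f"{self.dvm:.4f}"),
            ("I(X;Y) denominator (nats)", f"{self.denominator:.4f}"),
        ]
        if self.accuracy is not None:
            rows.append(("Held-out accuracy", f"{self.accuracy:.4f}"))
        width = max(len(k) for k, _ in rows)
        lines = ["Data Value Metric", "=" * 40]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)


def compute_dvm(data: LabeledDataset, model, cfg: FidelityConfig | None = None,
                lam: float = 0.01, reference: tuple[int, int] | None = None,
                seed: int = 0, splits: Sequence | None = None,
                denominator: float | None = None) -> DVMResult:
    """Compute the full DVM of a dataset under an inference method.

    ``reference`` is the (n, p) point at which the complexity regularizer
    equals 1; it defaults to the dataset's own dimensions, and must
    dominate them componentwise.
    """
    if lam < 0:
        raise ConfigError("lambda must be >= 0")
    cfg = cfg or FidelityConfig()
    model = make_model(model)
    if model.mode == SUPERVISED:
        parts = fidelity_supervised(data, model, cfg, seed, splits,
                                    denominator=denominator)
    else:
        parts = fidelity_unsupervised(data, model, cfg, seed, splits,
                                      denominator=denominator)
    ref_n, ref_p = reference if reference is not None else (data.n, data.p)
    reg = normalized_regularizer(
        model, data.n, data.p, ref_n, ref_p,
        allow_default_cost=bool(
            model.hyperparams.get("allow_default_cost", False)))
    fidelity = float(np.mean(parts.per_split))
    acc = parts.per_split_accuracy
    return DVMResult(
        fidelity=fidelity,
        per_split_fidelities=parts.per_split,
        ci95=_ci95(parts.per_split),
        regularizer=reg,
        lam=float(lam),
        dvm=fidelity - float(lam) * reg,
        denominator=parts.denominator,
        config={"beta": cfg.beta, "n_splits": cfg.n_splits,
                "train_fraction": cfg.train_fraction,
                "split_fractions": list(cfg.split_fractions),
                "estimator": cfg.estimator,
                "reference": [int(ref_n), int(ref_p)]},
        seed=int(seed),
        model_id=model.model_id,
        n=data.n, p=data.p,
        accuracy=None if acc is None else float(np.mean(acc)),
        per_split_accuracies=acc,
        accuracy_ci95=None if acc is None else _ci95(acc),
        splits=parts.splits,
    )


def ib_score(x, t, y, beta: float, estimator: str = "plugin",
             **params) -> float:
    """Information-bottleneck objective I(T;Y) - beta * I(X;T)."""
    ity = estimate_mi(t, y, estimator, **params).value
    ixt = estimate_mi(x, t, estimator, **params).value
    return float(ity - beta * ixt)


def fidelity_exact(x, t, y, beta: float) -> float:
    """Exact plug-in fidelity (I(T;Y) - beta * I(X;T|Y)) / I(X;Y).

    All three sample vectors must be discrete; no splitting or clipping is
    applied, so this evaluates the population-style fidelity of a joint
    table replicated as samples.  Bounded above by 1 for any beta >= 0.
    """
    ity = estimate_mi(t, y, "plugin").value
    ixty = estimate_cmi(x, t, y, "plugin").value
    ixy = estimate_mi(x, y, "plugin").value
    if ixy <= 0:
        raise DegenerateSignalError("I(X;Y) = 0: fidelity undefined")
    return float((ity - beta * ixty) / ixy)


class DataValueModel:
    """Data Value Metric model: a dataset paired with an inference method.

    Parameters
    ----------
    data : LabeledDataset, or an n x p array (then pass ``labels``).
    labels : length-n label vector when ``data`` is a bare array.
    model : inference method id (see ``dvmetric.models.MODEL_REGISTRY``)
        or an :class:`InferenceModel`.
    beta, lam : fidelity compression weight and regularizer penalty.
    n_splits, train_fraction, split_fractions, estimator,
    estimator_params, mi_floor : see :class:`FidelityConfig`.
    reference : (n, p) normalization point of the regularizer.
    hyperparams : passed to the underlying scikit-learn model.

    Examples
    --------
    >>> from dvmetric import DataValueModel, make_blobs_dataset
    >>> ds = make_blobs_dataset(n=400, p=20, cluster_std=2.0, seed=0)
    >>> res = DataValueModel(ds, model="naive_bayes").fit(seed=0)
    >>> 0.0 <= res.dvm <= 1.0
    True
    """

    def __init__(self, data, labels=None, *, model="random_forest",
                 mode: str | None = None, beta: float = 0.1,
                 lam: float = 0.01, n_splits: int = 10,
                 train_fraction: float = 0.7,
                 split_fractions=(0.4, 0.4, 0.2),
                 estimator: str = "hash_ensemble",
                 estimator_params: dict | None = None,
                 mi_floor: float = 1e-3,
                 reference: tuple[int, int] | None = None,
                 label_kind: str | None = None,
                 feature_names=None,
                 hyperparams: dict | None = None):
        if isinstance(data, LabeledDataset):
            self.data = data
        else:
            arr = np.asarray(data, dtype=float)
            if label_kind is None and labels is not None:
                labels = np.asarray(labels)
                label_kind = (CONTINUOUS if labels.dtype.kind == "f"
                              else CATEGORICAL)
            self.data = LabeledDataset(arr, labels, feature_names,
                                       label_kind or CATEGORICAL)
        self.model = make_model(model, mode, **(hyperparams or {}))
        self.config = FidelityConfig(
            beta=beta, n_splits=n_splits, train_fraction=train_fraction,
            split_fractions=split_fractions, estimator=estimator,
            estimator_params=estimator_params or {}, mi_floor=mi_floor)
        self.lam = float(lam)
        self.reference = reference

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str,
                       **kwargs) -> "DataValueModel":
        return cls(LabeledDataset.from_frame(df, label_column), **kwargs)

    def fit(self, seed: int = 0, splits: Sequence | None = None) -> DVMResult:
        return compute_dvm(self.data, self.model, self.config, self.lam,
                           self.reference, seed=seed, splits=splits)
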