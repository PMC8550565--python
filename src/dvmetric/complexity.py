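"""Training/prediction cost models for the DVM complexity regularizer.

Each registered inference method carries symbolic Big-O cost functions of
(n, p, hyperparameters), evaluated with unit constants.  The classifier
rows follow the standard published complexities (e.g. random forest
training ~ n^2 * p * k_trees, SVM ~ n^2 * p + n^3, naive Bayes ~ n * p).
Methods whose training cost genuinely varies with the implementation
(k-nearest neighbours, neural networks) have no default training cost and
require an explicit user-supplied cost function; kNN documents an opt-in
default of n * p (its prediction cost).

Clustering methods are not covered by the published table; the registry
extends it with the standard per-pass costs (k-means ~ n * p * k,
affinity propagation and agglomerative clustering ~ n^2 * p).

The regularizer used in the DVM is a [0, 1]-normalized log-cost ratio:
``log(1 + cost(n, p)) / log(1 + cost(n_ref, p_ref))``, equal to 1 at the
reference point and monotone in both n and p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .exceptions import ConfigError, MissingCostError

import numpy as np

__all__ = [
    "ComplexityModel",
    "COMPLEXITY_REGISTRY",
    "training_complexity",
    "prediction_complexity",
    "normalized_regularizer",
]

CostFn = Callable[[int, int, dict], float]


@dataclass(frozen=True)
class ComplexityModel:
    """Symbolic training/prediction cost of an inference method."""

    model_id: str
    training_cost: CostFn | None
    prediction_cost: CostFn | None
    defaults: dict = field(default_factory=dict)
    opt_in_training_cost: CostFn | None = None

    def _params(self, hyperparams: dict | None) -> dict:
        params = dict(self.defaults)
        if hyperparams:
            params.update(hyperparams)
        return params

    def training(self, n: int, p: int, hyperparams: dict | None = None,
                 allow_default_cost: bool = False) -> float:
        params = self._params(hyperparams)
        fn = self.training_cost
        if fn is None:
            user = params.get("training_cost")
            if user is not None:
                fn = user
            elif allow_default_cost and self.opt_in_training_cost is not None:
                fn = self.opt_in_training_cost
            else:
                raise MissingCostError(
                    f"training complexity of {self.model_id!r} varies with "
                    "the implementation; supply a 'training_cost' function "
                    "(or opt in to the documented default where available)")
        return float(fn(n, p, params))

    def prediction(self, n: int, p: int,
                   hyperparams: dict | None = None) -> float:
        params = self._params(hyperparams)
        if self.prediction_cost is None:
            raise MissingCostError(
                f"prediction complexity of {self.model_id!r} requires a "
                "user-supplied cost function")
        return float(self.prediction_cost(n, p, params))


COMPLEXITY_REGISTRY: dict[str, ComplexityModel] = {}


def _register(model_id, training, prediction, defaults=None, opt_in=None):
    COMPLEXITY_REGISTRY[model_id] = ComplexityModel(
        model_id, training, prediction, defaults or {}, opt_in)


_register("linear_regression",
          lambda n, p, h: p**2 * n + p**3,
          lambda n, p, h: p)
_register("decision_tree",
          lambda n, p, h: n**2 * p,
          lambda n, p, h: p)
_register("random_forest",
          lambda n, p, h: n**2 * p * h["k_trees"],
          lambda n, p, h: p * h["k_trees"],
          defaults={"k_trees": 100})
_register("gradient_boosting",
          lambda n, p, h: n * p * h["k_trees"],
          lambda n, p, h: p * h["k_trees"],
          defaults={"k_trees": 100})
_register("svm",
          lambda n, p, h: n**2 * p + n**3,
          lambda n, p, h: h["m_sv"] * p,
          defaults={"m_sv": 1})
_register("knn",
          None,
          lambda n, p, h: n * p,
          opt_in=lambda n, p, h: n * p)
_register("neural_network",
          None,
          lambda n, p, h: float(np.sum(np.asarray(h["layer_sizes"][:-1])
                                       * np.asarray(h["layer_sizes"][1:])))
          if "layer_sizes" in h else None,
          )
_register("naive_bayes",
          lambda n, p, h: n * p,
          lambda n, p, h: p)
# clustering extensions (not in the published classifier table)
_register("kmeans",
          lambda n, p, h: n * p * h["n_clusters"],
          lambda n, p, h: p * h["n_clusters"],
          defaults={"n_clusters": 8})
_register("affinity_propagation",
          lambda n, p, h: n**2 * p,
          lambda n, p, h: n * p)
_register("agglomerative",
          lambda n, p, h: n**2 * p,
          lambda n, p, h: n * p,
          defaults={"n_clusters": 2})


def _lookup(model) -> tuple[ComplexityModel, dict]:
    """Accept a model id string or an InferenceModel-like object."""
    if isinstance(model, str):
        model_id, hyperparams = model, {}
    else:
        model_id, hyperparams = model.model_id, dict(model.hyperparams or {})
    if model_id not in COMPLEXITY_REGISTRY:
        if hyperparams.get("training_cost") is not None:
            return (ComplexityModel(model_id, None, None), hyperparams)
        raise ConfigError(f"no complexity entry for model {model_id!r}")
    return COMPLEXITY_REGISTRY[model_id], hyperparams


def training_complexity(model, n: int, p: int, *,
                        allow_default_cost: bool = False,
                        **hyperparams) -> float:
    """Evaluate a model's symbolic training cost at (n, p), constants = 1."""
    if n < 1 or p < 1:
        raise ConfigError("n and p must be positive")
    cm, params = _lookup(model)
    params.update(hyperparams)
    return cm.training(n, p, params, allow_default_cost=allow_default_cost)


def prediction_complexity(model, n: int, p: int, **hyperparams) -> float:
    """Evaluate a model's symbolic prediction cost at (n, p)."""
    cm, params = _lookup(model)
    params.update(hyperparams)
    return cm.prediction(n, p, params)


def normalized_regularizer(model, n: int, p: int,
                           reference_n: int, reference_p: int, *,
                           allow_default_cost: bool = False,
                           **hyperparams) -> float:
    """Log-cost ratio regularizer in [0, 1].

    ``log1p(cost(n, p)) / log1p(cost(reference_n, reference_p))``; equals 1
    at the reference point and is monotone nondecreasing in n and p.
    """
    if reference_n < n or reference_p < p:
        raise ConfigError(
            "reference point must dominate the evaluated point: "
            f"({n}, {p}) vs reference ({reference_n}, {reference_p})")
    cost = training_complexity(model, n, p,
                               allow_default_cost=allow_default_cost,
                               **hyperparams)
    ref = training_complexity(model, reference_n, reference_p,
                              allow_default_cost=allow_default_cost,
                              **hyperparams)
    return float(np.log1p(cost) / np.log1p(ref))
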