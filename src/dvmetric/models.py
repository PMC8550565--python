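"""Inference-method registry: thin wrappers around scikit-learn models.

An :class:`InferenceModel` names a supervised or unsupervised method
(the ``g`` applied to the data), carries its hyperparameters, and knows
how to fit on a training subset and produce a per-sample representation
(predicted labels by default) on held-out samples.  Every model id either
appears in the complexity registry or carries a user-supplied cost
function, so the DVM regularizer is always computable.

Clustering methods without a native out-of-sample ``predict``
(agglomerative) assign held-out points to the cluster of their nearest
training point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complexity import COMPLEXITY_REGISTRY
from .exceptions import ConfigError, DegenerateClusteringError

__all__ = ["InferenceModel", "make_model", "MODEL_REGISTRY"]

SUPERVISED = "supervised"
UNSUPERVISED = "unsupervised"

# model_id -> (mode, classifier factory, regressor factory) ; clustering
# factories sit in the classifier slot.
MODEL_REGISTRY: dict[str, tuple] = {}


def _register(model_id, mode, clf=None, reg=None):
    MODEL_REGISTRY[model_id] = (mode, clf, reg)


def _clf(name):
    def build(params, random_state):
        import sklearn.ensemble as ens
        import sklearn.linear_model as lin
        import sklearn.naive_bayes as nb
        import sklearn.neighbors as nbr
        import sklearn.svm as svm
        import sklearn.tree as tree

        table = {
            "decision_tree": lambda: tree.DecisionTreeClassifier(
                random_state=random_state, **params),
            "random_forest": lambda: ens.RandomForestClassifier(
                n_estimators=params.pop("k_trees", 100),
                random_state=random_state, n_jobs=1, **params),
            "gradient_boosting": lambda: ens.HistGradientBoostingClassifier(
                max_iter=params.pop("k_trees", 100),
                random_state=random_state, **params),
            "svm": lambda: svm.SVC(random_state=random_state, **params),
            "knn": lambda: nbr.KNeighborsClassifier(**params),
            "naive_bayes": lambda: nb.GaussianNB(**params),
            "linear_regression": lambda: lin.LogisticRegression(
                max_iter=1000, **params),
        }
        return table[name]()
    return build


def _reg(name):
    def build(params, random_state):
        import sklearn.ensemble as ens
        import sklearn.linear_model as lin
        import sklearn.neighbors as nbr
        import sklearn.svm as svm
        import sklearn.tree as tree

        table = {
            "linear_regression": lambda: lin.LinearRegression(**params),
            "decision_tree": lambda: tree.DecisionTreeRegressor(
                random_state=random_state, **params),
            "random_forest": lambda: ens.RandomForestRegressor(
                n_estimators=params.pop("k_trees", 100),
                random_state=random_state, n_jobs=1, **params),
            "gradient_boosting": lambda: ens.HistGradientBoostingRegressor(
                max_iter=params.pop("k_trees", 100),
                random_state=random_state, **params),
            "svm": lambda: svm.SVR(**params),
            "knn": lambda: nbr.KNeighborsRegressor(**params),
        }
        return table[name]()
    return build


def _cluster(name):
    def build(params, random_state):
        import sklearn.cluster as cl

        table = {
            "kmeans": lambda: cl.KMeans(
                n_clusters=params.pop("n_clusters", 8), n_init=10,
                random_state=random_state, **params),
            "affinity_propagation": lambda: cl.AffinityPropagation(
                random_state=random_state, **params),
            "agglomerative": lambda: cl.AgglomerativeClustering(
                n_clusters=params.pop("n_clusters", 2), **params),
        }
        return table[name]()
    return build


for _id in ("decision_tree", "random_forest", "gradient_boosting", "svm",
            "knn", "naive_bayes"):
    _register(_id, SUPERVISED, _clf(_id), _reg(_id) if _id != "naive_bayes"
              else None)
_register("linear_regression", SUPERVISED, _clf("linear_regression"),
          _reg("linear_regression"))
for _id in ("kmeans", "affinity_propagation", "agglomerative"):
    _register(_id, UNSUPERVISED, _cluster(_id))


@dataclass
class InferenceModel:
    """A named inference method with mode, hyperparameters and fit/apply."""

    model_id: str
    mode: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in (SUPERVISED, UNSUPERVISED):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if (self.model_id not in COMPLEXITY_REGISTRY
                and self.hyperparams.get("training_cost") is None):
            raise ConfigError(
                f"model {self.model_id!r} has no complexity entry; supply "
                "hyperparams['training_cost']")

    # -- fitting -----------------------------------------------------------
    def _build(self, random_state: int, label_kind: str):
        mode, clf, reg = MODEL_REGISTRY[self.model_id]
        params = {k: v for k, v in self.hyperparams.items()
                  if k not in ("training_cost", "allow_default_cost")}
        if mode == UNSUPERVISED or label_kind != "continuous":
            factory = clf
        else:
            factory = reg
            if factory is None:
                raise ConfigError(
                    f"{self.model_id!r} has no regression variant")
        return factory(dict(params), random_state)

    def fit(self, X: np.ndarray, y: np.ndarray | None = None, *,
            random_state: int = 0, label_kind: str = "categorical"):
        """Fit on a training subset; returns a fitted estimator handle."""
        if self.model_id not in MODEL_REGISTRY:
            raise ConfigError(f"unknown model id {self.model_id!r}")
        est = self._build(random_state, label_kind)
        if self.mode == SUPERVISED:
            est.fit(X, y)
            return _Fitted(est, None, None)
        labels = est.fit_predict(X)
        if len(np.unique(labels)) < 2:
            raise DegenerateClusteringError(
                f"{self.model_id!r} returned a single cluster")
        return _Fitted(est, np.asarray(X, dtype=float), np.asarray(labels))

    def apply(self, fitted: "_Fitted", X: np.ndarray) -> np.ndarray:
        """Representation of held-out samples (predicted labels/values)."""
        est = fitted.estimator
        if self.mode == SUPERVISED or hasattr(est, "predict"):
            try:
                return np.asarray(est.predict(X))
            except AttributeError:
                pass
        # nearest-training-point assignment for fit_predict-only clusterers
        from scipy.spatial import cKDTree

        _, idx = cKDTree(fitted.train_X).query(np.asarray(X, dtype=float))
        return fitted.train_labels[idx]


@dataclass
class _Fitted:
    estimator: object
    train_X: np.ndarray | None
    train_labels: np.ndarray | None


def make_model(model_id: str, mode: str | None = None,
               **hyperparams) -> InferenceModel:
    """Build an :class:`InferenceModel`, inferring mode from the registry."""
    if isinstance(model_id, InferenceModel):
        return model_id
    if model_id not in MODEL_REGISTRY:
        raise ConfigError(
            f"unknown model id {model_id!r}; known: "
            f"{sorted(MODEL_REGISTRY)}")
    default_mode = MODEL_REGISTRY[model_id][0]
    return InferenceModel(model_id, mode or default_mode, hyperparams)
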