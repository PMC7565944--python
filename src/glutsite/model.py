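"""Classifier registry, training, prediction, and persistence.

The primary classifier is an Extra-Trees ensemble (10 trees,
``min_samples_split=2``); random-forest, AdaBoost, MLP and — when the
libraries are installed — XGBoost and LightGBM configurations are kept in
the registry for comparison runs.  All models expose positive-class scores
in [0, 1]; the decision threshold is 0.5, the natural operating point after
class balancing.
"""

from __future__ import annotations

import hashlib
import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.neural_network import MLPClassifier

from glutsite.dataset import LabeledDataset
from glutsite.features import N_FEATURES

#: Decision threshold on the positive-class score.
DECISION_THRESHOLD = 0.5

#: Default hyperparameters per registered classifier.
DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "extra_trees": {"n_estimators": 10, "min_samples_split": 2},
    "random_forest": {"max_depth": 2, "random_state": 42, "n_estimators": 300},
    "adaboost": {"n_estimators": 300},
    "xgboost": {"n_estimators": 300},
    # the printed learning rate for LightGBM in the source configuration is
    # not usable; the library default rate is kept
    "lightgbm": {"num_leaves": 31, "n_estimators": 40},
    "mlp": {
        "hidden_layer_sizes": (100,),
        "activation": "relu",
        "alpha": 1.0,
        "max_iter": 1000,
        "learning_rate_init": 0.001,
    },
}

_TREE_ENSEMBLES = {"extra_trees", "random_forest", "adaboost", "xgboost", "lightgbm"}


@dataclass(frozen=True)
class ClassifierConfig:
    """A named classifier with hyperparameters and a seed."""

    name: str = "extra_trees"
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(
                f"unknown classifier {self.name!r}; "
                f"registered: {sorted(DEFAULT_HYPERPARAMETERS)}"
            )

    @property
    def effective_hyperparameters(self) -> dict[str, Any]:
        merged = dict(DEFAULT_HYPERPARAMETERS[self.name])
        merged.update(self.hyperparameters)
        return merged

    def build(self):
        """Instantiate the underlying estimator."""
        params = self.effective_hyperparameters
        if self.name == "extra_trees":
            return ExtraTreesClassifier(random_state=self.seed, **params)
        if self.name == "random_forest":
            params.setdefault("random_state", self.seed)
            return RandomForestClassifier(**params)
        if self.name == "adaboost":
            return AdaBoostClassifier(random_state=self.seed, **params)
        if self.name == "mlp":
            return MLPClassifier(random_state=self.seed, **params)
        if self.name == "xgboost":
            from xgboost import XGBClassifier

            return XGBClassifier(random_state=self.seed, **params)
        if self.name == "lightgbm":
            from lightgbm import LGBMClassifier

            return LGBMClassifier(random_state=self.seed, verbose=-1, **params)
        raise AssertionError(self.name)


@dataclass
class TrainedModel:
    """A fitted classifier bound to a fixed feature width."""

    config: ClassifierConfig
    estimator: Any
    feature_count: int = N_FEATURES

    def _check_width(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.feature_count:
            raise ValueError(
                f"expected n x {self.feature_count} feature matrix, "
                f"got shape {features.shape}"
            )
        return features


def train_classifier(train: LabeledDataset, config: ClassifierConfig | None = None) -> TrainedModel:
    """Fit the configured classifier on a labeled dataset.

    Deterministic for a fixed config seed and input.  Raises if only one
    class is present.
    """
    config = config or ClassifierConfig()
    if len(train) == 0:
        raise ValueError("training set is empty")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set contains a single class; need both labels")
    estimator = config.build()
    estimator.fit(train.features, train.labels)
    return TrainedModel(
        config=config, estimator=estimator, feature_count=train.features.shape[1]
    )


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, positive-class scores); label = 1 iff score >= 0.5."""
    features = model._check_width(np.atleast_2d(features)) if np.size(features) else \
        np.empty((0, model.feature_count))
    if features.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=float)
    proba = model.estimator.predict_proba(features)
    pos_col = list(model.estimator.classes_).index(1)
    scores = np.clip(proba[:, pos_col], 0.0, 1.0)
    labels = (scores >= DECISION_THRESHOLD).astype(int)
    return labels, scores


def feature_importances(model: TrainedModel) -> np.ndarray:
    """Gini feature importances of a tree-ensemble model (sum to 1)."""
    if model.config.name not in _TREE_ENSEMBLES:
        raise TypeError(
            f"feature importances require a tree ensemble, not {model.config.name!r}"
        )
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp


# ---------------------------------------------------------------------------
# Persistence: pickled estimator + JSON metadata sidecar
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _ordering_hash(feature_count: int) -> str:
    ordering = ",".join(f"f{u + 1:03d}" for u in range(feature_count))
    return hashlib.sha256(ordering.encode()).hexdigest()[:16]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write the fitted state plus a metadata sidecar (``<path>.json``)."""
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model.estimator, fh)
    meta = {
        "format_version": _FORMAT_VERSION,
        "classifier": model.config.name,
        "hyperparameters": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in model.config.effective_hyperparameters.items()
        },
        "seed": model.config.seed,
        "feature_count": model.feature_count,
        "feature_ordering_hash": _ordering_hash(model.feature_count),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        warnings.warn(
            f"model was saved with format version {meta.get('format_version')}; "
            f"loading best-effort", stacklevel=2,
        )
    if meta.get("feature_ordering_hash") != _ordering_hash(meta["feature_count"]):
        warnings.warn("feature ordering hash mismatch; predictions may be invalid",
                      stacklevel=2)
    with open(path, "rb") as fh:
        estimator = pickle.load(fh)
    config = ClassifierConfig(name=meta["classifier"], seed=meta.get("seed", 0))
    return TrainedModel(
        config=config, estimator=estimator, feature_count=meta["feature_count"]
    )
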