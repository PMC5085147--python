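"""Random-forest decision stage over DPSP feature tables.

The classifier sits behind a narrow train / predict-scores contract so the
encoding and evaluation layers stay classifier-agnostic.  The continuous
score of a sample is the *vote fraction*: the proportion of trees in the
forest whose leaf vote is the positive class.  Scores are therefore exact
multiples of 1/n_trees, and thresholding them at t calls a sample positive
iff score >= t.

No forest hyperparameters come from upstream literature on this method;
the defaults here (500 trees, Gini impurity, unlimited depth, sqrt feature
sampling, mandatory explicit seed) are standard, stable choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import ConfigError, InputDataError, LengthMismatchError

__all__ = [
    "ModelConfig",
    "OriginForestClassifier",
    "TrainedModel",
    "train",
    "predict_scores",
    "classify",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Forest configuration.  The seed is mandatory: no silent global RNG."""

    random_seed: int
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError(f"n_trees must be >= 1, got {self.n_trees}")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigError(
                f"decision_threshold must lie in (0, 1), got {self.decision_threshold}"
            )

    def as_dict(self) -> dict:
        return asdict(self)


class OriginForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest with explicit vote-fraction scores and a decision threshold.

    A thin, sklearn-idiomatic wrapper around
    :class:`~sklearn.ensemble.RandomForestClassifier`: trees are fully
    grown with Gini impurity and sqrt feature sampling, and
    :meth:`vote_fractions` averages the hard votes of the individual
    trees (so scores are multiples of ``1 / n_estimators``).
    :meth:`predict` calls a sample positive iff its vote fraction is at
    least ``threshold``.

    The positive class is the larger of the two labels seen in ``y``
    (1 in the canonical 0/1 labelling).
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: str | int | float = "sqrt",
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError(f"threshold must lie in (0, 1), got {self.threshold}")
        X, y = validate_data(self, X, y, dtype=np.float64)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise InputDataError(
                f"need exactly two classes to train, got {len(self.classes_)}"
            )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            criterion="gini",
            max_features=self.max_features,
            random_state=self.random_state,
        ).fit(X, y)
        return self

    def _check_width(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise LengthMismatchError(
                f"expected a 2-D table with {self.n_features_in_} feature "
                f"column(s), got shape {X.shape}"
            )
        return X

    def vote_fractions(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class, per row of X."""
        X = self._check_width(X)
        if X.shape[0] == 0:
            return np.zeros(0, dtype=np.float64)
        positive = self.classes_[1]
        votes = np.zeros(X.shape[0], dtype=np.float64)
        for tree in self.forest_.estimators_:
            votes += tree.predict(X) == positive
        return votes / len(self.forest_.estimators_)

    def predict_proba(self, X) -> np.ndarray:
        s = self.vote_fractions(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.vote_fractions(X)
        return np.where(s >= self.threshold, self.classes_[1], self.classes_[0])


@dataclass
class TrainedModel:
    """A fitted forest plus the config and data fingerprint that produced it."""

    estimator: OriginForestClassifier
    config: ModelConfig
    z: int
    fingerprint: dict = field(default_factory=dict)

    def predict_scores(self, features) -> np.ndarray:
        """Vote-fraction scores in [0, 1]; rejects tables of wrong width."""
        return self.estimator.vote_fractions(features)

    def classify(self, features, threshold: float | None = None) -> np.ndarray:
        """Binary calls: positive (1) iff score >= threshold."""
        t = self.config.decision_threshold if threshold is None else threshold
        if not 0.0 < t < 1.0:
            raise ConfigError(f"threshold must lie in (0, 1), got {t}")
        return (self.predict_scores(features) >= t).astype(int)


def train(features, labels, config: ModelConfig) -> TrainedModel:
    """Fit the forest on an (n, Z) feature table with binary labels.

    Deterministic given (features, labels, config): the same inputs and
    seed reproduce bit-identical vote fractions on any probe point.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    est = OriginForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        threshold=config.decision_threshold,
        random_state=config.random_seed,
    ).fit(features, labels)
    fingerprint = {
        "n_pos": int(np.sum(labels == est.classes_[1])),
        "n_neg": int(np.sum(labels == est.classes_[0])),
    }
    return TrainedModel(
        estimator=est, config=config, z=features.shape[1], fingerprint=fingerprint
    )


def predict_scores(model: TrainedModel, features) -> np.ndarray:
    return model.predict_scores(features)


def classify(model: TrainedModel, features, threshold: float | None = None) -> np.ndarray:
    return model.classify(features, threshold)


def save_model(path: str | Path, model: TrainedModel, encoder=None, extra: dict | None = None) -> None:
    """Persist a trained model (optionally with its encoder) to one file."""
    payload = {
        "model": model,
        "encoder": encoder,
        "config": model.config.as_dict(),
        "fingerprint": model.fingerprint,
    }
    if extra:
        payload.update(extra)
    joblib.dump(payload, path)


def load_model(path: str | Path) -> dict:
    """Load a payload written by :func:`save_model`."""
    return joblib.load(path)
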