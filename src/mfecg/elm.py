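"""Extreme learning machine: a single-hidden-layer feedforward network
whose input weights are random and fixed, and whose output weights are
solved once by least squares.

Given standardized features X (n x d), hidden weights W (d x l) and biases
b (l,) drawn uniformly on [-1, 1], the hidden activations are
H = g(XW + b) with a logistic sigmoid g, and the output weights are
beta = pinv(H) @ T for one-hot targets T — the minimum-norm least-squares
solution. Prediction takes the argmax of H @ beta over classes (ties break
toward the lower class index, numpy argmax semantics).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from sklearn.utils.multiclass import unique_labels

__all__ = ["ELMClassifier", "elm_train", "elm_predict"]


class ELMClassifier(ClassifierMixin, BaseEstimator):
    """Extreme learning machine classifier.

    Parameters
    ----------
    n_hidden : int, default 60
        Number of hidden-layer nodes (l).
    activation : {'sigmoid'}, default 'sigmoid'
        Hidden-layer activation.
    random_state : int or None
        Seed for the fixed random input layer; the model is reconstructible
        bit-exactly from (random_state, d, n_hidden, activation) plus the
        stored output weights and feature scaler.

    Attributes
    ----------
    classes_ : ndarray of shape (c,)
    coef_hidden_ : ndarray (d, n_hidden) — random input weights W
    intercept_hidden_ : ndarray (n_hidden,) — random biases b
    beta_ : ndarray (n_hidden, c) — least-squares output weights
    mean_, scale_ : per-feature standardization from the training data

    Features are z-scored with the training statistics before the random
    projection; without it the sigmoid saturates on raw entropy /
    singularity-exponent scales.
    """

    def __init__(self, n_hidden: int = 60, activation: str = "sigmoid",
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.activation = activation
        self.random_state = random_state

    def _activate(self, Z: np.ndarray) -> np.ndarray:
        if self.activation != "sigmoid":
            raise ValueError(f"unsupported activation {self.activation!r}")
        return expit(Z)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if len(X) < 2:
            raise ValueError("need at least 2 training samples")
        if np.isnan(X).any():
            raise ValueError("X contains NaN; impute or drop undefined "
                             "feature vectors before training")
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("training labels contain a single class")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        self.scale_ = scale
        Z = (X - self.mean_) / self.scale_
        rng = np.random.default_rng(self.random_state)
        self.coef_hidden_ = rng.uniform(-1.0, 1.0,
                                        size=(self.n_features_in_,
                                              self.n_hidden))
        self.intercept_hidden_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._activate(Z @ self.coef_hidden_ + self.intercept_hidden_)
        T = (y[:, None] == self.classes_[None, :]).astype(float)
        self.beta_ = np.linalg.pinv(H, rcond=1e-12) @ T
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} features, got {X.shape}")
        Z = (X - self.mean_) / self.scale_
        H = self._activate(Z @ self.coef_hidden_ + self.intercept_hidden_)
        return H @ self.beta_

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted model to a JSON document."""
        check_is_fitted(self, "beta_")
        doc = {
            "n_hidden": self.n_hidden,
            "activation": self.activation,
            "random_state": self.random_state,
            "n_features_in": int(self.n_features_in_),
            "classes": self.classes_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "beta": self.beta_.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ELMClassifier":
        """Rebuild a fitted model from :meth:`to_json` output."""
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        doc = json.loads(text)
        model = cls(n_hidden=doc["n_hidden"], activation=doc["activation"],
                    random_state=doc["random_state"])
        model.n_features_in_ = doc["n_features_in"]
        model.classes_ = np.asarray(doc["classes"])
        model.mean_ = np.asarray(doc["mean"], dtype=float)
        model.scale_ = np.asarray(doc["scale"], dtype=float)
        model.beta_ = np.asarray(doc["beta"], dtype=float)
        rng = np.random.default_rng(model.random_state)
        model.coef_hidden_ = rng.uniform(
            -1.0, 1.0, size=(model.n_features_in_, model.n_hidden))
        model.intercept_hidden_ = rng.uniform(-1.0, 1.0, size=model.n_hidden)
        return model


def elm_train(X, y, l: int = 60, activation: str = "sigmoid",
              seed: int | None = None) -> ELMClassifier:
    """Train an ELM with ``l`` hidden nodes; thin functional wrapper."""
    return ELMClassifier(n_hidden=l, activation=activation,
                         random_state=seed).fit(X, y)


def elm_predict(model: ELMClassifier, X):
    """Predicted labels and raw class scores for ``X``."""
    return model.predict(X), model.decision_function(X)
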