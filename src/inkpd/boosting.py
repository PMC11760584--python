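"""A compact SAMME AdaBoost classifier over weighted CART base learners.

Discrete multiclass AdaBoost (SAMME): each round fits a depth-limited
decision tree on the current sample weights, receives an estimator weight
``alpha = lr * (ln((1-err)/err) + ln(K-1))`` from its weighted training
error, and the weights of misclassified samples are scaled up. Class
probabilities are the alpha-weighted mean of the trees' leaf class
distributions, so a single-tree ensemble returns exactly that tree's
probabilities.

The implementation runs on the numba kernels in :mod:`inkpd._fast`; the
test suite cross-checks split choice and decisions against scikit-learn.
"""

from __future__ import annotations

import numpy as np

from ._fast import fit_samme, predict_samme

__all__ = ["SammeAdaBoost"]


class SammeAdaBoost:
    """AdaBoost (SAMME) with decision-tree base learners.

    Parameters mirror the tuned hyperparameter box: ``max_depth`` d in
    [1, 30], ``min_samples_split`` m as a fraction of the training set in
    [e^-4, 1], ``n_estimators`` n in [1, 100], ``learning_rate`` r in
    [e^-6, 10].
    """

    def __init__(self, max_depth: int = 3, min_samples_split: float = 0.02,
                 n_estimators: int = 50, learning_rate: float = 1.0):
        if not 1 <= int(max_depth):
            raise ValueError("max_depth must be a positive integer")
        if not 0.0 < min_samples_split <= 1.0:
            raise ValueError("min_samples_split must be a fraction in (0, 1]")
        if not 1 <= int(n_estimators):
            raise ValueError("n_estimators must be a positive integer")
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.max_depth = int(max_depth)
        self.min_samples_split = float(min_samples_split)
        self.n_estimators = int(n_estimators)
        self.learning_rate = float(learning_rate)
        self._model = None
        self.classes_: np.ndarray | None = None
        self.n_features_in_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SammeAdaBoost":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, codes = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        self._model = fit_samme(
            X, codes.astype(np.int64), len(self.classes_), self.max_depth,
            self.min_samples_split, self.n_estimators, self.learning_rate,
        )
        return self

    @property
    def n_trees_(self) -> int:
        self._check_fitted()
        return int(self._model[-1])

    def _check_fitted(self) -> None:
        if self._model is None:
            raise ValueError("classifier is not fitted")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with "
                f"{self.n_features_in_}"
            )
        feats, thrs, lefts, rights, values, alphas, n_used = self._model
        return predict_samme(X, feats, thrs, lefts, rights, values, alphas,
                             n_used, len(self.classes_))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
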