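"""Model adapters: the model-agnostic contract the conformal layer uses.

The conformal machinery never touches a learner directly; it sees an
adapter exposing ``fit``, ``predict`` and (for classification)
``predict_proba`` with probability columns ordered by the dataset's
``label_space``.  Any scikit-learn-style estimator can be wrapped;
a deterministic distance-to-class-mean classifier is provided for
transductive prediction on small cohorts and for exact hand-checkable
behaviour.
"""

from __future__ import annotations


from typing import Sequence

import numpy as np
from sklearn.base import clone as _sk_clone


class ModelAdapter:
    """Abstract training/prediction contract.

    Implementations must be deterministic under their seed: fitting
    twice on the same data yields identical predictions.
    """

    label_space: tuple[str, ...] | None = None

    def clone(self) -> "ModelAdapter":
        """An unfitted copy with identical configuration and seed."""
        raise NotImplementedError

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ModelAdapter":
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """``(n, K)`` probabilities, columns ordered by ``label_space``."""
        raise NotImplementedError


class SklearnClassifierAdapter(ModelAdapter):
    """Wrap a scikit-learn-compatible classifier.

    Labels are encoded to integer codes indexing the lexicographic
    ``label_space`` before fitting (some estimators, e.g. gradient
    boosters, require contiguous integer classes) and probability
    columns are re-ordered back, so every downstream vector is
    consistently indexed by ``label_space``.
    """

    def __init__(self, estimator, label_space: Sequence[str] | None = None):
        self.estimator = estimator
        self.label_space = tuple(sorted(label_space)) if label_space is not None else None
        self._fitted = None

    def clone(self) -> "SklearnClassifierAdapter":
        return SklearnClassifierAdapter(_sk_clone(self.estimator), self.label_space)

    def _encode(self, y: np.ndarray) -> np.ndarray:
        index = {lab: c for c, lab in enumerate(self.label_space)}
        try:
            return np.asarray([index[lab] for lab in y], dtype=int)
        except KeyError as exc:
            raise ValueError(f"label {exc} not in label space {self.label_space}") from None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnClassifierAdapter":
        y = np.asarray(y, dtype=str)
        if self.label_space is None:
            self.label_space = tuple(sorted(np.unique(y)))
        codes = self._encode(y)
        # re-map to contiguous codes in case some class is absent
        present = np.unique(codes)
        contiguous = np.searchsorted(present, codes)
        self._present = present
        self._fitted = _sk_clone(self.estimator).fit(X, contiguous)
        return self

    def _check_fitted(self):
        if self._fitted is None:
            raise RuntimeError("adapter is not fitted")
        return self._fitted

    def predict(self, X: np.ndarray) -> np.ndarray:
        est = self._check_fitted()
        codes = self._present[np.asarray(est.predict(X), dtype=int)]
        return np.asarray([self.label_space[c] for c in codes], dtype=str)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        est = self._check_fitted()
        raw = np.asarray(est.predict_proba(X), dtype=float)
        out = np.zeros((raw.shape[0], len(self.label_space)))
        for col, contiguous_code in enumerate(np.asarray(est.classes_, dtype=int)):
            out[:, self._present[contiguous_code]] = raw[:, col]
        return out


class SklearnRegressorAdapter(ModelAdapter):
    """Wrap a scikit-learn-compatible regressor (point predictions only)."""

    def __init__(self, estimator):
        self.estimator = estimator
        self._fitted = None

    def clone(self) -> "SklearnRegressorAdapter":
        return SklearnRegressorAdapter(_sk_clone(self.estimator))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnRegressorAdapter":
        self._fitted = _sk_clone(self.estimator).fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._fitted is None:
            raise RuntimeError("adapter is not fitted")
        return np.asarray(self._fitted.predict(X), dtype=float)


class ClassMeanDistanceAdapter(ModelAdapter):
    """Nearest-class-centroid classifier with exact, closed-form behaviour.

    Stores per-class feature means at fit time.  ``distance(X, label)``
    is the Euclidean distance to that class's centroid — the natural
    non-conformity for transductive prediction on small cohorts.
    Probabilities are softmax of negative distances.
    """

    def __init__(self, label_space: Sequence[str] | None = None):
        self.label_space = tuple(sorted(label_space)) if label_space is not None else None
        self.means_: dict[str, np.ndarray] | None = None

    def clone(self) -> "ClassMeanDistanceAdapter":
        return ClassMeanDistanceAdapter(self.label_space)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassMeanDistanceAdapter":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=str)
        if self.label_space is None:
            self.label_space = tuple(sorted(np.unique(y)))
        self.means_ = {lab: X[y == lab].mean(axis=0) for lab in self.label_space if np.any(y == lab)}
        return self

    def distance(self, X: np.ndarray, label: str) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("adapter is not fitted")
        if label not in self.means_:
            return np.full(np.atleast_2d(X).shape[0], np.inf)
        return np.linalg.norm(np.atleast_2d(X) - self.means_[label], axis=1)

    def _distance_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([self.distance(X, lab) for lab in self.label_space])

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self._distance_matrix(np.atleast_2d(X))
        return np.asarray([self.label_space[j] for j in d.argmin(axis=1)], dtype=str)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = self._distance_matrix(np.atleast_2d(X))
        z = np.where(np.isfinite(d), -d, -np.inf)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
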