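"""Conformal prediction: non-conformity scores, p-values, TCP/ICP/regression.

The framework turns any point predictor into a set-valued predictor
with a finite-sample marginal coverage guarantee under exchangeability.
For a new instance, each candidate label ``y`` receives a conformal
p-value — the (+1-corrected) fraction of reference non-conformity
scores at least as large as the instance's score under ``y`` — and the
prediction region keeps every label whose p-value exceeds the
significance level ``ε = 1 − confidence``.

Two classification schemes are provided:

* **Transductive (TCP)** — the model is retrained once per candidate
  label on the training set augmented with the new instance; all
  ``n+1`` scores (the augmented instance included) form the reference
  set.  Exact but expensive; suited to small cohorts.
* **Inductive (ICP)** — the model is fitted once on a proper training
  set; a disjoint calibration set supplies the reference scores.  The
  Mondrian label-conditional variant (LCMCP) compares a candidate
  label's score only against calibration scores of that same label,
  giving per-class validity under label shift.

For regression, the split-conformal interval is the point prediction
plus/minus the ⌈(n_cal+1)·confidence⌉-th smallest calibration absolute
residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cpgen.adapters import ClassMeanDistanceAdapter, ModelAdapter
from cpgen.datasets import LabeledDataset
from cpgen.exceptions import CalibrationCoverageError, LeakageError, TaskError

# ---------------------------------------------------------------------------
# non-conformity measures
# ---------------------------------------------------------------------------


def inverse_probability_score(prob_vector: Sequence[float], label: str, label_space: Sequence[str]) -> float:
    """``1 − p̂(label | x)``: the inverse-probability non-conformity.

    ``prob_vector`` is indexed by ``label_space`` (lexicographic order).
    """
    label_space = list(label_space)
    if label not in label_space:
        raise ValueError(f"label {label!r} not in label space {label_space}")
    p = float(prob_vector[label_space.index(label)])
    return 1.0 - p


def hinge_score(prob_vector: Sequence[float], label: str, label_space: Sequence[str]) -> float:
    """Hinge non-conformity, ``1 − p̂(label | x)``.

    Numerically identical to :func:`inverse_probability_score`; kept as
    a distinct name because the two are conventionally distinguished in
    the conformal literature.
    """
    return inverse_probability_score(prob_vector, label, label_space)


def absolute_error_score(y_true: float, y_pred: float) -> float:
    """Absolute deviation ``|y_true − y_pred|`` (regression non-conformity)."""
    if not (math.isfinite(y_true) and math.isfinite(y_pred)):
        raise ValueError("absolute_error_score requires finite inputs")
    return abs(y_true - y_pred)


class NonconformityMeasure:
    """Vectorised non-conformity over a fitted adapter."""

    name: str = "abstract"
    task: str = "classification"

    def score_samples(self, adapter: ModelAdapter, X: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Score each sample under its (true or candidate) label."""
        raise NotImplementedError

    def score_matrix(self, adapter: ModelAdapter, X: np.ndarray) -> np.ndarray:
        """``(n, K)`` scores of each sample under every candidate label."""
        raise NotImplementedError


class InverseProbabilityMeasure(NonconformityMeasure):
    """``1 − p̂(y|x)`` from the adapter's probability estimates."""

    name = "inverse_probability"

    def score_matrix(self, adapter, X):
        return 1.0 - adapter.predict_proba(X)

    def score_samples(self, adapter, X, labels):
        mat = self.score_matrix(adapter, X)
        idx = [adapter.label_space.index(str(lab)) for lab in labels]
        return mat[np.arange(len(idx)), idx]


class HingeMeasure(InverseProbabilityMeasure):
    """Hinge loss non-conformity (same functional form, conventional name)."""

    name = "hinge"


class ClassMeanDistanceMeasure(NonconformityMeasure):
    """Euclidean distance to the candidate label's centroid.

    Requires a :class:`~cpgen.adapters.ClassMeanDistanceAdapter`; used
    for exact, enumerable transductive prediction on small cohorts.
    """

    name = "class_mean_distance"

    def score_matrix(self, adapter, X):
        if not isinstance(adapter, ClassMeanDistanceAdapter):
            raise TypeError("class_mean_distance requires a ClassMeanDistanceAdapter")
        return np.column_stack([adapter.distance(X, lab) for lab in adapter.label_space])

    def score_samples(self, adapter, X, labels):
        labels = np.asarray(labels, dtype=str)
        out = np.empty(len(labels))
        for lab in np.unique(labels):
            mask = labels == lab
            out[mask] = adapter.distance(np.atleast_2d(X)[mask], str(lab))
        return out


class AbsoluteErrorMeasure(NonconformityMeasure):
    """``|y − ŷ|`` against the adapter's point prediction."""

    name = "absolute_error"
    task = "regression"

    def score_samples(self, adapter, X, labels):
        return np.abs(np.asarray(labels, dtype=float) - adapter.predict(X))


_MEASURES = {
    m.name: m
    for m in (InverseProbabilityMeasure(), HingeMeasure(), ClassMeanDistanceMeasure(), AbsoluteErrorMeasure())
}


def get_measure(name: str) -> NonconformityMeasure:
    try:
        return _MEASURES[name]
    except KeyError:
        raise ValueError(f"unknown non-conformity measure {name!r}; known: {sorted(_MEASURES)}") from None


# ---------------------------------------------------------------------------
# p-values and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceSpec:
    """A confidence level in (0, 1); ``epsilon = 1 − confidence``."""

    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie strictly between 0 and 1")

    @property
    def epsilon(self) -> float:
        return 1.0 - self.confidence


@dataclass
class ScoreVector:
    """Non-conformity scores with their measure and optional Mondrian map."""

    scores: np.ndarray
    measure_name: str
    per_label_category: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.measure_name in ("inverse_probability", "hinge"):
            if np.any(self.scores < -1e-9) or np.any(self.scores > 1 + 1e-9):
                raise ValueError(f"{self.measure_name} scores must lie in [0, 1]")
        elif self.measure_name == "absolute_error" and np.any(self.scores < 0):
            raise ValueError("absolute_error scores must be non-negative")

    def __len__(self) -> int:
        return len(self.scores)


def conformal_p_value(reference_scores: ScoreVector | np.ndarray, test_score: float) -> float:
    """(+1)-corrected rank p-value of ``test_score`` among the references.

    ``(#{αᵢ ≥ α_test} + 1) / (n + 1)``, ties counted as ≥; lies in
    ``[1/(n+1), 1]``.
    """
    scores = reference_scores.scores if isinstance(reference_scores, ScoreVector) else np.asarray(reference_scores)
    if scores.size == 0:
        raise RuntimeError("empty reference score set")
    return (np.count_nonzero(scores >= test_score) + 1) / (scores.size + 1)


@dataclass
class PredictionRegion:
    """Per-label conformal p-values and the retained label set.

    ``region = {y : p_values[y] > ε}``.  A region of size one is a
    *singleton* (confident call); any other size — including the empty
    set — is *uncertain* (UNC).
    """

    p_values: dict[str, float]
    confidence: ConfidenceSpec
    region: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        eps = self.confidence.epsilon
        self.region = tuple(sorted(lab for lab, p in self.p_values.items() if p > eps))

    @property
    def singleton(self) -> bool:
        return len(self.region) == 1

    @property
    def uncertain(self) -> bool:
        return len(self.region) != 1

    @property
    def empty(self) -> bool:
        return len(self.region) == 0

    def __contains__(self, label: str) -> bool:
        return label in self.region


@dataclass
class PredictionInterval:
    """Symmetric conformal interval ``[ŷ − q, ŷ + q]``."""

    center: float
    half_width: float
    lower: float = field(init=False)
    upper: float = field(init=False)
    unbounded: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")
        self.unbounded = not math.isfinite(self.half_width)
        self.lower = self.center - self.half_width if not self.unbounded else -math.inf
        self.upper = self.center + self.half_width if not self.unbounded else math.inf

    def __contains__(self, y: float) -> bool:
        return self.lower <= y <= self.upper


@dataclass
class CalibrationModel:
    """A frozen fitted adapter plus its calibration non-conformity scores."""

    adapter: ModelAdapter
    calibration: ScoreVector
    n_cal: int
    task: str
    measure: NonconformityMeasure

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be classification or regression")


# ---------------------------------------------------------------------------
# transductive conformal prediction
# ---------------------------------------------------------------------------


def tcp_predict(
    dataset: LabeledDataset,
    new_features: np.ndarray,
    adapter: ModelAdapter,
    measure: NonconformityMeasure,
    conf: ConfidenceSpec,
) -> PredictionRegion:
    """Full (transductive) conformal prediction for one new instance.

    For each candidate label ``y`` the training set is augmented with
    ``(new_features, y)``, the adapter is retrained from scratch, all
    ``n+1`` instances are scored, and the p-value is the fraction of
    the ``n+1`` scores at least as large as the new instance's own
    (which counts itself, so no further +1 correction applies).
    """
    if dataset.task != "classification":
        raise TaskError("tcp_predict requires a classification dataset")
    x_new = np.asarray(new_features, dtype=float).reshape(1, -1)
    n = dataset.n_samples
    p_values: dict[str, float] = {}
    for label in dataset.label_space:
        X_aug = np.vstack([dataset.features, x_new])
        y_aug = np.append(dataset.labels.astype(str), label)
        fitted = adapter.clone().fit(X_aug, y_aug)
        scores = measure.score_samples(fitted, X_aug, y_aug)
        p_values[label] = float(np.count_nonzero(scores >= scores[-1]) / (n + 1))
    return PredictionRegion(p_values=p_values, confidence=conf)


# ---------------------------------------------------------------------------
# inductive conformal prediction
# ---------------------------------------------------------------------------


def icp_fit(
    train: LabeledDataset,
    calibration: LabeledDataset,
    adapter: ModelAdapter,
    measure: NonconformityMeasure,
) -> CalibrationModel:
    """Fit the adapter on ``train`` and score ``calibration`` once.

    The two sets must be disjoint in ``sample_ids`` (leakage check) and
    agree on features and label space.
    """
    overlap = set(train.sample_ids) & set(calibration.sample_ids)
    if overlap:
        raise LeakageError(f"train and calibration share samples: {sorted(overlap)[:5]}")
    if train.feature_ids != calibration.feature_ids:
        raise ValueError("train and calibration feature_ids differ")
    if train.label_space != calibration.label_space:
        raise ValueError("train and calibration label_space differ")
    fitted = adapter.clone().fit(train.features, train.labels)
    cal_scores = measure.score_samples(fitted, calibration.features, calibration.labels)
    per_label = None
    if train.task == "classification":
        labels = calibration.labels.astype(str)
        per_label = {lab: np.flatnonzero(labels == lab) for lab in train.label_space}
    return CalibrationModel(
        adapter=fitted,
        calibration=ScoreVector(cal_scores, measure.name, per_label),
        n_cal=calibration.n_samples,
        task=train.task,
        measure=measure,
    )


def icp_classify(
    model: CalibrationModel,
    test_features: np.ndarray,
    conf: ConfidenceSpec,
    mondrian: bool = False,
) -> list[PredictionRegion]:
    """Inductive conformal regions for each test sample.

    With ``mondrian=True`` (label-conditional Mondrian, LCMCP) each
    candidate label's score is ranked only against calibration samples
    of that same true label, restoring per-class validity under label
    shift; every label then needs at least one calibration example.
    """
    if model.task != "classification":
        raise TaskError("icp_classify requires a classification model")
    X = np.atleast_2d(np.asarray(test_features, dtype=float))
    label_space = model.adapter.label_space
    if mondrian:
        empty = [lab for lab, idx in model.calibration.per_label_category.items() if idx.size == 0]
        if empty:
            raise CalibrationCoverageError(f"no calibration samples for label(s) {empty}")
    score_mat = model.measure.score_matrix(model.adapter, X)  # (n_test, K)
    references = {}
    for j, lab in enumerate(label_space):
        if mondrian:
            ref = model.calibration.scores[model.calibration.per_label_category[lab]]
        else:
            ref = model.calibration.scores
        references[lab] = np.sort(ref)
    regions = []
    for i in range(X.shape[0]):
        p_values = {}
        for j, lab in enumerate(label_space):
            ref = references[lab]
            ge = ref.size - np.searchsorted(ref, score_mat[i, j], side="left")
            p_values[lab] = (ge + 1) / (ref.size + 1)
        regions.append(PredictionRegion(p_values=p_values, confidence=conf))
    return regions


def icp_classify_p_values(model: CalibrationModel, test_features: np.ndarray, mondrian: bool = False) -> np.ndarray:
    """``(n_test, K)`` matrix of per-label conformal p-values."""
    regions = icp_classify(model, test_features, ConfidenceSpec(0.5), mondrian=mondrian)
    label_space = model.adapter.label_space
    return np.array([[r.p_values[lab] for lab in label_space] for r in regions])


# ---------------------------------------------------------------------------
# inductive conformal regression
# ---------------------------------------------------------------------------


def icp_regress_quantile(model: CalibrationModel, conf: ConfidenceSpec) -> float:
    """The conformal half-width: the k-th smallest calibration residual.

    ``k = ⌈(n_cal + 1)·confidence⌉``; when ``k`` exceeds ``n_cal`` the
    calibration set is too small to support the requested confidence
    and the interval is unbounded (``inf`` marker).
    """
    if model.task != "regression":
        raise TaskError("icp_regress_quantile requires a regression model")
    n = model.n_cal
    if n < 1:
        raise RuntimeError("empty calibration set")
    k = math.ceil((n + 1) * conf.confidence)
    if k > n:
        return math.inf
    return float(np.sort(model.calibration.scores)[k - 1])


def icp_regress_predict(
    model: CalibrationModel,
    test_features: np.ndarray,
    conf: ConfidenceSpec,
) -> list[PredictionInterval]:
    """Symmetric conformal intervals around the point predictions.

    The half-width is a single calibration quantile, identical across
    test samples.
    """
    half_width = icp_regress_quantile(model, conf)
    centers = model.adapter.predict(np.atleast_2d(np.asarray(test_features, dtype=float)))
    return [PredictionInterval(center=float(c), half_width=half_width) for c in centers]


# ---------------------------------------------------------------------------
# tabular serialisation of predictions
# ---------------------------------------------------------------------------


def regions_to_frame(sample_ids: Sequence[str], regions: Sequence[PredictionRegion]):
    """One row per test sample: p-values, comma-joined region, UNC flag."""
    import pandas as pd

    labels = sorted(regions[0].p_values) if regions else []
    rows = []
    for sid, region in zip(sample_ids, regions):
        row = {"sample_id": sid}
        row.update({f"p_{lab}": region.p_values[lab] for lab in labels})
        row["region"] = ",".join(region.region)
        row["flag"] = "singleton" if region.singleton else "uncertain"
        rows.append(row)
    return pd.DataFrame(rows)


def intervals_to_frame(sample_ids: Sequence[str], intervals: Sequence[PredictionInterval]):
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "center": [iv.center for iv in intervals],
            "lower": [iv.lower for iv in intervals],
            "upper": [iv.upper for iv in intervals],
            "unbounded": [iv.unbounded for iv in intervals],
        }
    )
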