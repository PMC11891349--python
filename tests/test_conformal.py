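"""Conformal machinery: scores, p-values, TCP, ICP, Mondrian, regression."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cpgen.adapters import ClassMeanDistanceAdapter, SklearnClassifierAdapter
from cpgen.conformal import (
    AbsoluteErrorMeasure,
    CalibrationModel,
    ClassMeanDistanceMeasure,
    ConfidenceSpec,
    HingeMeasure,
    PredictionInterval,
    PredictionRegion,
    ScoreVector,
    absolute_error_score,
    conformal_p_value,
    hinge_score,
    icp_classify,
    icp_fit,
    icp_regress_predict,
    icp_regress_quantile,
    inverse_probability_score,
    tcp_predict,
)
from cpgen.exceptions import CalibrationCoverageError, LeakageError
from cpgen.preprocessing import make_split

LS3 = ("A", "B", "C")


# -- score functions --------------------------------------------------------


@pytest.mark.parametrize(
    "probs, label, space, expected",
    [
        ((1.0, 0.0), "A", ("A", "B"), 0.0),
        ((0.7, 0.3), "A", ("A", "B"), 0.3),
        ((0.2, 0.5, 0.3), "C", LS3, 0.7),
        ((1 / 3, 1 / 3, 1 / 3), "B", LS3, 2 / 3),
        ((0.9, 0.05, 0.05), "B", LS3, 0.95),
    ],
)
def test_probability_scores(probs, label, space, expected):
    assert inverse_probability_score(probs, label, space) == pytest.approx(expected)
    assert hinge_score(probs, label, space) == pytest.approx(expected)


def test_score_of_unknown_label_rejected():
    with pytest.raises(ValueError, match="not in label space"):
        inverse_probability_score((0.5, 0.5), "Z", ("A", "B"))


@pytest.mark.parametrize("a, b, expected", [(5, 3, 2), (4.5, 4.5, 0), (3, 5, 2)])
def test_absolute_error_score(a, b, expected):
    assert absolute_error_score(a, b) == expected


def test_absolute_error_rejects_non_finite():
    with pytest.raises(ValueError):
        absolute_error_score(math.nan, 0.0)


# -- conformal p-values -----------------------------------------------------


@pytest.mark.parametrize("test_score, expected", [(0.5, 0.2), (0.0, 1.0), (0.25, 0.6)])
def test_p_value_rank_formula(test_score, expected):
    assert conformal_p_value(np.array([0.1, 0.2, 0.3, 0.4]), test_score) == pytest.approx(expected)


def test_p_value_requires_references():
    with pytest.raises(RuntimeError):
        conformal_p_value(np.array([]), 0.5)


@given(
    refs=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
    score=st.floats(0, 1, allow_nan=False),
)
def test_p_value_range_property(refs, score):
    p = conformal_p_value(np.array(refs), score)
    n = len(refs)
    assert 1 / (n + 1) <= p <= 1.0


@given(
    refs=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
    s1=st.floats(0, 1, allow_nan=False),
    s2=st.floats(0, 1, allow_nan=False),
)
def test_p_value_monotone_in_score(refs, s1, s2):
    """A stranger instance can never earn a larger p-value."""
    lo, hi = min(s1, s2), max(s1, s2)
    arr = np.array(refs)
    assert conformal_p_value(arr, hi) <= conformal_p_value(arr, lo)


# -- prediction containers --------------------------------------------------


def test_region_thresholding_and_flags():
    region = PredictionRegion({"A": 0.9, "B": 0.04, "C": 0.2}, ConfidenceSpec(0.95))
    assert region.region == ("A", "C") and region.uncertain
    singleton = PredictionRegion({"A": 0.9, "B": 0.04, "C": 0.02}, ConfidenceSpec(0.95))
    assert singleton.singleton and not singleton.empty
    empty = PredictionRegion({"A": 0.03, "B": 0.04}, ConfidenceSpec(0.95))
    assert empty.empty and empty.uncertain and not empty.singleton


@given(
    p_values=st.dictionaries(st.sampled_from(list(LS3)), st.floats(0.001, 1.0), min_size=2, max_size=3),
    c1=st.floats(0.5, 0.99),
    c2=st.floats(0.5, 0.99),
)
def test_region_nesting_in_confidence(p_values, c1, c2):
    lo, hi = sorted((c1, c2))
    r_lo = PredictionRegion(dict(p_values), ConfidenceSpec(lo))
    r_hi = PredictionRegion(dict(p_values), ConfidenceSpec(hi))
    assert set(r_lo.region) <= set(r_hi.region)


def test_interval_arithmetic():
    iv = PredictionInterval(center=10.0, half_width=6.77)
    assert iv.lower == pytest.approx(3.23) and iv.upper == pytest.approx(16.77)
    assert iv.upper - iv.lower == pytest.approx(2 * 6.77)
    degenerate = PredictionInterval(center=2.0, half_width=0.0)
    assert degenerate.lower == degenerate.upper == 2.0
    unbounded = PredictionInterval(center=1.0, half_width=math.inf)
    assert unbounded.unbounded and unbounded.lower == -math.inf and unbounded.upper == math.inf


def test_score_vector_range_validation():
    with pytest.raises(ValueError):
        ScoreVector(np.array([1.2]), "hinge")
    with pytest.raises(ValueError):
        ScoreVector(np.array([-0.5]), "absolute_error")


# -- transductive prediction ------------------------------------------------


def test_tcp_hand_worked_example(three_point_cohort):
    """A at {0,1}, B at {10}, new point 9: by enumeration p(B)=1, p(A)=1/4."""
    adapter = ClassMeanDistanceAdapter(("A", "B"))
    measure = ClassMeanDistanceMeasure()
    region95 = tcp_predict(three_point_cohort, np.array([9.0]), adapter, measure, ConfidenceSpec(0.95))
    assert region95.p_values == {"A": 0.25, "B": 1.0}
    assert region95.region == ("A", "B") and region95.uncertain
    region70 = tcp_predict(three_point_cohort, np.array([9.0]), adapter, measure, ConfidenceSpec(0.70))
    assert region70.region == ("B",) and region70.singleton


# -- inductive classification ------------------------------------------------


def _icp_parts(cohort, seed=0):
    plan = make_split(cohort, (0.5, 0.25, 0.25), stratified=True, seed=seed)
    return (
        cohort.subset_by_ids(plan.train_ids),
        cohort.subset_by_ids(plan.calibration_ids),
        cohort.subset_by_ids(plan.test_ids),
    )


def test_icp_fit_scores_and_determinism(subtype_cohort):
    from sklearn.linear_model import LogisticRegression

    train, cal, _ = _icp_parts(subtype_cohort)
    adapter = SklearnClassifierAdapter(LogisticRegression(max_iter=1000), subtype_cohort.label_space)
    m1 = icp_fit(train, cal, adapter, HingeMeasure())
    m2 = icp_fit(train, cal, adapter, HingeMeasure())
    assert len(m1.calibration) == cal.n_samples
    np.testing.assert_array_equal(m1.calibration.scores, m2.calibration.scores)


def test_icp_fit_rejects_sample_leakage(subtype_cohort):
    train, cal, _ = _icp_parts(subtype_cohort)
    leaky = subtype_cohort.subset_by_ids(list(cal.sample_ids) + [train.sample_ids[0]])
    adapter = ClassMeanDistanceAdapter(subtype_cohort.label_space)
    with pytest.raises(LeakageError):
        icp_fit(train, leaky, adapter, ClassMeanDistanceMeasure())


def test_mondrian_p_value_counts_within_class():
    """Per-class references: score 0.15 under A against A:[0.1,0.2] gives 2/3."""
    adapter = ClassMeanDistanceAdapter(("A", "B"))
    adapter.fit(np.array([[0.0], [1.0], [10.0], [11.0]]), np.array(["A", "A", "B", "B"]))
    sv = ScoreVector(
        np.array([0.1, 0.2, 0.5, 0.6]),
        "hinge",
        per_label_category={"A": np.array([0, 1]), "B": np.array([2, 3])},
    )
    model = CalibrationModel(adapter=adapter, calibration=sv, n_cal=4, task="classification", measure=HingeMeasure())

    class FixedScoreMeasure(HingeMeasure):
        def score_matrix(self, adapter, X):
            return np.full((len(np.atleast_2d(X)), 2), 0.15)

    model.measure = FixedScoreMeasure()
    region = icp_classify(model, np.array([[0.5]]), ConfidenceSpec(0.5), mondrian=True)[0]
    assert region.p_values["A"] == pytest.approx(2 / 3)  # one of {0.1, 0.2} ≥ 0.15, plus correction
    assert region.p_values["B"] == pytest.approx(1.0)  # both of {0.5, 0.6} ≥ 0.15


def test_mondrian_requires_every_class_in_calibration(subtype_cohort):
    train, cal, test = _icp_parts(subtype_cohort)
    adapter = ClassMeanDistanceAdapter(subtype_cohort.label_space)
    model = icp_fit(train, cal, adapter, ClassMeanDistanceMeasure())
    model.calibration.per_label_category["C2"] = np.array([], dtype=int)
    with pytest.raises(CalibrationCoverageError):
        icp_classify(model, test.features, ConfidenceSpec(0.9), mondrian=True)


def test_mondrian_per_class_coverage_under_label_shift(subtype_cohort):
    """Label-conditional p-values keep per-class validity when the test
    class mix differs sharply from calibration."""
    train, cal, test = _icp_parts(subtype_cohort, seed=3)
    adapter = ClassMeanDistanceAdapter(subtype_cohort.label_space)
    model = icp_fit(train, cal, adapter, ClassMeanDistanceMeasure())
    # resample test towards the rare class to induce label shift
    rng = np.random.default_rng(0)
    labels = test.labels.astype(str)
    weights = np.where(labels == "C2", 5.0, 1.0)
    idx = rng.choice(test.n_samples, size=400, replace=True, p=weights / weights.sum())
    X, y = test.features[idx], labels[idx]
    regions = icp_classify(model, X, ConfidenceSpec(0.85), mondrian=True)
    for lab in subtype_cohort.label_space:
        mask = y == lab
        cov = np.mean([lab in r for r, m in zip(regions, mask) if m])
        n = mask.sum()
        assert cov >= 0.85 - 3 * np.sqrt(0.85 * 0.15 / n)


# -- inductive regression ----------------------------------------------------


class _ConstantPredictor:
    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), 10.0)


def _regression_model(scores):
    sv = ScoreVector(np.asarray(scores, dtype=float), "absolute_error")
    return CalibrationModel(
        adapter=_ConstantPredictor(), calibration=sv, n_cal=len(scores), task="regression",
        measure=AbsoluteErrorMeasure(),
    )


@pytest.mark.parametrize(
    "scores, confidence, expected",
    [
        (range(1, 10), 0.9, 9.0),
        (range(1, 10), 0.5, 5.0),
        ([1, 2, 3, 4], 0.95, math.inf),
    ],
)
def test_regression_quantile_order_statistic(scores, confidence, expected):
    q = icp_regress_quantile(_regression_model(list(scores)), ConfidenceSpec(confidence))
    assert q == expected


def test_regression_intervals_share_half_width_and_flag_unbounded():
    model = _regression_model(range(1, 10))
    ivs = icp_regress_predict(model, np.zeros((3, 1)), ConfidenceSpec(0.9))
    assert all(iv.half_width == 9.0 and iv.center == 10.0 for iv in ivs)
    unbounded = icp_regress_predict(_regression_model([1, 2, 3, 4]), np.zeros((1, 1)), ConfidenceSpec(0.95))[0]
    assert unbounded.unbounded


def test_regression_half_width_nested_in_confidence():
    model = _regression_model(np.linspace(0.1, 12.0, 60))
    widths = [icp_regress_quantile(model, ConfidenceSpec(c)) for c in (0.5, 0.85, 0.9, 0.95)]
    assert widths == sorted(widths)


def test_noiseless_response_with_perfect_learner_gives_zero_width(skewed_regression_cohort):
    """A learner that reproduces the response exactly leaves no residual."""

    class Oracle:
        def __init__(self, mapping):
            self.mapping = mapping

        def predict(self, X):
            return np.array([self.mapping[tuple(row)] for row in np.atleast_2d(X)])

    ds = skewed_regression_cohort
    mapping = {tuple(row): y for row, y in zip(ds.features, ds.labels)}
    model = CalibrationModel(
        adapter=Oracle(mapping),
        calibration=ScoreVector(np.zeros(100), "absolute_error"),
        n_cal=100,
        task="regression",
        measure=AbsoluteErrorMeasure(),
    )
    for c in (0.85, 0.9, 0.95):
        assert icp_regress_quantile(model, ConfidenceSpec(c)) == 0.0
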