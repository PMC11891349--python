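"""End-to-end conformalized pipelines and their file outputs.

Three study designs are wired up:

* ``binary_tcp`` — small two-class cohort: MRMR feature selection,
  80/20 train/test split, grid-tuned SVM, transductive conformal
  regions per test patient, error-detection against the bare model.
* ``multiclass_icp`` — three-subtype cohort: MRMR, 60/20/20
  train/calibration/test split, gradient-boosted classifier, inductive
  conformal regions (optionally Mondrian), region-composition
  tabulation, and — when an external cohort is supplied — an MMD shift
  audit plus a second coverage report on the external data.
* ``regression_icp`` — continuous drug-response cohort: log-IQR
  outlier management, MRMR, random-forest point predictions wrapped in
  split-conformal intervals at each configured confidence level.

Every run writes a config echo (JSON), a prediction table (TSV), a
coverage report (JSON) and a plain-text log carrying the seeds, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier, XGBRegressor

from cpgen.adapters import SklearnClassifierAdapter, SklearnRegressorAdapter
from cpgen.conformal import (
    ConfidenceSpec,
    get_measure,
    icp_classify,
    icp_fit,
    icp_regress_predict,
    icp_regress_quantile,
    intervals_to_frame,
    regions_to_frame,
    tcp_predict,
)
from cpgen.datasets import LabeledDataset, read_expression_table
from cpgen.evaluation import CoverageReport, empirical_coverage
from cpgen.exceptions import SpecificationError, TaskError
from cpgen.preprocessing import make_split, manage_outliers, mrmr_select
from cpgen.shift import mmd_permutation_test
from cpgen.synthetic import GeneratorSpec, generate_classification, generate_regression

#: label marking samples without a subtype call; excluded from training
#: and calibration, they receive prediction regions only.
UNCLASSIFIED_LABEL = "UNC"

#: hyperparameter grids for the grid-searched model families
MODEL_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"estimator__C": [0.1, 1.0, 10.0], "estimator__kernel": ["linear", "rbf"]},
    "gbdt": {"max_depth": [2, 3], "learning_rate": [0.1, 0.3]},
    "random_forest": {"max_depth": [None, 8]},
    "logistic": {"C": [0.1, 1.0, 10.0]},
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run; YAML keys match field names."""

    task: str
    input: str | None = None
    external_input: str | None = None
    generator: dict[str, Any] | None = None
    model: str = "svm"
    measure: str = "inverse_probability"
    confidence_levels: tuple[float, ...] = (0.95,)
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    mrmr_k: int = 20
    mondrian: bool = False
    grid_search: bool = True
    n_permutations: int = 199
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        known = {"binary_tcp", "multiclass_icp", "regression_icp", "shift_audit", "simulate"}
        if self.task not in known:
            raise SpecificationError(f"unknown task {self.task!r}; known: {sorted(known)}")
        self.confidence_levels = tuple(float(c) for c in self.confidence_levels)
        if not self.confidence_levels or any(not 0 < c < 1 for c in self.confidence_levels):
            raise SpecificationError("confidence_levels must be non-empty, each in (0, 1)")
        self.split_fractions = tuple(float(f) for f in self.split_fractions)
        if self.task == "binary_tcp" and self.split_fractions[1] > 0:
            raise SpecificationError("binary_tcp is transductive: calibration fraction must be 0")
        if self.model not in MODEL_GRIDS:
            raise SpecificationError(f"unknown model {self.model!r}; known: {sorted(MODEL_GRIDS)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _build_estimator(model: str, task: str, seed: int):
    if task == "classification":
        if model == "svm":
            # probability estimates via sigmoid calibration over CV folds
            return CalibratedClassifierCV(SVC(random_state=seed), ensemble=False)
        if model == "gbdt":
            return XGBClassifier(
                n_estimators=50, max_depth=3, learning_rate=0.3, tree_method="hist",
                n_jobs=1, random_state=seed, verbosity=0,
            )
        if model == "random_forest":
            return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        if model == "logistic":
            return LogisticRegression(max_iter=2000)
    else:
        if model == "random_forest":
            return RandomForestRegressor(n_estimators=100, random_state=seed, n_jobs=1)
        if model == "gbdt":
            return XGBRegressor(
                n_estimators=100, max_depth=3, tree_method="hist", n_jobs=1,
                random_state=seed, verbosity=0,
            )
    raise SpecificationError(f"model {model!r} unsupported for {task}")


def _tune_estimator(estimator, grid: dict, X: np.ndarray, y: np.ndarray, seed: int):
    """5-fold seeded grid search on the training portion only."""
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(estimator, grid, cv=cv, n_jobs=1)
    codes = pd.factorize(np.asarray(y, dtype=str), sort=True)[0]
    search.fit(X, codes)
    return search.best_estimator_, search.best_params_


def _load_classification(config: PipelineConfig) -> LabeledDataset:
    if config.input is not None:
        return read_expression_table(config.input)
    if config.generator is not None:
        spec = GeneratorSpec(**{**config.generator, "seed": config.generator.get("seed", config.seed)})
        return generate_classification(spec)
    raise SpecificationError("need either an input path or a generator spec")


def _load_regression(config: PipelineConfig) -> LabeledDataset:
    if config.input is not None:
        return read_expression_table(config.input)
    if config.generator is not None:
        spec = GeneratorSpec(**{**config.generator, "seed": config.generator.get("seed", config.seed)})
        return generate_regression(spec)
    raise SpecificationError("need either an input path or a generator spec")


def _write_outputs(
    config: PipelineConfig,
    predictions: pd.DataFrame,
    report: dict,
    log_lines: list[str],
) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")


# ---------------------------------------------------------------------------
# binary transductive pipeline
# ---------------------------------------------------------------------------


@dataclass
class BinaryTCPResult:
    report: CoverageReport
    predictions: pd.DataFrame
    selected_features: list[str]
    best_params: dict | None


def run_binary_tcp(config: PipelineConfig) -> BinaryTCPResult:
    """Transductive conformal prediction over a small binary cohort."""
    dataset = _load_classification(config)
    if len(dataset.label_space) != 2:
        raise TaskError(f"binary_tcp requires 2 classes, got {len(dataset.label_space)}")
    log = [f"task=binary_tcp seed={config.seed}", f"n_samples={dataset.n_samples} n_features={dataset.n_features}"]

    selected = mrmr_select(dataset, min(config.mrmr_k, dataset.n_features))
    dataset = dataset.select_features(selected)
    log.append(f"mrmr_k={len(selected)}")

    plan = make_split(dataset, config.split_fractions, stratified=True, seed=config.seed)
    train = dataset.subset_by_ids(plan.train_ids)
    test = dataset.subset_by_ids(plan.test_ids)
    log.append(f"split train={train.n_samples} test={test.n_samples} split_seed={config.seed}")

    estimator = _build_estimator(config.model, "classification", config.seed)
    best_params = None
    if config.grid_search:
        estimator, best_params = _tune_estimator(
            estimator, MODEL_GRIDS[config.model], train.features, train.labels, config.seed
        )
        log.append(f"grid_search best_params={best_params}")

    adapter = SklearnClassifierAdapter(estimator, dataset.label_space)
    base = adapter.clone().fit(train.features, train.labels)
    base_predictions = base.predict(test.features)

    measure = get_measure(config.measure)
    conf = ConfidenceSpec(config.confidence_levels[0])
    regions = [
        tcp_predict(train, test.features[i], adapter, measure, conf)
        for i in range(test.n_samples)
    ]
    report = CoverageReport.from_predictions(regions, test.labels, base_predictions)
    predictions = regions_to_frame(test.sample_ids, regions)
    predictions.insert(1, "base_prediction", base_predictions)
    predictions.insert(2, "truth", test.labels)
    log.append(f"confidence={conf.confidence}")
    _write_outputs(config, predictions, {"internal": report.to_dict()}, log)
    return BinaryTCPResult(report, predictions, selected, best_params)


# ---------------------------------------------------------------------------
# multiclass inductive pipeline with shift audit
# ---------------------------------------------------------------------------


@dataclass
class MulticlassICPResult:
    reports: dict[str, CoverageReport]
    predictions: pd.DataFrame
    region_composition: dict[str, dict[str, int]]
    shift_test: dict | None
    unclassified: pd.DataFrame | None
    selected_features: list[str]


def _region_composition(regions) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in regions:
        key = "{" + ",".join(r.region) + "}"
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))


def _split_off_unclassified(dataset: LabeledDataset) -> tuple[LabeledDataset, LabeledDataset | None]:
    labels = dataset.labels.astype(str)
    mask = labels == UNCLASSIFIED_LABEL
    if not mask.any():
        return dataset, None
    space = tuple(lab for lab in dataset.label_space if lab != UNCLASSIFIED_LABEL)
    classified = LabeledDataset(
        features=dataset.features[~mask],
        labels=labels[~mask],
        sample_ids=[s for s, m in zip(dataset.sample_ids, mask) if not m],
        feature_ids=list(dataset.feature_ids),
        label_space=space,
        metadata=dict(dataset.metadata),
    )
    unclassified = LabeledDataset(
        features=dataset.features[mask],
        labels=labels[mask],
        sample_ids=[s for s, m in zip(dataset.sample_ids, mask) if m],
        feature_ids=list(dataset.feature_ids),
        label_space=(UNCLASSIFIED_LABEL,),
        metadata=dict(dataset.metadata),
    )
    return classified, unclassified


def run_multiclass_icp(
    config: PipelineConfig,
    external: LabeledDataset | None = None,
    dataset: LabeledDataset | None = None,
) -> MulticlassICPResult:
    """Inductive conformal subtyping with an optional external-cohort audit.

    ``dataset``/``external`` may be passed in memory; otherwise they are
    loaded from ``config.input`` / ``config.external_input`` (TSV paths)
    or generated.  Samples labelled ``UNC`` are excluded from training
    and calibration and tabulated separately.
    """
    if dataset is None:
        dataset = _load_classification(config)
    dataset, unclassified = _split_off_unclassified(dataset)
    if len(dataset.label_space) < 3:
        raise TaskError(f"multiclass_icp requires ≥3 classes, got {len(dataset.label_space)}")
    if external is None and config.external_input is not None:
        external = read_expression_table(config.external_input)
    if external is not None:
        ext_classified, _ = _split_off_unclassified(external)
        if ext_classified.label_space != dataset.label_space:
            raise ValueError(
                f"label_space mismatch: {ext_classified.label_space} vs {dataset.label_space}"
            )
        external = ext_classified
    log = [f"task=multiclass_icp seed={config.seed}", f"n_samples={dataset.n_samples}"]

    selected = mrmr_select(dataset, min(config.mrmr_k, dataset.n_features))
    dataset = dataset.select_features(selected)
    log.append(f"mrmr_k={len(selected)}")

    plan = make_split(dataset, config.split_fractions, stratified=True, seed=config.seed)
    train = dataset.subset_by_ids(plan.train_ids)
    cal = dataset.subset_by_ids(plan.calibration_ids)
    test = dataset.subset_by_ids(plan.test_ids)
    log.append(f"split train={train.n_samples} cal={cal.n_samples} test={test.n_samples}")

    estimator = _build_estimator(config.model, "classification", config.seed)
    best_params = None
    if config.grid_search:
        estimator, best_params = _tune_estimator(
            estimator, MODEL_GRIDS[config.model], train.features, train.labels, config.seed
        )
        log.append(f"grid_search best_params={best_params}")
    adapter = SklearnClassifierAdapter(estimator, dataset.label_space)

    measure = get_measure(config.measure)
    model = icp_fit(train, cal, adapter, measure)
    conf = ConfidenceSpec(config.confidence_levels[0])

    base_internal = model.adapter.predict(test.features)
    internal_regions = icp_classify(model, test.features, conf, mondrian=config.mondrian)
    reports = {"internal": CoverageReport.from_predictions(internal_regions, test.labels, base_internal)}
    composition = {"internal": _region_composition(internal_regions)}
    predictions = regions_to_frame(test.sample_ids, internal_regions)
    predictions.insert(1, "cohort", "internal")
    predictions.insert(2, "base_prediction", base_internal)
    predictions.insert(3, "truth", test.labels)

    shift_test = None
    if external is not None:
        external_sel = external.select_features(selected)
        base_external = model.adapter.predict(external_sel.features)
        external_regions = icp_classify(model, external_sel.features, conf, mondrian=config.mondrian)
        reports["external"] = CoverageReport.from_predictions(
            external_regions, external_sel.labels, base_external
        )
        composition["external"] = _region_composition(external_regions)
        ext_frame = regions_to_frame(external_sel.sample_ids, external_regions)
        ext_frame.insert(1, "cohort", "external")
        ext_frame.insert(2, "base_prediction", base_external)
        ext_frame.insert(3, "truth", external_sel.labels)
        predictions = pd.concat([predictions, ext_frame], ignore_index=True)
        shift_test = mmd_permutation_test(
            dataset.features, external_sel.features,
            n_permutations=config.n_permutations, seed=config.seed,
        ).to_dict()
        log.append(f"mmd={shift_test['mmd']:.6g} p={shift_test['p_value']:.4g}")

    unc_frame = None
    if unclassified is not None:
        unc_sel = unclassified.select_features(selected)
        unc_regions = icp_classify(model, unc_sel.features, conf, mondrian=config.mondrian)
        unc_frame = regions_to_frame(unc_sel.sample_ids, unc_regions)
        composition["unclassified"] = _region_composition(unc_regions)
        log.append(f"unclassified n={unc_sel.n_samples}")

    payload = {
        "reports": {k: v.to_dict() for k, v in reports.items()},
        "region_composition": composition,
        "shift_test": shift_test,
        "best_params": best_params,
    }
    _write_outputs(config, predictions, payload, log)
    return MulticlassICPResult(reports, predictions, composition, shift_test, unc_frame, selected)


# ---------------------------------------------------------------------------
# regression inductive pipeline
# ---------------------------------------------------------------------------


@dataclass
class RegressionICPResult:
    summary: pd.DataFrame  # one row per confidence: half_width, coverage
    predictions: pd.DataFrame
    removed_outliers: list[str]
    selected_features: list[str]
    mse: float
    r2: float


def run_regression_icp(config: PipelineConfig) -> RegressionICPResult:
    """Split-conformal intervals around a point regressor's predictions."""
    dataset = _load_regression(config)
    if dataset.task != "regression":
        raise TaskError("regression_icp requires a continuous response")
    log = [f"task=regression_icp seed={config.seed}", f"n_samples={dataset.n_samples}"]

    dataset, removed = manage_outliers(dataset)
    log.append(f"outliers_removed={len(removed)}")
    selected = mrmr_select(dataset, min(config.mrmr_k, dataset.n_features))
    dataset = dataset.select_features(selected)
    log.append(f"mrmr_k={len(selected)}")

    plan = make_split(dataset, config.split_fractions, stratified=False, seed=config.seed)
    train = dataset.subset_by_ids(plan.train_ids)
    cal = dataset.subset_by_ids(plan.calibration_ids)
    test = dataset.subset_by_ids(plan.test_ids)
    log.append(f"split train={train.n_samples} cal={cal.n_samples} test={test.n_samples}")

    adapter = SklearnRegressorAdapter(_build_estimator(config.model, "regression", config.seed))
    measure = get_measure("absolute_error")
    model = icp_fit(train, cal, adapter, measure)

    point = model.adapter.predict(test.features)
    residuals = test.labels.astype(float) - point
    mse = float(np.mean(residuals**2))
    ss_tot = float(np.sum((test.labels - test.labels.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else float("nan")
    log.append(f"base mse={mse:.4f} r2={r2:.4f}")

    rows = []
    frames = []
    for level in config.confidence_levels:
        conf = ConfidenceSpec(level)
        half_width = icp_regress_quantile(model, conf)
        intervals = icp_regress_predict(model, test.features, conf)
        coverage = empirical_coverage(intervals, test.labels.astype(float))
        rows.append({"confidence": level, "half_width": half_width, "empirical_coverage": coverage})
        frame = intervals_to_frame(test.sample_ids, intervals)
        frame.insert(1, "confidence", level)
        frame["truth"] = test.labels
        frames.append(frame)
        log.append(f"confidence={level} half_width={half_width:.4f} coverage={coverage:.4f}")
    summary = pd.DataFrame(rows)
    predictions = pd.concat(frames, ignore_index=True)
    _write_outputs(
        config,
        predictions,
        {"summary": rows, "mse": mse, "r2": r2, "outliers_removed": removed},
        log,
    )
    return RegressionICPResult(summary, predictions, removed, selected, mse, r2)
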