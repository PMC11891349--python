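"""Feature selection, outlier management, splitting, exchangeability check.

MRMR (maximum relevance, minimum redundancy) greedily selects features
maximising ``relevance(f, y) − mean_{s∈selected} |corr(f, s)|`` — the
difference (MRMR-D) criterion with F-statistic relevance for
categorical outcomes and absolute Pearson correlation for continuous
ones.  Outlier management drops samples whose log-response falls
beyond 3×IQR from the log-scale quartiles.  Splitting produces
disjoint, optionally class-stratified train/calibration/test plans.
The exchangeability diagnostic reuses the MMD permutation test on
random halves of a cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.feature_selection import f_classif

from cpgen.datasets import LabeledDataset
from cpgen.exceptions import TaskError
from cpgen.shift import mmd_permutation_test


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint sample-id sets covering a dataset exactly."""

    train_ids: tuple[str, ...]
    calibration_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fractions: tuple[float, float, float]
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.calibration_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split parts must be pairwise disjoint")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "train_ids": list(self.train_ids),
                "calibration_ids": list(self.calibration_ids),
                "test_ids": list(self.test_ids),
                "fractions": list(self.fractions),
                "stratified": self.stratified,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


# ---------------------------------------------------------------------------
# MRMR feature selection
# ---------------------------------------------------------------------------


def _relevance(dataset: LabeledDataset) -> np.ndarray:
    X = dataset.features
    if dataset.task == "classification":
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat, _ = f_classif(X, dataset.labels)
        return np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    y = dataset.labels.astype(float)
    sd_x = X.std(axis=0)
    sd_y = y.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = (X - X.mean(axis=0)).T @ (y - y.mean()) / len(y)
        corr = np.where((sd_x > 0) & (sd_y > 0), cov / (sd_x * sd_y), 0.0)
    return np.abs(corr)


def mrmr_select(dataset: LabeledDataset, k: int) -> list[str]:
    """Greedy MRMR-D selection of ``k`` features, in selection order.

    Constant features have zero relevance (and zero redundancy
    contribution), so they are never preferred over an informative
    non-constant feature.
    """
    p = dataset.n_features
    if not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    X = dataset.features
    relevance = _relevance(dataset)
    sd = X.std(axis=0)
    centered = X - X.mean(axis=0)

    selected: list[int] = [int(np.argmax(relevance))]
    redundancy_sum = np.zeros(p)
    available = np.ones(p, dtype=bool)
    available[selected[0]] = False
    while len(selected) < k:
        last = selected[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = centered.T @ centered[:, last] / len(X)
            corr = np.where((sd > 0) & (sd[last] > 0), cov / (sd * sd[last]), 0.0)
        redundancy_sum += np.abs(corr)
        criterion = relevance - redundancy_sum / len(selected)
        criterion[~available] = -np.inf
        nxt = int(np.argmax(criterion))
        selected.append(nxt)
        available[nxt] = False
    return [dataset.feature_ids[j] for j in selected]


# ---------------------------------------------------------------------------
# outlier management
# ---------------------------------------------------------------------------


def manage_outliers(dataset: LabeledDataset, iqr_multiplier: float = 3.0) -> tuple[LabeledDataset, list[str]]:
    """Drop samples whose log-response lies beyond ``iqr_multiplier``×IQR.

    Fences are ``[Q1 − m·IQR, Q3 + m·IQR]`` on the natural-log response
    (responses must be strictly positive).  Returns the filtered
    dataset and the removed sample ids; a pass with no outliers is the
    identity, and the operation is idempotent whenever the surviving
    quartile fences still contain all survivors.
    """
    if dataset.task != "regression":
        raise TaskError("manage_outliers requires a regression dataset")
    y = dataset.labels.astype(float)
    if np.any(y <= 0):
        raise ValueError("log-scale outlier fencing requires strictly positive responses")
    log_y = np.log(y)
    q1, q3 = np.percentile(log_y, [25, 75])
    iqr = q3 - q1
    keep = (log_y >= q1 - iqr_multiplier * iqr) & (log_y <= q3 + iqr_multiplier * iqr)
    removed = [sid for sid, k in zip(dataset.sample_ids, keep) if not k]
    if not removed:
        return dataset, []
    return dataset.subset(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    quotas = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = np.argsort([-(q - c) for q, c in zip(quotas, counts)], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def make_split(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float],
    stratified: bool = False,
    seed: int = 0,
) -> SplitPlan:
    """Seeded train/calibration/test partition of the sample ids.

    Part sizes follow the largest-remainder rule, so a stratified split
    preserves per-class proportions within ±1 sample.  A zero fraction
    yields an empty part (e.g. no calibration set for transductive
    prediction).
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    n_parts = sum(f > 0 for f in fractions)
    parts: list[list[str]] = [[], [], []]

    def allocate(indices: np.ndarray) -> None:
        shuffled = rng.permutation(indices)
        counts = _largest_remainder(len(indices), fractions)
        start = 0
        for part, count in zip(parts, counts):
            part.extend(dataset.sample_ids[i] for i in shuffled[start : start + count])
            start += count

    if stratified:
        if dataset.task != "classification":
            raise TaskError("stratified splitting requires a classification dataset")
        labels = dataset.labels.astype(str)
        for lab in dataset.label_space:
            idx = np.flatnonzero(labels == lab)
            if 0 < len(idx) < n_parts:
                raise ValueError(f"class {lab!r} has {len(idx)} samples, fewer than {n_parts} split parts")
            allocate(idx)
    else:
        allocate(np.arange(dataset.n_samples))

    return SplitPlan(
        train_ids=tuple(parts[0]),
        calibration_ids=tuple(parts[1]),
        test_ids=tuple(parts[2]),
        fractions=fractions,
        stratified=stratified,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exchangeability diagnostic
# ---------------------------------------------------------------------------


def exchangeability_check(
    dataset: LabeledDataset,
    n_splits: int = 10,
    seed: int = 0,
    n_permutations: int = 99,
) -> float:
    """Median MMD permutation p-value over random half-splits.

    Under exchangeability any random half of the cohort is distributed
    like the other, so a small median p-value is evidence against the
    i.i.d./exchangeability assumption the conformal guarantees rest on.
    This is a diagnostic, not a calibrated test of a sharp null.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be at least 1")
    n = dataset.n_samples
    if n < 4:
        raise ValueError("dataset too small for a half-split diagnostic")
    rng = np.random.default_rng(seed)
    p_values = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        result = mmd_permutation_test(
            dataset.features[perm[:half]],
            dataset.features[perm[half:]],
            n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        p_values.append(result.p_value)
    return float(np.median(p_values))
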