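"""Coverage and adaptivity metrics for conformal predictors.

Empirical coverage is the frequency of the true outcome inside the
prediction region/interval; the UNC rate is the fraction of non-singleton
(uncertain) regions, empty regions included; the error-detection rate is,
among the base model's misclassifications, the fraction the conformal
layer flags as uncertain; size-stratified coverage (SSC) tabulates
coverage per region size as an adaptivity diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cpgen.conformal import (
    ConfidenceSpec,
    NonconformityMeasure,
    PredictionInterval,
    PredictionRegion,
    icp_classify,
    icp_fit,
)
from cpgen.datasets import LabeledDataset


def empirical_coverage(
    regions: Sequence[PredictionRegion] | Sequence[PredictionInterval],
    truths: Sequence,
) -> float:
    """Fraction of samples whose true label/value lies in the region/interval."""
    if len(regions) != len(truths):
        raise ValueError(f"{len(regions)} regions but {len(truths)} truths")
    if not regions:
        raise ValueError("empty evaluation set")
    return float(np.mean([t in r for r, t in zip(regions, truths)]))


def unc_rate(regions: Sequence[PredictionRegion]) -> float:
    """Fraction of uncertain (non-singleton, including empty) regions."""
    if not regions:
        raise ValueError("empty region list")
    return float(np.mean([r.uncertain for r in regions]))


def error_detection(
    base_predictions: Sequence[str],
    regions: Sequence[PredictionRegion],
    truths: Sequence[str],
) -> float | None:
    """Among base-model errors, the fraction flagged uncertain by CP.

    Returns ``None`` (undefined, not zero) when the base model makes no
    errors, so a perfect base model never reads as perfect detection.
    """
    if not (len(base_predictions) == len(regions) == len(truths)):
        raise ValueError("length mismatch")
    flagged = errors = 0
    for pred, region, truth in zip(base_predictions, regions, truths):
        if str(pred) != str(truth):
            errors += 1
            flagged += region.uncertain
    if errors == 0:
        return None
    return flagged / errors


def size_stratified_coverage(
    regions: Sequence[PredictionRegion],
    truths: Sequence[str],
) -> dict[int, tuple[int, float]]:
    """Per-region-size (count, coverage); zero-count strata omitted."""
    if len(regions) != len(truths):
        raise ValueError("length mismatch")
    strata: dict[int, list[bool]] = {}
    for region, truth in zip(regions, truths):
        strata.setdefault(len(region.region), []).append(truth in region)
    return {size: (len(hits), float(np.mean(hits))) for size, hits in sorted(strata.items())}


@dataclass
class CoverageReport:
    """Summary of a conformal evaluation run.

    Invariants: ``empirical_coverage + error_rate = 1``;
    ``unc_rate + singleton_rate = 1``; SSC counts sum to ``n_test``.
    """

    n_test: int
    empirical_coverage: float
    unc_rate: float
    error_detection: float | None
    ssc: dict[int, tuple[int, float]]
    error_rate: float = field(init=False)
    singleton_rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.error_rate = 1.0 - self.empirical_coverage
        self.singleton_rate = 1.0 - self.unc_rate
        if sum(c for c, _ in self.ssc.values()) != self.n_test:
            raise ValueError("SSC counts must sum to n_test")

    @classmethod
    def from_predictions(
        cls,
        regions: Sequence[PredictionRegion],
        truths: Sequence[str],
        base_predictions: Sequence[str] | None = None,
    ) -> "CoverageReport":
        det = error_detection(base_predictions, regions, truths) if base_predictions is not None else None
        return cls(
            n_test=len(regions),
            empirical_coverage=empirical_coverage(regions, truths),
            unc_rate=unc_rate(regions),
            error_detection=det,
            ssc=size_stratified_coverage(regions, truths),
        )

    def to_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "empirical_coverage": self.empirical_coverage,
            "error_rate": self.error_rate,
            "unc_rate": self.unc_rate,
            "singleton_rate": self.singleton_rate,
            "error_detection": self.error_detection,
            "ssc": {str(k): {"count": c, "coverage": cov} for k, (c, cov) in self.ssc.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        """Human-readable one-per-line percentages (two decimals)."""
        det = "undefined" if self.error_detection is None else f"{100 * self.error_detection:.2f}%"
        lines = [
            f"n_test:             {self.n_test}",
            f"empirical coverage: {100 * self.empirical_coverage:.2f}%",
            f"error rate:         {100 * self.error_rate:.2f}%",
            f"UNC rate:           {100 * self.unc_rate:.2f}%",
            f"error detection:    {det}",
        ]
        for size, (count, cov) in self.ssc.items():
            lines.append(f"SSC size {size}: n={count}, coverage {100 * cov:.2f}%")
        return "\n".join(lines)


def repeated_split_coverage(
    dataset: LabeledDataset,
    adapter,
    measure: NonconformityMeasure,
    conf: ConfidenceSpec,
    n_repeats: int,
    seed: int,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    mondrian: bool = False,
) -> np.ndarray:
    """Coverage over fresh train/calibration/test splits.

    Each repeat draws a seeded split, fits an inductive conformal
    classifier, and records its empirical coverage on the test part;
    the spread of the returned vector reflects the Beta-law calibration
    variability plus test-sampling noise.
    """
    from cpgen.preprocessing import make_split

    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    rng = np.random.default_rng(seed)
    coverages = np.empty(n_repeats)
    for r in range(n_repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        plan = make_split(dataset, fractions, stratified=True, seed=split_seed)
        train = dataset.subset_by_ids(plan.train_ids)
        cal = dataset.subset_by_ids(plan.calibration_ids)
        test = dataset.subset_by_ids(plan.test_ids)
        model = icp_fit(train, cal, adapter, measure)
        regions = icp_classify(model, test.features, conf, mondrian=mondrian)
        coverages[r] = empirical_coverage(regions, test.labels)
    return coverages
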