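"""Synthetic expression cohorts for benchmarking conformal pipelines.

Three study designs are emulated, matching the statistical structure of
typical clinical expression cohorts:

* a small two-class responder/non-responder cohort (overlapping
  class-conditional profiles, tens of samples);
* a three-class molecular-subtyping cohort in which one subtype is well
  separated and the other two overlap (the MHG / GCB / ABC picture),
  optionally with a covariate-shifted sibling cohort standing in for an
  external validation series;
* a cell-line drug-response cohort whose continuous response is
  strongly right-skewed, spanning several orders of magnitude like IC50
  concentrations.

The model is deliberately simple — class-conditional Gaussians with
equal spherical covariance, standard-normal noise features, a
(log-)linear response — which is sufficient to exercise every property
of the conformal machinery while keeping expected behaviour derivable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from cpgen.datasets import LabeledDataset
from cpgen.exceptions import SpecificationError

#: fraction of the nominal separation kept between an overlapping pair;
#: at the default 3-SD separation this leaves the pair 2.1 SD apart — a
#: visible but partial overlap, like two subtypes touching in a PCA plot
OVERLAP_FRACTION = 0.7


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic cohort.

    ``separation`` is the between-class centroid displacement in units
    of the within-class standard deviation (``noise_sd``).  For
    regression (``class_proportions=None``) the response is a linear
    combination of the informative features with unit weights plus
    ``N(0, noise_sd²)`` noise, exponentiated when ``response_skew`` is
    set so the response is strictly positive and right-skewed.
    """

    n_samples: int
    n_features: int
    n_informative: int
    class_proportions: tuple[float, ...] | None = None
    separation: float = 2.0
    overlap_pair: tuple[int, int] | None = None
    noise_sd: float = 1.0
    response_skew: bool = False
    seed: int = 0
    #: seed for the structural draws (class centroid patterns); defaults
    #: to ``seed``.  Two specs sharing a structure_seed but differing in
    #: ``seed`` describe sibling cohorts: fresh samples from the same
    #: class-conditional distributions, as with an external validation
    #: series from the same population.
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_features <= 0 or self.n_informative <= 0:
            raise SpecificationError("n_samples, n_features, n_informative must be positive")
        if self.n_informative > self.n_features:
            raise SpecificationError(
                f"n_informative ({self.n_informative}) exceeds n_features ({self.n_features})"
            )
        if self.separation < 0:
            raise SpecificationError("separation must be non-negative")
        if self.noise_sd <= 0 and not (self.noise_sd == 0 and self.class_proportions is None):
            raise SpecificationError("noise_sd must be positive (zero allowed for regression only)")
        if self.class_proportions is not None:
            props = tuple(float(p) for p in self.class_proportions)
            if len(props) < 2:
                raise SpecificationError("need at least two classes")
            if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
                raise SpecificationError("class_proportions must be positive and sum to 1")
            object.__setattr__(self, "class_proportions", props)
            if self.overlap_pair is not None:
                i, j = self.overlap_pair
                if not (0 <= i < len(props) and 0 <= j < len(props)) or i == j:
                    raise SpecificationError("overlap_pair must index two distinct classes")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ShiftSpec:
    """A pure covariate shift: translate and rescale a feature subset.

    ``mean_shift=0`` with ``scale_factor=1`` is the identity map, so a
    null spec leaves the source distribution untouched.
    """

    mean_shift: float = 0.0
    scale_factor: float = 1.0
    fraction_shifted_features: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_shift < 0:
            raise SpecificationError("mean_shift must be non-negative")
        if self.scale_factor <= 0:
            raise SpecificationError("scale_factor must be positive")
        if not 0.0 <= self.fraction_shifted_features <= 1.0:
            raise SpecificationError("fraction_shifted_features must lie in [0, 1]")


def _class_centroids(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Class centroids over the informative features, ``(K, n_informative)``.

    Each class gets a ±1 sign pattern scaled so that two non-overlapping
    classes sit ~``separation·√2`` apart in within-class-SD units; an
    ``overlap_pair`` has its second member pulled to within
    ``OVERLAP_FRACTION·separation`` of the first.
    """
    k = len(spec.class_proportions)
    d = spec.n_informative
    signs = rng.choice([-1.0, 1.0], size=(k, d))
    # every informative feature must separate at least one class pair:
    # redraw any column whose signs coincide across all classes
    for f in range(d):
        while np.all(signs[:, f] == signs[0, f]):
            signs[:, f] = rng.choice([-1.0, 1.0], size=k)
    # and classes must have distinct patterns overall
    for a in range(1, k):
        while any(np.array_equal(signs[a], signs[b]) for b in range(a)):
            f = int(rng.integers(d))
            col = rng.choice([-1.0, 1.0], size=k)
            if not np.all(col == col[0]):
                signs[:, f] = col
    centroids = spec.separation * spec.noise_sd * signs / np.sqrt(d)
    if spec.overlap_pair is not None:
        i, j = spec.overlap_pair
        direction = rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        centroids[j] = centroids[i] + OVERLAP_FRACTION * spec.separation * spec.noise_sd * direction
    return centroids


def generate_classification(spec: GeneratorSpec) -> LabeledDataset:
    """Draw a class-conditional Gaussian cohort.

    Only the first ``n_informative`` features carry class signal; the
    rest are standard-normal noise.  Class sizes are multinomial draws
    from ``class_proportions``.  Labels are ``C0 … C{K-1}``.
    """
    if spec.class_proportions is None:
        raise SpecificationError("classification requires class_proportions")
    struct_seed = spec.seed if spec.structure_seed is None else spec.structure_seed
    centroids = _class_centroids(spec, np.random.default_rng(struct_seed))
    rng = np.random.default_rng(spec.seed)
    k = len(spec.class_proportions)
    counts = rng.multinomial(spec.n_samples, spec.class_proportions)

    X = rng.standard_normal((spec.n_samples, spec.n_features))
    y = np.empty(spec.n_samples, dtype=object)
    row = 0
    for cls in range(k):
        n_c = counts[cls]
        block = slice(row, row + n_c)
        X[block, : spec.n_informative] = centroids[cls] + spec.noise_sd * rng.standard_normal(
            (n_c, spec.n_informative)
        )
        y[block] = f"C{cls}"
        row += n_c
    order = rng.permutation(spec.n_samples)
    X, y = X[order], y[order]

    return LabeledDataset(
        features=X,
        labels=y.astype(str),
        sample_ids=[f"S{i:05d}" for i in range(spec.n_samples)],
        feature_ids=[f"G{j:05d}" for j in range(spec.n_features)],
        label_space=tuple(f"C{c}" for c in range(k)),
        metadata={
            "generator_spec": spec.to_dict(),
            "informative_features": [f"G{j:05d}" for j in range(spec.n_informative)],
        },
    )


def generate_regression(spec: GeneratorSpec) -> LabeledDataset:
    """Draw a continuous-response cohort.

    ``response = Σ informative features + N(0, noise_sd²)``, passed
    through ``exp`` when ``response_skew`` is set (log-normal response,
    strictly positive, heavy right tail).
    """
    if spec.class_proportions is not None:
        raise SpecificationError("regression forbids class_proportions")
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    linear = X[:, : spec.n_informative].sum(axis=1)
    if spec.noise_sd > 0:
        linear = linear + spec.noise_sd * rng.standard_normal(spec.n_samples)
    response = np.exp(linear) if spec.response_skew else linear
    return LabeledDataset(
        features=X,
        labels=response,
        sample_ids=[f"S{i:05d}" for i in range(spec.n_samples)],
        feature_ids=[f"G{j:05d}" for j in range(spec.n_features)],
        label_space=None,
        metadata={
            "generator_spec": spec.to_dict(),
            "informative_features": [f"G{j:05d}" for j in range(spec.n_informative)],
        },
    )


def apply_shift(dataset: LabeledDataset, shift: ShiftSpec) -> LabeledDataset:
    """Apply a pure covariate shift to a cohort; labels are untouched.

    A seeded random subset of ``fraction_shifted_features`` of the
    columns is transformed as ``x ↦ scale_factor·x + mean_shift``.
    """
    if dataset.n_samples == 0:
        raise SpecificationError("dataset is empty")
    rng = np.random.default_rng(shift.seed)
    p = dataset.n_features
    n_shift = int(round(shift.fraction_shifted_features * p))
    cols = rng.choice(p, size=n_shift, replace=False)
    X = dataset.features.copy()
    X[:, cols] = shift.scale_factor * X[:, cols] + shift.mean_shift
    meta = dict(dataset.metadata)
    meta["shift_spec"] = asdict(shift)
    return LabeledDataset(
        features=X,
        labels=dataset.labels.copy(),
        sample_ids=list(dataset.sample_ids),
        feature_ids=list(dataset.feature_ids),
        label_space=dataset.label_space,
        metadata=meta,
    )


# -- default cohorts for the three study designs --------------------------------------------
# Defaults mirror the three study designs: a 78-sample binary cohort
# (40 responders / 38 non-responders), a 1,032-sample three-subtype
# cohort (345 ABC, 517 GCB, 170 MHG) with a shifted 789-sample sibling,
# and a 765-cell-line skewed-response cohort.  Feature counts are scaled
# down from probe-level arrays to keep the benchmark desk-sized.


def binary_cohort_spec(seed: int = 0, n_features: int = 200, n_informative: int = 20) -> GeneratorSpec:
    return GeneratorSpec(
        n_samples=78,
        n_features=n_features,
        n_informative=n_informative,
        class_proportions=(40 / 78, 38 / 78),
        separation=2.5,
        noise_sd=1.0,
        seed=seed,
    )


def subtype_cohort_spec(
    seed: int = 0,
    n_samples: int = 1032,
    n_features: int = 200,
    n_informative: int = 20,
    separation: float = 3.0,
    structure_seed: int | None = None,
) -> GeneratorSpec:
    # C0=ABC, C1=GCB, C2=MHG; ABC and GCB overlap, MHG separable
    return GeneratorSpec(
        n_samples=n_samples,
        n_features=n_features,
        n_informative=n_informative,
        class_proportions=(345 / 1032, 517 / 1032, 170 / 1032),
        separation=separation,
        overlap_pair=(0, 1),
        noise_sd=1.0,
        seed=seed,
        structure_seed=structure_seed,
    )


def ic50_cohort_spec(seed: int = 0, n_samples: int = 765, n_features: int = 100, n_informative: int = 4) -> GeneratorSpec:
    # 4 unit-weight informative features + noise give log-response SD ≈ 2,
    # so the response spans ~5 orders of magnitude like IC50 concentrations
    return GeneratorSpec(
        n_samples=n_samples,
        n_features=n_features,
        n_informative=n_informative,
        class_proportions=None,
        noise_sd=0.5,
        response_skew=True,
        seed=seed,
    )
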