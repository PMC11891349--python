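import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cpgen.datasets import LabeledDataset
from cpgen.synthetic import GeneratorSpec, generate_classification, generate_regression

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("deterministic")


@pytest.fixture
def three_point_cohort() -> LabeledDataset:
    """The smallest hand-checkable binary cohort: A at {0,1}, B at {10}."""
    return LabeledDataset(
        features=np.array([[0.0], [1.0], [10.0]]),
        labels=np.array(["A", "A", "B"]),
        sample_ids=["s1", "s2", "s3"],
        feature_ids=["g1"],
        label_space=("A", "B"),
    )


@pytest.fixture(scope="session")
def binary_cohort() -> LabeledDataset:
    return generate_classification(
        GeneratorSpec(n_samples=120, n_features=30, n_informative=8, class_proportions=(0.5, 0.5), separation=2.5, seed=11)
    )


@pytest.fixture(scope="session")
def subtype_cohort() -> LabeledDataset:
    return generate_classification(
        GeneratorSpec(
            n_samples=400, n_features=40, n_informative=10,
            class_proportions=(0.35, 0.45, 0.2), separation=3.0, overlap_pair=(0, 1), seed=7,
        )
    )


@pytest.fixture(scope="session")
def skewed_regression_cohort() -> LabeledDataset:
    return generate_regression(
        GeneratorSpec(n_samples=400, n_features=20, n_informative=4, noise_sd=0.5, response_skew=True, seed=13)
    )
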