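"""End-to-end pipelines, their file outputs, and the command line."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from cpgen.cli import main as cli_main
from cpgen.datasets import write_expression_table
from cpgen.exceptions import SpecificationError, TaskError
from cpgen.pipelines import (
    PipelineConfig,
    run_binary_tcp,
    run_multiclass_icp,
    run_regression_icp,
)
from cpgen.synthetic import GeneratorSpec, ShiftSpec, apply_shift, generate_classification


def binary_config(tmp_path=None, **overrides):
    base = dict(
        task="binary_tcp",
        generator=dict(n_samples=80, n_features=40, n_informative=8, class_proportions=(0.5, 0.5), separation=2.5),
        model="logistic",
        measure="inverse_probability",
        confidence_levels=(0.95,),
        split_fractions=(0.8, 0.0, 0.2),
        mrmr_k=8,
        grid_search=False,
        seed=3,
    )
    base.update(overrides)
    if tmp_path is not None:
        base["output_dir"] = str(tmp_path)
    return PipelineConfig(**base)


def multiclass_config(**overrides):
    base = dict(
        task="multiclass_icp",
        generator=dict(
            n_samples=450, n_features=40, n_informative=10,
            class_proportions=(0.35, 0.45, 0.2), separation=3.0, overlap_pair=(0, 1),
        ),
        model="gbdt",
        measure="hinge",
        confidence_levels=(0.95,),
        split_fractions=(0.6, 0.2, 0.2),
        mrmr_k=10,
        grid_search=False,
        n_permutations=49,
        seed=5,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def regression_config(**overrides):
    base = dict(
        task="regression_icp",
        generator=dict(n_samples=500, n_features=30, n_informative=4, noise_sd=0.5, response_skew=True),
        model="random_forest",
        measure="absolute_error",
        confidence_levels=(0.85, 0.90, 0.95),
        split_fractions=(0.5, 0.25, 0.25),
        mrmr_k=6,
        grid_search=False,
        seed=7,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def test_binary_tcp_report_and_outputs(tmp_path):
    result = run_binary_tcp(binary_config(tmp_path))
    report = result.report
    assert report.n_test == 16
    assert 0.0 <= report.unc_rate <= 1.0
    # written artefacts sufficient to re-run
    for name in ("config.json", "predictions.tsv", "report.json", "run.log"):
        assert (tmp_path / name).exists()
    frame = pd.read_csv(tmp_path / "predictions.tsv", sep="\t")
    assert set(frame.columns) >= {"sample_id", "base_prediction", "truth", "p_C0", "p_C1", "region", "flag"}
    assert "seed=3" in (tmp_path / "run.log").read_text()


def test_binary_tcp_reruns_are_byte_identical(tmp_path):
    run_binary_tcp(binary_config(tmp_path))
    snapshot = {p.name: p.read_bytes() for p in tmp_path.iterdir()}
    run_binary_tcp(binary_config(tmp_path))
    for p in tmp_path.iterdir():
        assert p.read_bytes() == snapshot[p.name], p.name


def test_binary_tcp_flagged_base_error_counts_toward_detection(tmp_path):
    result = run_binary_tcp(binary_config(tmp_path))
    df = result.predictions
    errors = df[df.base_prediction != df.truth]
    if len(errors):
        flagged = (errors.flag == "uncertain").sum()
        assert result.report.error_detection == pytest.approx(flagged / len(errors))
    else:
        assert result.report.error_detection is None


def test_binary_tcp_rejects_multiclass_input():
    cfg = binary_config()
    cfg.generator["class_proportions"] = (0.3, 0.3, 0.4)
    with pytest.raises(TaskError):
        run_binary_tcp(cfg)


def test_config_forbids_calibration_fraction_for_tcp():
    with pytest.raises(SpecificationError):
        binary_config(split_fractions=(0.6, 0.2, 0.2))


def test_multiclass_icp_internal_only_has_no_shift_test():
    result = run_multiclass_icp(multiclass_config())
    assert result.shift_test is None
    assert set(result.reports) == {"internal"}


def test_multiclass_icp_overlap_pair_dominates_double_regions():
    """Non-singleton regions concentrate on the overlapping pair C0/C1."""
    result = run_multiclass_icp(multiclass_config())
    comp = result.region_composition["internal"]
    pair = comp.get("{C0,C1}", 0)
    others = comp.get("{C0,C2}", 0) + comp.get("{C1,C2}", 0)
    assert pair > others


def test_multiclass_icp_with_shifted_external_cohort():
    # a sibling of the internal cohort (same structure seed), then shifted
    ext = generate_classification(
        GeneratorSpec(
            n_samples=300, n_features=40, n_informative=10,
            class_proportions=(0.35, 0.45, 0.2), separation=3.0, overlap_pair=(0, 1),
            seed=99, structure_seed=5,
        )
    )
    ext = apply_shift(ext, ShiftSpec(mean_shift=1.0, fraction_shifted_features=0.5, seed=1))
    result = run_multiclass_icp(multiclass_config(), external=ext)
    assert set(result.reports) == {"internal", "external"}
    assert result.shift_test is not None
    assert result.shift_test["p_value"] <= 0.05
    assert result.reports["external"].unc_rate >= result.reports["internal"].unc_rate


def test_multiclass_icp_rejects_label_space_mismatch():
    ext = generate_classification(GeneratorSpec(100, 40, 10, (0.5, 0.5), seed=2))
    with pytest.raises(ValueError, match="label_space mismatch"):
        run_multiclass_icp(multiclass_config(), external=ext)


def test_multiclass_icp_unclassified_samples_get_regions_only():
    from cpgen.datasets import LabeledDataset

    ds = generate_classification(
        GeneratorSpec(
            n_samples=450, n_features=40, n_informative=10,
            class_proportions=(0.35, 0.45, 0.2), separation=3.0, overlap_pair=(0, 1), seed=5,
        )
    )
    labels = ds.labels.astype(object)
    labels[:40] = "UNC"
    with_unc = LabeledDataset(
        ds.features, labels.astype(str), ds.sample_ids, ds.feature_ids,
        label_space=("C0", "C1", "C2", "UNC"),
    )
    cfg = multiclass_config()
    cfg.generator = None
    result = run_multiclass_icp(cfg, dataset=with_unc)
    assert result.unclassified is not None and len(result.unclassified) == 40
    assert "unclassified" in result.region_composition
    # excluded from training: internal report covers only labelled samples
    assert result.reports["internal"].n_test == pytest.approx(0.2 * 410, abs=1)


def test_regression_icp_half_widths_nested_and_coverage_tracks_confidence():
    result = run_regression_icp(regression_config())
    widths = result.summary.half_width.to_numpy()
    assert np.all(np.diff(widths) >= 0)
    cov = result.summary.empirical_coverage.to_numpy()
    n_test = (result.predictions.confidence == 0.85).sum()
    slack = 3 * np.sqrt(0.95 * 0.05 / n_test) + 0.02
    for c, got in zip(result.summary.confidence, cov):
        assert got >= c - max(slack, 0.05)


def test_regression_icp_removes_injected_outlier(tmp_path):
    from cpgen.datasets import LabeledDataset
    from cpgen.synthetic import generate_regression

    ds = generate_regression(
        GeneratorSpec(n_samples=300, n_features=30, n_informative=4, noise_sd=0.5, response_skew=True, seed=7)
    )
    labels = ds.labels.copy()
    labels[0] = 1e9
    spiked = LabeledDataset(ds.features, labels, ds.sample_ids, ds.feature_ids, None)
    path = tmp_path / "spiked.tsv"
    write_expression_table(spiked, path)
    cfg = regression_config(generator=None, input=str(path))
    result = run_regression_icp(cfg)
    assert ds.sample_ids[0] in result.removed_outliers


# -- command line ------------------------------------------------------------


def test_cli_simulate_and_mmd_roundtrip(tmp_path):
    runner = CliRunner()
    a = tmp_path / "a.tsv"
    b = tmp_path / "b.tsv"
    for path, seed in ((a, 1), (b, 2)):
        res = runner.invoke(
            cli_main,
            ["simulate", "--n-samples", "60", "--n-features", "10", "--n-informative", "3",
             "--proportions", "0.5,0.5", "--seed", str(seed), "--out", str(path)],
        )
        assert res.exit_code == 0, res.output
    res = runner.invoke(cli_main, ["mmd", "--x", str(a), "--y", str(b), "--permutations", "49", "--seed", "0"])
    assert res.exit_code == 0, res.output
    payload = json.loads(res.output)
    assert payload["p_value"] >= 1 / 50 and payload["mmd"] >= 0


def test_cli_binary_tcp_and_evaluate(tmp_path):
    runner = CliRunner()
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(
        "task: binary_tcp\n"
        "model: logistic\n"
        "grid_search: false\n"
        "mrmr_k: 8\n"
        "split_fractions: [0.8, 0.0, 0.2]\n"
        "generator:\n"
        "  n_samples: 80\n"
        "  n_features: 30\n"
        "  n_informative: 8\n"
        "  class_proportions: [0.5, 0.5]\n"
        "  separation: 2.5\n"
    )
    out = tmp_path / "run"
    res = runner.invoke(cli_main, ["binary-tcp", "--config", str(cfg), "--seed", "3", "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert "empirical coverage" in res.output
    res2 = runner.invoke(
        cli_main, ["evaluate", "--predictions", str(out / "predictions.tsv"), "--confidence", "0.95"]
    )
    assert res2.exit_code == 0, res2.output
    assert "empirical coverage" in res2.output
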