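"""Generate the three synthetic study cohorts and write them under results/data/.

Cohorts: a 78-sample binary responder cohort, a 1,032-sample
three-subtype cohort plus a 789-sample covariate-shifted sibling
(standing in for an external validation series), and a 765-cell-line
skewed-response cohort.  Each is written as TSV with a JSON metadata
sidecar recording the generating spec.
"""

import argparse
from pathlib import Path

from cpgen.datasets import write_expression_table
from cpgen.synthetic import (
    ShiftSpec,
    apply_shift,
    binary_cohort_spec,
    generate_classification,
    generate_regression,
    ic50_cohort_spec,
    subtype_cohort_spec,
)


def main(seed: int = 0, out: str = "results/data") -> None:
    out_dir = Path(out)
    out_dir.mkdir(parents=True, exist_ok=True)

    binary = generate_classification(binary_cohort_spec(seed=seed))
    write_expression_table(binary, out_dir / "binary_cohort.tsv")
    print(f"binary cohort: {binary.n_samples} samples, classes {binary.class_counts()}")

    subtype = generate_classification(subtype_cohort_spec(seed=seed + 1))
    write_expression_table(subtype, out_dir / "subtype_cohort.tsv")
    print(f"subtype cohort: {subtype.n_samples} samples, classes {subtype.class_counts()}")

    sibling = generate_classification(
        subtype_cohort_spec(seed=seed + 2, n_samples=789, structure_seed=seed + 1)
    )
    shifted = apply_shift(
        sibling, ShiftSpec(mean_shift=0.5, fraction_shifted_features=0.5, seed=seed + 3)
    )
    write_expression_table(shifted, out_dir / "subtype_external.tsv")
    print(f"external cohort: {shifted.n_samples} samples, half the features translated by 0.5 SD")

    ic50 = generate_regression(ic50_cohort_spec(seed=seed + 4))
    write_expression_table(ic50, out_dir / "ic50_cohort.tsv")
    print(
        f"drug-response cohort: {ic50.n_samples} cell lines, response range "
        f"[{ic50.labels.min():.5f}, {ic50.labels.max():.1f}]"
    )


if __name__ == "__main__":
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results/data")
    args = parser.parse_args()
    main(args.seed, args.out)
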