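"""The in-memory container for expression cohorts and its TSV round trip.

A cohort is a samples-by-features matrix of continuous expression values
plus one outcome per sample: a categorical label (classification) or a
real-valued response (regression).  On disk it is a plain TSV with
samples in rows, a leading ``sample_id`` column and a trailing ``label``
or ``response`` column, optionally accompanied by a JSON metadata
sidecar (generator provenance, planted informative features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from cpgen.exceptions import TableFormatError

LABEL_COLUMN = "label"
RESPONSE_COLUMN = "response"
SAMPLE_ID_COLUMN = "sample_id"


@dataclass
class LabeledDataset:
    """Expression matrix with per-sample outcomes.

    Parameters
    ----------
    features
        ``(n_samples, n_features)`` float matrix; no missing values.
    labels
        Length-``n_samples`` vector: category names (classification) or
        reals (regression).
    sample_ids, feature_ids
        Unique identifier strings for rows and columns.
    label_space
        Ordered (lexicographic) category names; ``None`` for regression.
    metadata
        Free-form provenance, e.g. the generating spec and the indices
        of planted informative features.
    """

    features: np.ndarray
    labels: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    label_space: tuple[str, ...] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = self.features.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing or non-finite values")
        labels = np.asarray(self.labels)
        if labels.shape != (n,):
            raise ValueError("labels must be one per sample")
        if self.label_space is not None:
            self.label_space = tuple(sorted(str(c) for c in self.label_space))
            labels = labels.astype(str)
            unknown = set(labels) - set(self.label_space)
            if unknown:
                raise ValueError(f"labels outside label_space: {sorted(unknown)}")
        else:
            labels = labels.astype(float)
            if not np.all(np.isfinite(labels)):
                raise ValueError("regression responses must be finite")
        self.labels = labels

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def task(self) -> str:
        return "classification" if self.label_space is not None else "regression"

    def class_counts(self) -> dict[str, int]:
        if self.task != "classification":
            raise ValueError("class_counts is only defined for classification")
        values, counts = np.unique(self.labels, return_counts=True)
        return {str(v): int(c) for v, c in zip(values, counts)}

    # -- manipulation --------------------------------------------------------

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledDataset":
        """A new dataset restricted to ``indices`` (row positions)."""
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            label_space=self.label_space,
            metadata=dict(self.metadata),
        )

    def subset_by_ids(self, ids: Sequence[str]) -> "LabeledDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.subset([pos[s] for s in ids])

    def select_features(self, feature_ids: Sequence[str]) -> "LabeledDataset":
        """A new dataset restricted to the named features, in the given order."""
        pos = {f: j for j, f in enumerate(self.feature_ids)}
        cols = [pos[f] for f in feature_ids]
        return LabeledDataset(
            features=self.features[:, cols],
            labels=self.labels,
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[j] for j in cols],
            label_space=self.label_space,
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        outcome = LABEL_COLUMN if self.task == "classification" else RESPONSE_COLUMN
        df = pd.DataFrame(self.features, columns=self.feature_ids)
        df.insert(0, SAMPLE_ID_COLUMN, self.sample_ids)
        df[outcome] = self.labels
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledDataset):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and self.label_space == other.label_space
            and np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
        )


def write_expression_table(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset as TSV plus a ``<path>.meta.json`` sidecar.

    Feature values are written with ``repr`` round-trip precision so a
    write→read cycle reproduces the matrix exactly.
    """
    path = Path(path)
    df = dataset.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = dict(dataset.metadata)
    if dataset.label_space is not None:
        meta["label_space"] = list(dataset.label_space)
    sidecar.write_text(json.dumps(meta, indent=2, default=str))


def read_expression_table(path: str | Path, genes_in_rows: bool = False) -> LabeledDataset:
    """Read a TSV expression table written by :func:`write_expression_table`.

    ``genes_in_rows=True`` transposes a gene-major matrix (features in
    rows, samples in columns, outcome in the final row) before parsing.

    Raises
    ------
    TableFormatError
        On ragged rows, missing cells, duplicate sample ids, or a
        missing ``label``/``response`` column — each naming the
        offending line where one exists.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"{path}: ragged or unparsable table ({exc})") from exc
    if genes_in_rows:
        df = df.set_index(df.columns[0]).T.reset_index(names=SAMPLE_ID_COLUMN)
    if df.columns[0] != SAMPLE_ID_COLUMN:
        raise TableFormatError(f"{path}: first column must be '{SAMPLE_ID_COLUMN}', got '{df.columns[0]}'")
    outcome = df.columns[-1]
    if outcome not in (LABEL_COLUMN, RESPONSE_COLUMN):
        raise TableFormatError(
            f"{path}: unlabeled matrix — last column must be '{LABEL_COLUMN}' or "
            f"'{RESPONSE_COLUMN}', got '{outcome}'"
        )
    missing = df.isna()
    if missing.any().any():
        row = int(missing.any(axis=1).idxmax())
        raise TableFormatError(f"{path}: missing value at line {row + 2}")  # +2: header + 1-based
    sample_ids = df[SAMPLE_ID_COLUMN].tolist()
    dupes = df[SAMPLE_ID_COLUMN].duplicated()
    if dupes.any():
        row = int(dupes.idxmax())
        raise TableFormatError(f"{path}: duplicate sample_id '{sample_ids[row]}' at line {row + 2}")
    feature_ids = list(df.columns[1:-1])
    try:
        features = df[feature_ids].to_numpy(dtype=float)
    except ValueError as exc:
        raise TableFormatError(f"{path}: non-numeric feature value ({exc})") from exc

    sidecar = path.with_suffix(path.suffix + ".meta.json")
    metadata: dict[str, Any] = {}
    label_space: tuple[str, ...] | None = None
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        if "label_space" in metadata:
            label_space = tuple(metadata.pop("label_space"))

    if outcome == LABEL_COLUMN:
        labels = df[outcome].to_numpy(dtype=str)
        if label_space is None:
            label_space = tuple(sorted(np.unique(labels)))
    else:
        try:
            labels = df[outcome].to_numpy(dtype=float)
        except ValueError as exc:
            raise TableFormatError(f"{path}: non-numeric response ({exc})") from exc
    return LabeledDataset(
        features=features,
        labels=labels,
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        label_space=label_space,
        metadata=metadata,
    )
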