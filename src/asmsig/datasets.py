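"""Labelled sample-by-feature datasets and their on-disk TSV form.

A :class:`LabeledDataset` is the container every stage of the analysis
consumes: a numeric samples x features matrix, one class label per sample,
and a layer tag saying whether the features are methylation probes,
expression intensities, or the column-wise concatenation of both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The four stimulation states of the cultured airway smooth muscle cells.
CLASSES = ("control", "IL-13", "IL-17", "IL-13+IL-17")

#: Recognised data layers.
LAYERS = ("methylation", "expression", "combined")


class DatasetError(ValueError):
    """Raised for malformed datasets or dataset files."""


@dataclass
class LabeledDataset:
    """Numeric sample-by-feature matrix with per-sample class labels.

    Parameters
    ----------
    values
        DataFrame of shape (n_samples, n_features); index is the sample id,
        columns are feature ids ("cg..." style for methylation probes,
        gene-symbol style for expression; prefixed with ``meth:`` / ``expr:``
        in the combined layer).
    labels
        Series of class labels aligned to ``values.index``.
    layer
        One of :data:`LAYERS`.
    """

    values: pd.DataFrame
    labels: pd.Series
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise DatasetError(
                f"unknown layer {self.layer!r}; expected one of {LAYERS}"
            )
        if not self.values.index.equals(self.labels.index):
            raise DatasetError("labels index does not match sample ids")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DatasetError(f"duplicated feature id {dup!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DatasetError(f"duplicated sample id {dup!r}")
        if self.values.isna().any().any():
            raise DatasetError("matrix contains missing values")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DatasetError("matrix contains non-finite values")
        if self.labels.isna().any():
            raise DatasetError("labels contain missing values")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def classes(self) -> list[str]:
        """Sorted list of distinct class labels present."""
        return sorted(self.labels.unique())

    def class_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def subset(self, feature_ids: Sequence[str]) -> "LabeledDataset":
        """Restrict to the given features (order preserved)."""
        missing = [f for f in feature_ids if f not in self.values.columns]
        if missing:
            raise DatasetError(f"unknown feature ids: {missing[:5]}")
        return LabeledDataset(
            values=self.values.loc[:, list(feature_ids)],
            labels=self.labels,
            layer=self.layer,
        )

    def equals(self, other: "LabeledDataset") -> bool:
        return (
            self.layer == other.layer
            and self.values.equals(other.values)
            and self.labels.equals(other.labels)
        )


# -- on-disk form ---------------------------------------------------------

_MATRIX = "matrix.tsv"
_LABELS = "labels.tsv"
_META = "meta.json"


def write_dataset(ds: LabeledDataset, path: str | Path) -> Path:
    """Write a dataset into directory ``path`` (created if absent).

    Emits three files: ``matrix.tsv`` (samples as rows, header row of
    feature ids, first column the sample id), ``labels.tsv`` (sample id,
    class) and ``meta.json`` (the layer tag).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ds.values.to_csv(path / _MATRIX, sep="\t", index_label="sample_id")
    ds.labels.rename("class").to_csv(
        path / _LABELS, sep="\t", index_label="sample_id"
    )
    (path / _META).write_text(json.dumps({"layer": ds.layer}) + "\n")
    return path


def read_dataset(
    path: str | Path,
    allowed_classes: Iterable[str] | None = CLASSES,
) -> LabeledDataset:
    """Read a dataset written by :func:`write_dataset`.

    Validation is strict: duplicated ids, non-numeric cells, label/sample
    mismatches and unknown class strings all raise :class:`DatasetError`
    naming the offending entry.  Pass ``allowed_classes=None`` to accept
    arbitrary label strings.
    """
    path = Path(path)
    raw = pd.read_csv(path / _MATRIX, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise DatasetError(f"duplicated sample id {dup!r} in {_MATRIX}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise DatasetError(f"duplicated feature id {dup!r} in {_MATRIX}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.any().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise DatasetError(
            f"non-numeric cell at sample {row!r}, feature {col!r}: "
            f"{raw.loc[row, col]!r}"
        )
    if values.isna().any().any():
        row = values.index[values.isna().any(axis=1)][0]
        raise DatasetError(f"missing value in row for sample {row!r}")

    lab = pd.read_csv(path / _LABELS, sep="\t", index_col=0, dtype=str)
    if "class" not in lab.columns:
        raise DatasetError(f"{_LABELS} must have columns (sample_id, class)")
    labels = lab["class"]
    if labels.index.duplicated().any():
        dup = labels.index[labels.index.duplicated()][0]
        raise DatasetError(f"duplicated sample id {dup!r} in {_LABELS}")
    extra = set(labels.index) - set(values.index)
    missing = set(values.index) - set(labels.index)
    if extra or missing:
        off = (sorted(extra) + sorted(missing))[0]
        raise DatasetError(
            f"label/sample mismatch: sample {off!r} present in only one file"
        )
    labels = labels.reindex(values.index)
    if allowed_classes is not None:
        allowed = set(allowed_classes)
        unknown = [c for c in labels.unique() if c not in allowed]
        if unknown:
            raise DatasetError(f"unknown class {unknown[0]!r} in {_LABELS}")

    meta = json.loads((path / _META).read_text())
    return LabeledDataset(values=values, labels=labels, layer=meta["layer"])
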