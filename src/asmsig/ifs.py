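"""Incremental feature selection (IFS).

Given a feature ranking, IFS sweeps nested top-k prefixes: the first
subset is the top-ranked feature alone, the second the top two, and so
on.  Each subset is scored by cross-validating a classifier, and the
optimum is the subset size maximising the multiclass MCC (smallest k on
ties).  The resulting curve — per-class accuracies, ACC and MCC against
subset size — is the object the analysis reads optima from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, cross_validate
from .datasets import LabeledDataset
from .metrics import PerformanceRecord
from .mcfs import FeatureRanking


@dataclass
class IFSRecord:
    k: int
    record: PerformanceRecord

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("prefix size k must be >= 1")


@dataclass
class IFSCurve:
    spec: ClassifierSpec
    records: list[IFSRecord]
    class_order: list[str]

    @property
    def optimum_index(self) -> int:
        mccs = [r.record.mcc for r in self.records]
        best = max(mccs)
        return mccs.index(best)  # first occurrence = smallest k

    @property
    def optimum_k(self) -> int:
        return self.records[self.optimum_index].k

    @property
    def optimum_record(self) -> PerformanceRecord:
        return self.records[self.optimum_index].record


def default_k_grid(n_features: int, cap: int = 5000, step: int = 1) -> list[int]:
    """Nested-prefix grid 1..min(cap, n_features) at the given step."""
    top = min(cap, n_features)
    grid = list(range(1, top + 1, step))
    if grid[-1] != top:
        grid.append(top)
    return grid


def ifs_sweep(
    ds: LabeledDataset,
    ranking: FeatureRanking,
    spec: ClassifierSpec,
    k_grid: Sequence[int] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> IFSCurve:
    """Score every top-k prefix of the ranking under cross-validation.

    The same seeded fold split is reused across all subset sizes, so the
    curve reflects feature content, not fold noise.
    """
    if k_grid is None:
        k_grid = default_k_grid(len(ranking.feature_ids))
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("empty k_grid")
    if any(b <= a for a, b in zip(k_grid, k_grid[1:])):
        raise ValueError("k_grid must be strictly increasing")
    if k_grid[-1] > len(ranking.feature_ids):
        raise ValueError(
            f"max(k_grid) = {k_grid[-1]} exceeds the "
            f"{len(ranking.feature_ids)} ranked features"
        )
    records = []
    for k in k_grid:
        sub = ds.subset(ranking.top(k))
        records.append(IFSRecord(k=k, record=cross_validate(sub, spec, folds, seed)))
    return IFSCurve(spec=spec, records=records, class_order=ds.classes())


# -- persistence ----------------------------------------------------------


def curve_frame(curve: IFSCurve) -> pd.DataFrame:
    rows = []
    for rec in curve.records:
        row = {"k": rec.k}
        for c in curve.class_order:
            row[f"acc_{c}"] = rec.record.per_class_accuracy.get(c, np.nan)
        row["acc"] = rec.record.acc
        row["mcc"] = rec.record.mcc
        rows.append(row)
    return pd.DataFrame(rows)


def write_curve(curve: IFSCurve, path: str | Path) -> None:
    """Write the curve TSV plus a JSON sidecar with the optimum.

    Columns, in order: k, one per-class accuracy column per class (in
    the curve's class order), acc, mcc.  The sidecar path is the TSV
    path with ``.json`` appended.
    """
    path = Path(path)
    curve_frame(curve).to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "algorithm": curve.spec.to_dict(),
        "class_order": curve.class_order,
        "optimum": {
            "k": curve.optimum_k,
            "acc": curve.optimum_record.acc,
            "mcc": curve.optimum_record.mcc,
        },
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_curve(path: str | Path) -> IFSCurve:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    class_order = sidecar["class_order"]
    records = []
    for _, row in frame.iterrows():
        per_class = {
            c: float(row[f"acc_{c}"])
            for c in class_order
            if not pd.isna(row[f"acc_{c}"])
        }
        records.append(
            IFSRecord(
                k=int(row["k"]),
                record=PerformanceRecord(
                    per_class_accuracy=per_class,
                    acc=float(row["acc"]),
                    mcc=float(row["mcc"]),
                ),
            )
        )
    return IFSCurve(
        spec=ClassifierSpec.from_dict(sidecar["algorithm"]),
        records=records,
        class_order=class_order,
    )
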