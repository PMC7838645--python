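"""Uniform adapter over the four classification back-ends.

The incremental-feature-selection stage scores feature subsets with one
of four algorithms, each at fixed hyperparameters: random forest with 10
trees, a polynomial-kernel SVM with C = 1.0 (one-vs-one multiclass,
degree 1), k-nearest neighbours with Euclidean distance (k = 1), and a
RIPPER-style rule learner.  RF/SVM/kNN are scikit-learn estimators; the
rule learner is the in-package sequential-covering inducer
(:func:`asmsig.rules.induce_rules`), whose contract — an ordered
decision list with a default class — is all the adapter requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import rules as rules_mod
from .datasets import LabeledDataset
from .metrics import PerformanceRecord, performance_record

ALGORITHMS = ("rf", "svm", "knn", "ripper")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "rf": {"n_trees": 10},
    "svm": {"kernel": "poly", "c": 1.0, "degree": 1},
    "knn": {"k": 1, "metric": "euclidean"},
    "ripper": {"prune": True},
}


@dataclass
class ClassifierSpec:
    """Algorithm name + hyperparameter overrides + seed."""

    algorithm: str = "rf"
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        p = self.resolved_params()
        if self.algorithm == "rf" and p["n_trees"] < 1:
            raise ValueError("rf n_trees must be >= 1")
        if self.algorithm == "svm" and p["c"] <= 0:
            raise ValueError("svm c must be > 0")
        if self.algorithm == "knn" and p["k"] < 1:
            raise ValueError("knn k must be >= 1")

    def resolved_params(self) -> dict[str, Any]:
        return {**_DEFAULTS[self.algorithm], **self.params}

    # YAML round-trip for pipeline configs
    def to_dict(self) -> dict[str, Any]:
        return {"algorithm": self.algorithm, "params": dict(self.params), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ClassifierSpec":
        return cls(
            algorithm=d.get("algorithm", "rf"),
            params=dict(d.get("params", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "ClassifierSpec":
        return cls.from_dict(yaml.safe_load(text))


class FittedModel:
    """Trained model handle: predicts on feature-aligned samples."""

    def __init__(self, spec: ClassifierSpec, feature_ids: list[str], inner):
        self.spec = spec
        self.feature_ids = feature_ids
        self._inner = inner

    def predict(self, values: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in values.columns]
        if missing:
            raise ValueError(f"samples are missing features {missing[:5]}")
        X = values.loc[:, self.feature_ids]
        if isinstance(self._inner, rules_mod.RuleList):
            pred, _ = rules_mod.predict_frame(self._inner, X)
            return pred
        return self._inner.predict(X.to_numpy(dtype=float)).astype(object)

    @property
    def rule_list(self) -> rules_mod.RuleList | None:
        return self._inner if isinstance(self._inner, rules_mod.RuleList) else None


def fit(spec: ClassifierSpec, train: LabeledDataset) -> FittedModel:
    """Fit one classifier; seeded algorithms are reproducible."""
    if len(set(train.labels)) < 2:
        raise ValueError("training set has a single class")
    p = spec.resolved_params()
    if spec.algorithm == "ripper":
        rl = rules_mod.induce_rules(train, seed=spec.seed, prune=p["prune"])
        return FittedModel(spec, train.feature_ids, rl)
    if spec.algorithm == "rf":
        est = RandomForestClassifier(
            n_estimators=p["n_trees"], random_state=spec.seed
        )
    elif spec.algorithm == "svm":
        est = SVC(kernel=p["kernel"], C=p["c"], degree=p["degree"])
    else:  # knn
        est = KNeighborsClassifier(n_neighbors=p["k"], metric=p["metric"])
    est.fit(train.values.to_numpy(dtype=float), train.labels.to_numpy(dtype=object))
    return FittedModel(spec, train.feature_ids, est)


def cross_validate(
    ds: LabeledDataset,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
) -> PerformanceRecord:
    """Stratified k-fold CV scored on the pooled out-of-fold predictions.

    Fold assignment depends only on (labels, folds, seed), so nested
    feature subsets of the same dataset share the same split.  If the
    rarest class has fewer members than ``folds``, the fold count is
    reduced to that size with a warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = ds.labels.to_numpy(dtype=object)
    min_count = min(ds.class_counts().values())
    if min_count < folds:
        warnings.warn(
            f"reducing folds from {folds} to {min_count} "
            "(smallest class size)", stacklevel=2
        )
        folds = min_count
        if folds < 2:
            raise ValueError("smallest class has < 2 members; cannot cross-validate")

    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y), dtype=object)
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        train = LabeledDataset(
            values=ds.values.iloc[train_idx],
            labels=ds.labels.iloc[train_idx],
            layer=ds.layer,
        )
        model = fit(spec, train)
        pooled[test_idx] = model.predict(ds.values.iloc[test_idx])
    return performance_record(y, pooled, sorted(set(y) | set(pooled)))
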