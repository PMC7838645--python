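"""Monte Carlo feature selection (MCFS).

Feature importance is estimated by aggregating information-gain
contributions over a large ensemble of decision trees, each grown on a
random projection of m features (m << M) and a random train/test split.
The relative importance of feature f is

    RI_f = sum over trees tau of (wAcc_tau)^u *
           sum over nodes of tau splitting on f of
               IG(node) * (n_node / n_root)^v

where wAcc is the tree's weighted accuracy on its held-out split (the
unweighted mean of per-class sensitivities, so trees that only get the
majority class right are discounted), IG is the entropy information gain
of the split in bits, and n_node / n_root is the fraction of training
samples reaching the node.  u = v = 1 by default.  Features are then
ranked by decreasing RI.

The per-projection trees are grown with scikit-learn
(criterion="entropy", min_samples_leaf=2, no pruning — the goal is
importance, not prediction); the projection scheme, wAcc weighting, RI
aggregation and ranking are implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.tree import DecisionTreeClassifier

from .datasets import LabeledDataset


@dataclass
class McfsParams:
    """Ensemble geometry for one MCFS run.

    ``m`` (features per projection) defaults to max(ceil(0.05*M), 30),
    resolved against the dataset at run time; ``s`` projections x ``t``
    splits per projection gives s*t trees (2,000 by default).  ``u`` and
    ``v`` are the exponents on weighted accuracy and on the node-size
    fraction.
    """

    m: int | None = None
    s: int | None = None
    t: int = 5
    train_fraction: float = 0.66
    u: float = 1.0
    v: float = 1.0
    seed: int = 0

    def resolved(self, n_features: int) -> "McfsParams":
        m = self.m if self.m is not None else min(
            n_features, max(math.ceil(0.05 * n_features), 30)
        )
        s = self.s if self.s is not None else max(2000 // self.t, 1)
        out = McfsParams(
            m=m, s=s, t=self.t, train_fraction=self.train_fraction,
            u=self.u, v=self.v, seed=self.seed,
        )
        out.validate(n_features)
        return out

    def validate(self, n_features: int) -> None:
        if self.m is None or not (1 <= self.m <= n_features):
            raise ValueError(
                f"m must satisfy 1 <= m <= {n_features}, got {self.m}"
            )
        if self.s is None or self.s < 1 or self.t < 1:
            raise ValueError("s and t must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.u < 0 or self.v < 0:
            raise ValueError("u and v must be >= 0")


@dataclass
class TreeRecord:
    """One projection tree: its held-out wAcc and per-node contributions.

    ``node_contributions`` holds one entry per internal split:
    (feature_id, information gain in bits, training samples at the node,
    training samples at the root).
    """

    features: list[str]
    wacc: float
    node_contributions: list[tuple[str, float, int, int]]


@dataclass
class FeatureRanking:
    """Features sorted by decreasing RI; ties broken by feature id."""

    feature_ids: list[str]
    ri: np.ndarray
    #: number of trees in which the feature was actually used in a split
    tree_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ri = np.asarray(self.ri, dtype=float)
        if len(self.feature_ids) != self.ri.size:
            raise ValueError("feature_ids and ri length mismatch")

    def top(self, k: int) -> list[str]:
        return self.feature_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.feature_ids) + 1),
                "feature_id": self.feature_ids,
                "ri": self.ri,
            }
        )
        frame["tree_count"] = (
            self.tree_counts
            if self.tree_counts is not None
            else np.zeros(len(self.feature_ids), dtype=int)
        )
        return frame


def write_ranking(ranking: FeatureRanking, path: str | Path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path) -> FeatureRanking:
    frame = pd.read_csv(path, sep="\t")
    return FeatureRanking(
        feature_ids=list(frame["feature_id"]),
        ri=frame["ri"].to_numpy(),
        tree_counts=frame["tree_count"].to_numpy(),
    )


# -- the three stages -----------------------------------------------------


def draw_projections(
    n_features: int, params: McfsParams, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Draw s random feature subsets of m distinct indices each."""
    params = params.resolved(n_features)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return [
        rng.choice(n_features, size=params.m, replace=False)
        for _ in range(params.s)
    ]


def grow_projection_tree(
    values: np.ndarray,
    labels: np.ndarray,
    feature_ids: Sequence[str],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    params: McfsParams,
    tree_seed: int = 0,
) -> TreeRecord:
    """Grow one tree on a projection's training split and record it.

    ``values`` is samples x m (the projection's columns only).  The tree
    is grown greedily on entropy information gain to purity (min-leaf 2).
    wAcc is the unweighted mean of per-class sensitivities over the
    classes present in the held-out split; with single-class training
    data the tree is a bare leaf with no contributions.
    """
    X_train = values[train_idx]
    y_train = labels[train_idx]
    clf = DecisionTreeClassifier(
        criterion="entropy", min_samples_leaf=2, random_state=tree_seed
    )
    clf.fit(X_train, y_train)

    tree = clf.tree_
    contributions: list[tuple[str, float, int, int]] = []
    n_root = int(tree.n_node_samples[0])
    for node in range(tree.node_count):
        left = tree.children_left[node]
        right = tree.children_right[node]
        if left == -1:  # leaf
            continue
        n_node = int(tree.n_node_samples[node])
        ig = tree.impurity[node] - (
            tree.n_node_samples[left] * tree.impurity[left]
            + tree.n_node_samples[right] * tree.impurity[right]
        ) / n_node
        ig = max(float(ig), 0.0)  # guard float round-off
        contributions.append(
            (feature_ids[tree.feature[node]], ig, n_node, n_root)
        )

    y_test = labels[test_idx]
    y_pred = clf.predict(values[test_idx])
    sens = [
        float((y_pred[y_test == c] == c).mean()) for c in np.unique(y_test)
    ]
    return TreeRecord(
        features=list(feature_ids),
        wacc=float(np.mean(sens)),
        node_contributions=contributions,
    )


def relative_importance(
    tree_records: Sequence[TreeRecord],
    all_feature_ids: Sequence[str],
    params: McfsParams,
) -> FeatureRanking:
    """Aggregate tree records into the RI ranking.

    Features never used in any split get RI = 0.  The output is sorted by
    decreasing RI with ties broken lexicographically on feature id.
    """
    if not tree_records:
        raise ValueError("tree_records is empty")
    ri: dict[str, float] = {f: 0.0 for f in all_feature_ids}
    counts: dict[str, int] = {f: 0 for f in all_feature_ids}
    for rec in tree_records:
        weight = rec.wacc ** params.u if params.u != 0 else 1.0
        seen: set[str] = set()
        for feat, ig, n_node, n_root in rec.node_contributions:
            ri[feat] += weight * ig * (n_node / n_root) ** params.v
            seen.add(feat)
        for feat in seen:
            counts[feat] += 1
    order = sorted(all_feature_ids, key=lambda f: (-ri[f], f))
    return FeatureRanking(
        feature_ids=order,
        ri=np.array([ri[f] for f in order]),
        tree_counts=np.array([counts[f] for f in order]),
    )


def run_mcfs(
    ds: LabeledDataset,
    params: McfsParams,
    return_records: bool = False,
) -> FeatureRanking | tuple[FeatureRanking, list[TreeRecord]]:
    """Full MCFS run: s projections x t stratified splits -> RI ranking.

    Projections are drawn by feature index over the canonically sorted
    feature ids, so the ranking does not depend on the column order of
    the input matrix.  Reproducible from ``params.seed``.  With
    ``return_records`` the per-tree records are returned alongside the
    ranking (e.g. to audit the RI aggregation).
    """
    if len(set(ds.labels)) < 2:
        raise ValueError("MCFS requires at least 2 classes")
    params = params.resolved(ds.n_features)
    order = sorted(ds.feature_ids)
    values = ds.values.loc[:, order].to_numpy(dtype=np.float32)
    labels = ds.labels.to_numpy(dtype=object)

    rng = np.random.default_rng(params.seed)
    projections = draw_projections(ds.n_features, params, rng)
    seeds = rng.integers(0, 2**31 - 1, size=params.s * params.t)

    records: list[TreeRecord] = []
    tree_i = 0
    for proj in projections:
        proj_values = values[:, proj]
        proj_ids = [order[j] for j in proj]
        splitter = StratifiedShuffleSplit(
            n_splits=params.t,
            train_size=params.train_fraction,
            random_state=int(seeds[tree_i]) % (2**31),
        )
        for train_idx, test_idx in splitter.split(proj_values, labels):
            records.append(
                grow_projection_tree(
                    proj_values,
                    labels,
                    proj_ids,
                    train_idx,
                    test_idx,
                    params,
                    tree_seed=int(seeds[tree_i]),
                )
            )
            tree_i += 1
    ranking = relative_importance(records, order, params)
    return (ranking, records) if return_records else ranking
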