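"""Ordered threshold decision lists: parse, apply, induce, evaluate.

A decision list is a sequence of IF-THEN rules evaluated top-down, each a
conjunction of threshold conditions ``(FEATURE >= x)`` / ``(FEATURE <= y)``
over numeric features, closed by a default class for unmatched samples.
The textual grammar is one rule per line::

    (GPR44 >= 7.200) and (ZC3H12A <= 8.211) => IL-13
    default => IL-13 and IL-17

Only non-strict inequalities are admitted; the consequent is an arbitrary
class string (so the combined-stimulation label "IL-13 and IL-17" is a
single atomic class).

Rule induction follows the RIPPER family of sequential-covering
learners: classes are processed from rarest to most frequent, rules are
grown greedily by FOIL information gain on a growing split, pruned on a
held-out third, and the samples a kept rule covers are removed before
the next rule is grown.  The most frequent class becomes the default.
The full MDL-based optimisation passes of RIPPER are omitted — the
contract is an ordered decision list, and the grow/prune core is what
shapes it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import LabeledDataset
from .metrics import PerformanceRecord, performance_record

DEFAULT_SENTINEL = -1  # fired-rule index reported when the default fires


class RuleParseError(ValueError):
    """Raised for text not in the rule grammar."""


@dataclass(frozen=True)
class Condition:
    """A single threshold test ``feature <op> threshold``."""

    feature: str
    op: str  # "<=" or ">="
    threshold: float
    literal: str | None = None  # original number text, kept for round-trips

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">="):
            raise RuleParseError(f"operator must be <= or >=, got {self.op!r}")
        if not np.isfinite(self.threshold):
            raise RuleParseError("threshold must be finite")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value >= self.threshold

    def text(self) -> str:
        num = self.literal if self.literal is not None else format(self.threshold, "g")
        return f"({self.feature} {self.op} {num})"


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions with a class consequent."""

    conditions: tuple[Condition, ...]
    consequent: str

    def __post_init__(self) -> None:
        if not self.conditions:
            raise RuleParseError("non-default rules need at least one condition")

    def text(self) -> str:
        return " and ".join(c.text() for c in self.conditions) + f" => {self.consequent}"


@dataclass
class RuleList:
    """Ordered rules plus the default class fired when none match."""

    rules: list[Rule]
    default_class: str

    def referenced_features(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            for c in r.conditions:
                seen.setdefault(c.feature, None)
        return list(seen)


# -- grammar --------------------------------------------------------------

_COND_RE = re.compile(
    r"\(\s*(?P<feat>[^\s()<>=]+)\s*(?P<op><=|>=)\s*"
    r"(?P<num>[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s*\)"
)
_FILLER_RE = re.compile(r"^(\s*and\s*)*\s*$")


def parse_rules(text: str) -> RuleList:
    """Parse rule-grammar text into a :class:`RuleList`.

    Malformed lines (including strict ``<`` / ``>`` operators) raise
    :class:`RuleParseError` with the 1-based line number; a missing or
    duplicated default line is an error.
    """
    rules: list[Rule] = []
    default: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if default is not None:
            raise RuleParseError(
                f"line {lineno}: rule after the default line"
            )
        if "=>" not in line:
            raise RuleParseError(f"line {lineno}: missing '=>' in {line!r}")
        lhs, _, cls = line.partition("=>")
        cls = cls.strip()
        if not cls:
            raise RuleParseError(f"line {lineno}: empty consequent")
        lhs = lhs.strip()
        if lhs == "default":
            default = cls
            continue
        conds = []
        for m in _COND_RE.finditer(lhs):
            conds.append(
                Condition(
                    feature=m.group("feat"),
                    op=m.group("op"),
                    threshold=float(m.group("num")),
                    literal=m.group("num"),
                )
            )
        residue = _COND_RE.sub("", lhs)
        if not conds or not _FILLER_RE.match(residue):
            raise RuleParseError(
                f"line {lineno}: malformed condition in {line!r} "
                "(grammar admits only '(FEAT >= x)' / '(FEAT <= y)' "
                "joined by 'and')"
            )
        rules.append(Rule(conditions=tuple(conds), consequent=cls))
    if default is None:
        raise RuleParseError("missing 'default => CLASS' line")
    return RuleList(rules=rules, default_class=default)


def serialize_rules(rl: RuleList) -> str:
    lines = [r.text() for r in rl.rules]
    lines.append(f"default => {rl.default_class}")
    return "\n".join(lines) + "\n"


def read_rules(path: str | Path) -> RuleList:
    return parse_rules(Path(path).read_text())


def write_rules(rl: RuleList, path: str | Path) -> None:
    Path(path).write_text(serialize_rules(rl))


def load_fixture(name: str) -> RuleList:
    """Load a packaged rule list.

    Available fixtures: ``table2_expression`` (decision list learned on
    the expression layer) and ``table3_combined`` (combined layer).
    """
    text = (
        resources.files("asmsig") / "resources" / f"{name}.rules"
    ).read_text()
    return parse_rules(text)


# -- application ----------------------------------------------------------


def apply_rules(rl: RuleList, sample: Mapping[str, float]) -> tuple[str, int]:
    """Classify one sample; returns (class, index of fired rule).

    The first rule (in order) whose conjunction holds fires; otherwise the
    default fires and the index is :data:`DEFAULT_SENTINEL` (-1).  Every
    feature referenced by the list must be present in ``sample``.
    """
    for feat in rl.referenced_features():
        if feat not in sample:
            raise KeyError(f"sample is missing feature {feat!r}")
    for i, rule in enumerate(rl.rules):
        if all(c.holds(sample[c.feature]) for c in rule.conditions):
            return rule.consequent, i
    return rl.default_class, DEFAULT_SENTINEL


def predict_frame(
    rl: RuleList, values: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised first-match application over a samples x features frame."""
    missing = [f for f in rl.referenced_features() if f not in values.columns]
    if missing:
        raise KeyError(f"samples are missing features {missing}")
    n = len(values)
    fired = np.full(n, DEFAULT_SENTINEL, dtype=int)
    pred = np.full(n, rl.default_class, dtype=object)
    undecided = np.ones(n, dtype=bool)
    for i, rule in enumerate(rl.rules):
        mask = np.ones(n, dtype=bool)
        for c in rule.conditions:
            col = values[c.feature].to_numpy(dtype=float)
            mask &= (col <= c.threshold) if c.op == "<=" else (col >= c.threshold)
        hit = mask & undecided
        pred[hit] = rule.consequent
        fired[hit] = i
        undecided &= ~hit
    return pred, fired


# -- evaluation -----------------------------------------------------------


def evaluate_rules(
    rl: RuleList, ds: LabeledDataset
) -> tuple[pd.DataFrame, PerformanceRecord]:
    """Per-rule coverage/precision plus overall pooled metrics.

    Each sample fires exactly one entry (a rule or the default), so the
    per-rule coverages partition the sample count.
    """
    pred, fired = predict_frame(rl, ds.values)
    actual = ds.labels.to_numpy(dtype=object)
    rows = []
    for i, rule in enumerate(rl.rules):
        mask = fired == i
        n_fired = int(mask.sum())
        n_correct = int((actual[mask] == rule.consequent).sum())
        rows.append(
            {
                "rule": i,
                "consequent": rule.consequent,
                "n_fired": n_fired,
                "n_correct": n_correct,
                "precision": n_correct / n_fired if n_fired else np.nan,
            }
        )
    mask = fired == DEFAULT_SENTINEL
    n_fired = int(mask.sum())
    n_correct = int((actual[mask] == rl.default_class).sum())
    rows.append(
        {
            "rule": DEFAULT_SENTINEL,
            "consequent": rl.default_class,
            "n_fired": n_fired,
            "n_correct": n_correct,
            "precision": n_correct / n_fired if n_fired else np.nan,
        }
    )
    record = performance_record(actual, pred, sorted(set(actual) | set(pred)))
    return pd.DataFrame(rows), record


# -- induction ------------------------------------------------------------


def _coverage(
    X: np.ndarray, cols: dict[str, int], conds: Sequence[Condition]
) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for c in conds:
        col = X[:, cols[c.feature]]
        mask &= (col <= c.threshold) if c.op == "<=" else (col >= c.threshold)
    return mask


def _foil_gain(p: np.ndarray, n: np.ndarray, P: int, N: int) -> np.ndarray:
    """FOIL information gain of candidate conditions, vectorised.

    p, n: positives/negatives covered after adding the condition;
    P, N: positives/negatives covered before.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = p * (np.log2(p / (p + n)) - np.log2(P / (P + N)))
    gain = np.where(p > 0, gain, -np.inf)
    return gain


def _grow_rule(
    X: np.ndarray,
    is_pos: np.ndarray,
    feature_ids: Sequence[str],
    max_conditions: int,
    n_thresholds: int,
) -> list[Condition]:
    cols = {f: j for j, f in enumerate(feature_ids)}
    conds: list[Condition] = []
    mask = np.ones(X.shape[0], dtype=bool)
    for _ in range(max_conditions):
        P = int(is_pos[mask].sum())
        N = int((~is_pos)[mask].sum())
        if P == 0 or N == 0:
            break
        best = (-np.inf, None)  # (gain, Condition)
        sub = X[mask]
        sub_pos = is_pos[mask]
        for j, feat in enumerate(feature_ids):
            vals = np.unique(sub[:, j])
            if vals.size < 2:
                continue
            mids = (vals[:-1] + vals[1:]) / 2.0
            if mids.size > n_thresholds:
                take = np.linspace(0, mids.size - 1, n_thresholds).astype(int)
                mids = mids[take]
            le = sub[:, j][:, None] <= mids[None, :]
            p_le = (le & sub_pos[:, None]).sum(axis=0)
            n_le = (le & ~sub_pos[:, None]).sum(axis=0)
            tot_p = sub_pos.sum()
            tot_n = (~sub_pos).sum()
            for op, p_arr, n_arr in (
                ("<=", p_le, n_le),
                (">=", tot_p - p_le, tot_n - n_le),
            ):
                gains = _foil_gain(p_arr, n_arr, P, N)
                k = int(np.argmax(gains))
                if gains[k] > best[0] + 1e-12:
                    best = (
                        float(gains[k]),
                        Condition(feature=feat, op=op, threshold=float(mids[k])),
                    )
        if best[1] is None or best[0] <= 1e-9:
            break
        conds.append(best[1])
        mask &= _coverage(X, cols, [best[1]])
        if (~is_pos & mask).sum() == 0:  # no negatives left covered
            break
    return conds


def _prune_rule(
    conds: list[Condition],
    X: np.ndarray,
    is_pos: np.ndarray,
    feature_ids: Sequence[str],
) -> list[Condition]:
    """Keep the condition prefix maximising (p - n) / (p + n) on prune data."""
    cols = {f: j for j, f in enumerate(feature_ids)}
    best_len, best_val = len(conds), -np.inf
    for length in range(len(conds), 0, -1):
        mask = _coverage(X, cols, conds[:length])
        p = int(is_pos[mask].sum())
        n = int((~is_pos)[mask].sum())
        val = (p - n) / (p + n) if (p + n) else -np.inf
        if val > best_val:
            best_val, best_len = val, length
    return conds[:best_len]


def induce_rules(
    ds: LabeledDataset,
    seed: int = 0,
    prune: bool = True,
    max_conditions: int = 8,
    max_rules_per_class: int = 8,
    n_thresholds: int = 32,
    min_precision: float = 0.5,
) -> RuleList:
    """Learn an ordered threshold decision list by sequential covering.

    Classes are processed from rarest to most frequent (ties broken by
    name); the most frequent class becomes the default and gets no rules.
    Each rule is grown by FOIL gain on a 2/3 growing split, pruned on the
    remaining third, and accepted only if its held-out precision exceeds
    ``min_precision``; the samples it covers are then removed.
    """
    classes = ds.classes()
    if len(classes) < 2:
        raise ValueError("rule induction requires at least 2 classes")
    counts = ds.class_counts()
    default = sorted(classes, key=lambda c: (-counts[c], c))[0]
    order = [c for c in sorted(classes, key=lambda c: (counts[c], c)) if c != default]

    X = ds.values.to_numpy(dtype=float)
    y = ds.labels.to_numpy(dtype=object)
    feature_ids = ds.feature_ids
    cols = {f: j for j, f in enumerate(feature_ids)}
    rng = np.random.default_rng(seed)

    remaining = np.ones(len(y), dtype=bool)
    rules: list[Rule] = []
    for cls in order:
        for _ in range(max_rules_per_class):
            idx = np.flatnonzero(remaining)
            is_pos = y[idx] == cls
            if is_pos.sum() == 0:
                break
            # grow/prune split (stratified on pos/neg)
            use_prune = prune and is_pos.sum() >= 3 and (~is_pos).sum() >= 3
            if use_prune:
                grow_rows, prune_rows = [], []
                for flag in (True, False):
                    part = idx[is_pos == flag] if flag else idx[~is_pos]
                    part = part.copy()
                    rng.shuffle(part)
                    cut = max(int(round(len(part) * 2 / 3)), 1)
                    grow_rows.append(part[:cut])
                    prune_rows.append(part[cut:])
                grow_idx = np.concatenate(grow_rows)
                prune_idx = np.concatenate(prune_rows)
            else:
                grow_idx, prune_idx = idx, np.array([], dtype=int)

            conds = _grow_rule(
                X[grow_idx], y[grow_idx] == cls, feature_ids,
                max_conditions, n_thresholds,
            )
            if not conds:
                break
            if prune_idx.size:
                conds = _prune_rule(
                    conds, X[prune_idx], y[prune_idx] == cls, feature_ids
                )
            # held-out acceptance check
            check_idx = prune_idx if prune_idx.size else grow_idx
            mask = _coverage(X[check_idx], cols, conds)
            p = int((y[check_idx][mask] == cls).sum())
            n = int(mask.sum()) - p
            if p + n == 0 or p / (p + n) <= min_precision:
                break
            rules.append(Rule(conditions=tuple(conds), consequent=cls))
            covered = _coverage(X, cols, conds) & remaining
            if not covered.any():
                break
            remaining &= ~covered
    return RuleList(rules=rules, default_class=default)
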