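"""Synthetic four-group multiomics data generator.

Emulates the study design the analysis assumes: four equal-size groups of
airway smooth muscle cell samples (vehicle control, IL-13, IL-17 and
IL-13+IL-17 combined stimulation), profiled on an expression layer
(log2-intensity-like scale, roughly 7-13) and a methylation layer (beta
values in [0,1]).  A small set of responsive features is mean-shifted in
the stimulated groups against a large background of uninformative
features, reproducing the needle-in-a-haystack structure that Monte Carlo
feature selection is designed for.

Shift structure per responsive feature class:

- IL-13-responsive: shifted in the IL-13 and IL-13+IL-17 groups;
- IL-17-responsive: shifted in the IL-17 and IL-13+IL-17 groups;
- combination-only: shifted only in IL-13+IL-17.

Expression values are drawn as ``baseline + shift + Normal(0, noise_sd)``
with per-feature baselines uniform over ``baseline_range``; methylation is
generated on a latent logit scale (same shift, applied additively) and
squashed through the inverse logit, which guarantees values in [0,1]
without truncation artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .datasets import CLASSES, LabeledDataset


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults are desk-scale: 2,000 expression features and 5,000
    methylation probes (the real arrays are far larger) with 20 responsive
    features per factor per layer, 64 samples per group.
    """

    n_per_group: int = 64
    n_expr_features: int = 2000
    n_meth_features: int = 5000
    n_il13_features: int = 20
    n_il17_features: int = 20
    n_combo_features: int = 20
    #: mean shift, in log2-intensity units (expression) / logit units (methylation)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline_range: Tuple[float, float] = (7.0, 12.0)
    #: latent-logit baseline range for methylation probes
    meth_baseline_range: Tuple[float, float] = (-2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        n_resp = self.n_il13_features + self.n_il17_features + self.n_combo_features
        if min(
            self.n_il13_features, self.n_il17_features, self.n_combo_features
        ) < 0:
            raise ValueError("responsive feature counts must be >= 0")
        for name, width in (
            ("n_expr_features", self.n_expr_features),
            ("n_meth_features", self.n_meth_features),
        ):
            if width < 1:
                raise ValueError(f"{name} must be >= 1")
            if n_resp > width:
                raise ValueError(
                    f"responsive feature counts sum to {n_resp}, "
                    f"exceeding {name} = {width}"
                )
        lo, hi = self.baseline_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("baseline_range must be a finite (low, high) pair")


def responsive_features(config: SyntheticConfig, layer: str) -> dict[str, list[str]]:
    """Feature ids of the responsive sets for one layer.

    The generator assigns responsiveness to the leading feature indices
    (IL-13 first, then IL-17, then combination-only); this helper exposes
    that mapping so recovery experiments know the ground truth.
    """
    ids = _feature_ids(config, layer)
    a = config.n_il13_features
    b = a + config.n_il17_features
    c = b + config.n_combo_features
    return {"IL-13": ids[:a], "IL-17": ids[a:b], "combo": ids[b:c]}


def _feature_ids(config: SyntheticConfig, layer: str) -> list[str]:
    if layer == "expression":
        return [f"GENE{i:05d}" for i in range(config.n_expr_features)]
    if layer == "methylation":
        return [f"cg{i:08d}" for i in range(config.n_meth_features)]
    raise ValueError(f"no per-layer ids for layer {layer!r}")


def _shift_matrix(config: SyntheticConfig, n_features: int) -> np.ndarray:
    """(4 groups x features) matrix of mean shifts, group order = CLASSES."""
    shifts = np.zeros((len(CLASSES), n_features))
    a = config.n_il13_features
    b = a + config.n_il17_features
    c = b + config.n_combo_features
    e = config.effect_size
    g = {name: i for i, name in enumerate(CLASSES)}
    shifts[g["IL-13"], :a] += e
    shifts[g["IL-13+IL-17"], :a] += e
    shifts[g["IL-17"], a:b] += e
    shifts[g["IL-13+IL-17"], a:b] += e
    shifts[g["IL-13+IL-17"], b:c] += e
    return shifts


def generate(
    config: SyntheticConfig,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Generate (methylation, expression, combined) datasets.

    All three share the same samples in the same order; the combined layer
    is the column-wise concatenation with ``meth:`` / ``expr:`` feature-id
    prefixes.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    labels = np.repeat(list(CLASSES), n)
    group_idx = np.repeat(np.arange(len(CLASSES)), n)
    sample_ids = [f"sample_{i:04d}" for i in range(len(labels))]
    label_s = pd.Series(labels, index=sample_ids, name="class")

    # expression layer
    ids_e = _feature_ids(config, "expression")
    base_e = rng.uniform(*config.baseline_range, size=config.n_expr_features)
    shift_e = _shift_matrix(config, config.n_expr_features)
    vals_e = (
        base_e[None, :]
        + shift_e[group_idx, :]
        + rng.normal(0.0, config.noise_sd, size=(len(labels), config.n_expr_features))
    )
    expr = LabeledDataset(
        values=pd.DataFrame(vals_e, index=sample_ids, columns=ids_e),
        labels=label_s.copy(),
        layer="expression",
    )

    # methylation layer: latent logit scale, then squash
    ids_m = _feature_ids(config, "methylation")
    base_m = rng.uniform(*config.meth_baseline_range, size=config.n_meth_features)
    shift_m = _shift_matrix(config, config.n_meth_features)
    latent = (
        base_m[None, :]
        + shift_m[group_idx, :]
        + rng.normal(0.0, config.noise_sd, size=(len(labels), config.n_meth_features))
    )
    meth = LabeledDataset(
        values=pd.DataFrame(expit(latent), index=sample_ids, columns=ids_m),
        labels=label_s.copy(),
        layer="methylation",
    )

    combined = LabeledDataset(
        values=pd.concat(
            [
                meth.values.add_prefix("meth:"),
                expr.values.add_prefix("expr:"),
            ],
            axis=1,
        ),
        labels=label_s.copy(),
        layer="combined",
    )
    return meth, expr, combined
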