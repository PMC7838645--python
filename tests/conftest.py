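import numpy as np
import pandas as pd
import pytest

from asmsig.datasets import LabeledDataset


def make_dataset(values: np.ndarray, labels, layer: str = "expression",
                 feature_ids=None) -> LabeledDataset:
    """Build a LabeledDataset from a plain array and label list."""
    n, p = values.shape
    feature_ids = feature_ids or [f"F{j:03d}" for j in range(p)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    return LabeledDataset(
        values=pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        labels=pd.Series(list(labels), index=sample_ids),
        layer=layer,
    )


@pytest.fixture
def separable_2class() -> LabeledDataset:
    """Two clouds split cleanly on the first feature."""
    rng = np.random.default_rng(7)
    n = 20
    x0 = np.concatenate([rng.normal(-3, 0.5, n), rng.normal(3, 0.5, n)])
    noise = rng.normal(size=(2 * n, 4))
    values = np.column_stack([x0, noise])
    return make_dataset(values, ["A"] * n + ["B"] * n)


@pytest.fixture
def four_class_informative() -> LabeledDataset:
    """Four balanced classes, 5 informative features then 45 noise features.

    The informative features encode class structure strongly enough that
    any sensible classifier separates the classes once it sees them.
    """
    rng = np.random.default_rng(42)
    n = 16
    labels = np.repeat(["control", "IL-13", "IL-17", "IL-13+IL-17"], n)
    centers = {
        "control": [0, 0, 0, 0, 0],
        "IL-13": [4, 0, 4, 0, 4],
        "IL-17": [0, 4, 0, 4, 0],
        "IL-13+IL-17": [4, 4, 4, 4, 4],
    }
    info = np.vstack([
        rng.normal(centers[lab], 0.8) for lab in labels
    ])
    noise = rng.normal(size=(4 * n, 45))
    return make_dataset(np.column_stack([info, noise]), labels)
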