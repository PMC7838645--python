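"""Generator structure, calibration under the null, and TSV round-trips."""

import numpy as np
import pytest
from scipy.stats import ranksums

from asmsig.datasets import CLASSES, DatasetError, read_dataset, write_dataset
from asmsig.synthetic import SyntheticConfig, generate, responsive_features

SMALL = dict(
    n_per_group=16, n_expr_features=120, n_meth_features=150,
    n_il13_features=5, n_il17_features=5, n_combo_features=5, seed=3,
)


class TestConfigValidation:
    def test_responsive_counts_must_fit_layer(self):
        with pytest.raises(ValueError, match="responsive"):
            SyntheticConfig(n_expr_features=10, n_il13_features=20,
                            n_il17_features=0, n_combo_features=0)

    @pytest.mark.parametrize("kwargs", [
        dict(n_per_group=0), dict(noise_sd=0.0), dict(baseline_range=(9, 7)),
    ])
    def test_invalid_scalars_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerate:
    def test_group_sizes_and_shared_sample_order(self):
        meth, expr, combined = generate(SyntheticConfig(**SMALL))
        for ds in (meth, expr, combined):
            assert ds.n_samples == 64
            counts = ds.class_counts()
            assert set(counts) == set(CLASSES)
            assert all(v == 16 for v in counts.values())
        assert meth.sample_ids == expr.sample_ids == combined.sample_ids

    def test_combined_is_prefixed_concatenation(self):
        meth, expr, combined = generate(SyntheticConfig(**SMALL))
        assert combined.n_features == meth.n_features + expr.n_features
        assert combined.feature_ids[: meth.n_features] == [
            f"meth:{f}" for f in meth.feature_ids
        ]
        assert combined.feature_ids[meth.n_features:] == [
            f"expr:{f}" for f in expr.feature_ids
        ]

    def test_methylation_in_unit_interval(self):
        meth, _, _ = generate(SyntheticConfig(**SMALL, effect_size=5.0))
        vals = meth.values.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_seed_determinism_bitwise(self):
        a = generate(SyntheticConfig(**SMALL))
        b = generate(SyntheticConfig(**SMALL))
        for x, y in zip(a, b):
            assert x.values.equals(y.values)

    def test_shift_structure_in_expectation(self):
        """Each responsive set is shifted in exactly its stimulated groups."""
        cfg = SyntheticConfig(
            n_per_group=64, n_expr_features=60, n_meth_features=60,
            n_il13_features=10, n_il17_features=10, n_combo_features=10,
            effect_size=2.0, noise_sd=1.0, seed=8,
        )
        _, expr, _ = generate(cfg)
        resp = responsive_features(cfg, "expression")
        means = expr.values.groupby(expr.labels).mean()

        def shift(feats, group):
            return (means.loc[group, feats] - means.loc["control", feats]).mean()

        assert shift(resp["IL-13"], "IL-13") == pytest.approx(2.0, abs=0.2)
        assert shift(resp["IL-13"], "IL-13+IL-17") == pytest.approx(2.0, abs=0.2)
        assert shift(resp["IL-13"], "IL-17") == pytest.approx(0.0, abs=0.2)
        assert shift(resp["combo"], "IL-13+IL-17") == pytest.approx(2.0, abs=0.2)
        assert shift(resp["combo"], "IL-13") == pytest.approx(0.0, abs=0.2)

    def test_parameter_recovery_per_feature(self):
        """At effect 2, noise 1, n=64: per-feature empirical shifts land
        within 3*noise_sd/sqrt(64) of the true effect for >= 95% of the
        IL-13-responsive features."""
        cfg = SyntheticConfig(
            n_per_group=64, n_expr_features=200, n_meth_features=200,
            n_il13_features=40, n_il17_features=0, n_combo_features=0,
            effect_size=2.0, noise_sd=1.0, seed=21,
        )
        _, expr, _ = generate(cfg)
        resp = responsive_features(cfg, "expression")["IL-13"]
        means = expr.values.groupby(expr.labels).mean()
        shifts = means.loc["IL-13", resp] - means.loc["control", resp]
        tol = 3 * cfg.noise_sd / np.sqrt(64)
        frac = (np.abs(shifts - 2.0) <= tol).mean()
        assert frac >= 0.95

    def test_null_rejection_rate_calibrated(self):
        """With effect 0, a rank-sum test IL-13 vs control rejects at
        alpha=0.01 for roughly 1% of 1,000 background features."""
        cfg = SyntheticConfig(
            n_per_group=64, n_expr_features=1000, n_meth_features=10,
            n_il13_features=0, n_il17_features=0, n_combo_features=0,
            effect_size=0.0, seed=17,
        )
        _, expr, _ = generate(cfg)
        a = expr.values[expr.labels == "IL-13"].to_numpy()
        b = expr.values[expr.labels == "control"].to_numpy()
        pvals = ranksums(a, b, axis=0).pvalue
        n_reject = int((pvals < 0.01).sum())
        # Binomial(1000, 0.01): mean 10, sd ~3.15; accept +/- ~4.5 sd
        assert 1 <= n_reject <= 25


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        _, expr, _ = generate(SyntheticConfig(**SMALL))
        write_dataset(expr, tmp_path / "expr")
        back = read_dataset(tmp_path / "expr")
        assert back.layer == expr.layer
        assert back.labels.equals(expr.labels)
        assert np.allclose(back.values.to_numpy(), expr.values.to_numpy())
        assert back.feature_ids == expr.feature_ids

    def test_unknown_class_named(self, tmp_path):
        _, expr, _ = generate(SyntheticConfig(**SMALL))
        path = write_dataset(expr, tmp_path / "expr")
        labels = (path / "labels.tsv").read_text().replace("IL-17", "IL-99")
        (path / "labels.tsv").write_text(labels)
        with pytest.raises(DatasetError, match="IL-99"):
            read_dataset(path)

    def test_non_numeric_cell_coordinates_named(self, tmp_path):
        _, expr, _ = generate(SyntheticConfig(**SMALL))
        path = write_dataset(expr, tmp_path / "expr")
        lines = (path / "matrix.tsv").read_text().splitlines()
        cells = lines[2].split("\t")
        sample_id, feature_id = cells[0], lines[0].split("\t")[3]
        cells[3] = "oops"
        lines[2] = "\t".join(cells)
        (path / "matrix.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(DatasetError) as err:
            read_dataset(path)
        assert sample_id in str(err.value) and feature_id in str(err.value)

    def test_label_sample_mismatch_named(self, tmp_path):
        _, expr, _ = generate(SyntheticConfig(**SMALL))
        path = write_dataset(expr, tmp_path / "expr")
        lines = (path / "labels.tsv").read_text().splitlines()
        dropped = lines.pop(3).split("\t")[0]
        (path / "labels.tsv").write_text("\n".join(lines) + "\n")
        with pytest.raises(DatasetError, match=dropped):
            read_dataset(path)
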