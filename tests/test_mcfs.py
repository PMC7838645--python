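"""Monte Carlo feature selection: projections, trees, RI aggregation."""

import numpy as np
import pytest

from asmsig.mcfs import (
    FeatureRanking,
    McfsParams,
    TreeRecord,
    draw_projections,
    grow_projection_tree,
    read_ranking,
    relative_importance,
    run_mcfs,
    write_ranking,
)
from asmsig.synthetic import SyntheticConfig, generate, responsive_features
from conftest import make_dataset


def ri_conservation_gap(ranking, records, params):
    """|sum_f RI_f - sum_trees wAcc^u * (total weighted gain)|."""
    total = 0.0
    for rec in records:
        w = rec.wacc ** params.u if params.u != 0 else 1.0
        total += w * sum(
            ig * (n_node / n_root) ** params.v
            for _, ig, n_node, n_root in rec.node_contributions
        )
    return abs(ranking.ri.sum() - total)


class TestProjections:
    def test_saturated_projection_is_full_set(self):
        params = McfsParams(m=10, s=1, t=1, seed=0)
        (proj,) = draw_projections(10, params)
        assert sorted(proj) == list(range(10))

    def test_uniform_coverage(self):
        params = McfsParams(m=100, s=400, t=1, seed=5)
        projections = draw_projections(2000, params)
        counts = np.zeros(2000, dtype=int)
        for proj in projections:
            assert len(set(proj)) == 100
            counts[proj] += 1
        assert counts.mean() == pytest.approx(400 * 100 / 2000)  # = 20
        # Poisson-like spread around 20: sd ~ 4.4, allow ~4.5 sd
        assert counts.min() >= 2 and counts.max() <= 40

    def test_seed_determinism(self):
        params = McfsParams(m=20, s=10, t=1, seed=9)
        a = draw_projections(100, params)
        b = draw_projections(100, params)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_m_larger_than_total_rejected(self):
        with pytest.raises(ValueError, match="m must"):
            draw_projections(5, McfsParams(m=10, s=1, t=1))


class TestProjectionTree:
    def _params(self):
        return McfsParams(m=2, s=1, t=1)

    def test_hand_computed_single_split(self):
        # 4 samples, 2 per class, perfectly separated by binary feature f;
        # root entropy is 1 bit and the split is pure: IG = 1.0 bit.
        values = np.array([[0.0, 1.0], [0.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
        labels = np.array(["A", "A", "B", "B"], dtype=object)
        idx = np.arange(4)
        rec = grow_projection_tree(
            values, labels, ["f", "const"], idx, idx, self._params()
        )
        assert rec.wacc == 1.0
        assert len(rec.node_contributions) == 1
        feat, ig, n_node, n_root = rec.node_contributions[0]
        assert feat == "f"
        assert ig == pytest.approx(1.0, abs=1e-12)
        assert n_node == n_root == 4

    def test_constant_projection_gives_no_splits(self):
        values = np.ones((6, 2))
        labels = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        idx = np.arange(6)
        rec = grow_projection_tree(
            values, labels, ["c1", "c2"], idx, idx, self._params()
        )
        assert rec.node_contributions == []

    def test_wacc_is_mean_per_class_sensitivity(self):
        # constant features force an all-majority prediction; with a 9:1
        # held-out split the weighted accuracy is 0.5, not 0.9
        train_values = np.ones((10, 1))
        train_labels = np.array(["A"] * 9 + ["B"], dtype=object)
        rec = grow_projection_tree(
            train_values, train_labels, ["c"], np.arange(10), np.arange(10),
            self._params(),
        )
        assert rec.wacc == pytest.approx(0.5)


class TestRelativeImportance:
    def _single_tree(self):
        return TreeRecord(
            features=["f", "g"], wacc=1.0,
            node_contributions=[("f", 1.0, 4, 4)],
        )

    def test_single_tree_hand_value(self):
        ranking = relative_importance(
            [self._single_tree()], ["f", "g", "h"], McfsParams(m=2, s=1, t=1)
        )
        assert ranking.feature_ids[0] == "f"
        assert ranking.ri[0] == pytest.approx(1.0)
        assert (ranking.ri[1:] == 0).all()

    def test_zero_exponents_reduce_to_ig_sum(self):
        rec = TreeRecord(
            features=["f"], wacc=0.3,
            node_contributions=[("f", 0.7, 2, 8), ("f", 0.2, 4, 8)],
        )
        ranking = relative_importance(
            [rec], ["f"], McfsParams(m=1, s=1, t=1, u=0.0, v=0.0)
        )
        assert ranking.ri[0] == pytest.approx(0.9)

    def test_duplicating_records_doubles_ri(self):
        params = McfsParams(m=2, s=1, t=1)
        one = relative_importance([self._single_tree()], ["f", "g"], params)
        two = relative_importance(
            [self._single_tree(), self._single_tree()], ["f", "g"], params
        )
        assert np.allclose(two.ri, 2 * one.ri)

    def test_ties_broken_lexicographically(self):
        recs = [
            TreeRecord(features=["b"], wacc=1.0,
                       node_contributions=[("b", 0.5, 4, 4)]),
            TreeRecord(features=["a"], wacc=1.0,
                       node_contributions=[("a", 0.5, 4, 4)]),
        ]
        ranking = relative_importance(recs, ["b", "a"], McfsParams(m=1, s=1, t=1))
        assert ranking.feature_ids == ["a", "b"]


class TestRunMcfs:
    SMALL = McfsParams(m=20, s=60, t=2, seed=13)

    def _dataset(self, seed=13):
        cfg = SyntheticConfig(
            n_per_group=32, n_expr_features=200, n_meth_features=15,
            n_il13_features=5, n_il17_features=5, n_combo_features=5,
            effect_size=2.0, noise_sd=1.0, seed=seed,
        )
        _, expr, _ = generate(cfg)
        return cfg, expr

    def test_recovers_responsive_features(self):
        cfg, expr = self._dataset()
        ranking = run_mcfs(expr, self.SMALL)
        resp = [f for fs in responsive_features(cfg, "expression").values()
                for f in fs]
        top = set(ranking.top(50))
        assert sum(f in top for f in resp) >= 14  # 15 responsive in 200

    def test_permuted_labels_rank_responsive_at_chance(self):
        cfg, expr = self._dataset()
        rng = np.random.default_rng(99)
        permuted = expr.labels.sample(frac=1.0, random_state=1)
        permuted.index = expr.labels.index
        shuffled = make_dataset(
            expr.values.to_numpy(), permuted.to_list(),
            feature_ids=expr.feature_ids,
        )
        ranking = run_mcfs(shuffled, self.SMALL)
        resp = [f for fs in responsive_features(cfg, "expression").values()
                for f in fs]
        top = set(ranking.top(50))
        # chance overlap: 50 * 15 / 200 = 3.75
        assert sum(f in top for f in resp) <= 9

    def test_ri_conservation(self):
        _, expr = self._dataset()
        ranking, records = run_mcfs(expr, self.SMALL, return_records=True)
        assert ri_conservation_gap(ranking, records, self.SMALL) < 1e-9

    def test_determinism_and_column_order_invariance(self):
        _, expr = self._dataset()
        a = run_mcfs(expr, self.SMALL)
        shuffled_cols = expr.values.sample(frac=1.0, axis=1, random_state=3)
        b = run_mcfs(
            make_dataset(shuffled_cols.to_numpy(), expr.labels.to_list(),
                         feature_ids=list(shuffled_cols.columns)),
            self.SMALL,
        )
        assert a.feature_ids == b.feature_ids
        assert np.allclose(a.ri, b.ri)

    def test_injected_perfect_feature_ranks_first(self):
        rng = np.random.default_rng(31)
        labels = np.repeat(["A", "B", "C", "D"], 10)
        values = rng.normal(size=(40, 50))
        values[:, 17] = np.repeat([0.0, 1.0, 2.0, 3.0], 10)  # class-determining
        ds = make_dataset(values, labels)
        ranking = run_mcfs(ds, McfsParams(m=10, s=400, t=5, seed=1))
        assert ranking.feature_ids[0] == "F017"

    def test_single_class_rejected(self):
        ds = make_dataset(np.random.default_rng(0).normal(size=(10, 5)),
                          ["A"] * 10)
        with pytest.raises(ValueError, match="2 classes"):
            run_mcfs(ds, McfsParams(m=2, s=1, t=1))

    def test_ranking_tsv_round_trip(self, tmp_path):
        _, expr = self._dataset()
        ranking = run_mcfs(expr, McfsParams(m=10, s=10, t=1, seed=2))
        write_ranking(ranking, tmp_path / "rank.tsv")
        back = read_ranking(tmp_path / "rank.tsv")
        assert back.feature_ids == ranking.feature_ids
        assert np.allclose(back.ri, ranking.ri)
        assert (back.tree_counts == ranking.tree_counts).all()
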