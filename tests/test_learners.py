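import numpy as np
import pytest

from leafspec import (
    fod_sweep,
    evaluate_grid,
    make_split,
    metrics,
    train_learner,
)
from leafspec.preprocess import trim_edges, savgol_smooth


class TestSplit:
    def test_default_293_split(self):
        split = make_split(293, seed=0)
        assert split.sizes == (187, 59, 47)

    def test_partition_is_disjoint_and_exhaustive(self):
        split = make_split(100, sizes=(60, 25, 15), seed=1)
        all_idx = np.concatenate(
            [split.train_index, split.test_index, split.validation_index]
        )
        assert sorted(all_idx) == list(range(100))

    def test_seed_determinism(self):
        a, b = make_split(50, seed=7), make_split(50, seed=7)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            make_split(100, sizes=(50, 30, 30))


class TestTrainLearner:
    def test_unknown_name_lists_valid_learners(self):
        with pytest.raises(ValueError, match="RR"):
            train_learner("MLP", np.zeros((4, 2)), np.zeros(4))

    def test_ridge_without_penalty_equals_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.2, 40)
        model = train_learner("RR", X, y, hyper={"alpha": 0.0})
        coef = np.linalg.lstsq(
            np.column_stack([X, np.ones(40)]), y, rcond=None
        )[0]
        np.testing.assert_allclose(
            model.predict(X), np.column_stack([X, np.ones(40)]) @ coef, atol=1e-8
        )

    @pytest.mark.parametrize("name", ["RF", "XGBoost"])
    def test_tree_learners_on_constant_response(self, name):
        rng = np.random.default_rng(1)
        X = rng.random((30, 4))
        y = np.full(30, 5.0)
        model = train_learner(name, X, y, hyper={"n_estimators": 20})
        np.testing.assert_allclose(model.predict(X), 5.0, atol=1e-5)

    def test_gpr_interpolates_training_points(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-2, 2, size=(25, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        model = train_learner("GPR", X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-3)


class TestMetrics:
    def test_perfect_prediction(self):
        m = metrics(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))
        assert (m.r2, m.mae, m.rmse) == (1.0, 0.0, 0.0)
        assert np.isnan(m.rpiq)  # undefined, not infinite

    def test_hand_worked_example(self):
        m = metrics(np.array([1.0, 2.0, 3.0, 4.0]), np.full(4, 2.0))
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(1.5))
        assert m.r2 == pytest.approx(-0.2)

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([2.0, 4.0, 9.0, 1.0])
        m = metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_constant_observations_give_nan_r2(self):
        m = metrics(np.full(4, 3.0), np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.isnan(m.r2)

    def test_invariants_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = rng.integers(4, 40)
            y = rng.normal(0, rng.uniform(0.5, 10), n)
            y_hat = y + rng.normal(0, rng.uniform(0.01, 5), n)
            m = metrics(y, y_hat)
            assert m.rmse >= m.mae >= 0
            q1, q3 = np.percentile(y, [25, 75])
            assert m.rpiq * m.rmse == pytest.approx(q3 - q1, abs=1e-9)


@pytest.fixture(scope="module")
def small_grid(small_dataset):
    spectra, traits = small_dataset
    s = savgol_smooth(trim_edges(spectra))
    fods = fod_sweep(s, orders=[0.0, 0.6])
    selections = {
        0.0: np.array([550, 700, 720, 850]),
        0.6: np.array([550, 700, 720, 850]),
    }
    split = make_split(40, sizes=(26, 8, 6), seed=0)
    return evaluate_grid(
        fods, selections, traits.lcc, split, learners=("RR", "GPR"), seed=0
    )


class TestEvaluateGrid:

    def test_row_structure(self, small_grid):
        assert len(small_grid.table) == 4  # 2 orders x 2 learners
        assert set(small_grid.table["algorithm"]) == {"RR", "GPR"}

    def test_validation_rpiq_present_and_consistent(self, small_grid):
        for _, row in small_grid.table.iterrows():
            if row["validation_rmse"] > 0:
                assert np.isfinite(row["validation_rpiq"])

    def test_long_table_mirrors_wide(self, small_grid):
        long = small_grid.long()
        assert len(long) == 12  # 4 combos x 3 splits
        wide_val = small_grid.table.set_index(["order", "algorithm"])["validation_r2"]
        for (order, alg), expected in wide_val.items():
            got = long.query(
                "order == @order and algorithm == @alg and split == 'validation'"
            )["r2"].iloc[0]
            assert got == expected

    def test_missing_selection_skipped_with_warning(self, small_dataset):
        spectra, traits = small_dataset
        s = savgol_smooth(trim_edges(spectra))
        fods = fod_sweep(s, orders=[0.0, 1.0])
        split = make_split(40, sizes=(26, 8, 6), seed=0)
        with pytest.warns(UserWarning, match="skipped"):
            report = evaluate_grid(
                fods, {0.0: np.array([550, 720])}, traits.lcc, split,
                learners=("RR",), seed=0,
            )
        assert set(report.table["order"]) == {0.0}

    def test_strong_signal_yields_high_validation_r2(self, small_grid):
        assert small_grid.table["validation_r2"].max() >= 0.85
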