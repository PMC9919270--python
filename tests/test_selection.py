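import numpy as np
import pytest

from leafspec import (
    SelectionConfig,
    bms_sample,
    edf_schedule,
    exhaustive_best_subset,
    ga_optimize,
    make_planted_bands,
    mpa_frequencies,
    vcpa_ga_select,
    vcpa_select,
    vcpa_shrink,
)
from leafspec._pls import cv_score, make_folds

FAST = dict(
    omega=20,
    edf_runs=6,
    bms_draws=60,
    replications=2,
    ga_population=12,
    ga_generations=8,
)


class TestBMS:
    def test_inclusion_frequency_near_probability(self):
        M = bms_sample(50, 1000, prob=0.5, seed=0)
        freq = M.mean(axis=0)
        se = np.sqrt(0.25 / 1000)
        assert np.all(np.abs(freq - 0.5) < 3 * se + 0.02)

    def test_seed_determinism(self):
        np.testing.assert_array_equal(bms_sample(20, 50, seed=5), bms_sample(20, 50, seed=5))

    def test_minimum_two_variables_enforced(self):
        M = bms_sample(2, 200, prob=0.5, seed=1)
        assert np.all(M.sum(axis=1) == 2)  # redraw forces [1, 1]


class TestEDF:
    def test_boundary_counts(self):
        sched = edf_schedule(501, 100, 50)
        assert sched[0] == 501 and sched[-1] == 100 and len(sched) == 50
        assert np.all(np.diff(sched) <= 0)

    def test_two_point_schedule(self):
        np.testing.assert_array_equal(edf_schedule(30, 5, 2), [30, 5])

    def test_invalid_endpoints(self):
        with pytest.raises(ValueError):
            edf_schedule(10, 10, 5)


class TestMPA:
    def test_always_present_variable_scores_one(self):
        subsets = np.array([[1, 1, 0], [1, 0, 1], [1, 0, 0], [1, 1, 1]], dtype=bool)
        freq = mpa_frequencies(subsets, np.array([0.1, 0.2, 0.3, 0.4]), 0.5)
        assert freq[0] == 1.0

    def test_ten_percent_of_ten_subsets_is_the_single_best(self):
        rng = np.random.default_rng(0)
        subsets = rng.random((10, 4)) < 0.5
        scores = np.arange(10.0)
        freq = mpa_frequencies(subsets, scores, 0.10)
        np.testing.assert_array_equal(freq, subsets[0].astype(float))

    def test_planted_design_separates_informative_variable(self):
        # A sits in every low-score subset, B in every high-score one
        subsets = np.zeros((20, 3), dtype=bool)
        subsets[:10, 0] = True
        subsets[10:, 1] = True
        subsets[:, 2] = True
        scores = np.concatenate([np.full(10, 1.0), np.full(10, 9.0)])
        freq = mpa_frequencies(subsets, scores, 0.5)
        assert freq[0] == 1.0 and freq[1] == 0.0 and freq[2] == 1.0


class TestShrink:
    def test_noop_guard_returns_input_indices(self):
        rng = np.random.default_rng(0)
        X, y = rng.random((30, 10)), rng.random(30)
        cfg = SelectionConfig(omega=10, **{k: v for k, v in FAST.items() if k != "omega"})
        np.testing.assert_array_equal(vcpa_shrink(X, y, cfg), np.arange(10))

    def test_deterministic_under_seed(self):
        X, y, _ = make_planted_bands(n=60, p=40, n_informative=3, seed=1)
        cfg = SelectionConfig(**{**FAST, "omega": 10})
        np.testing.assert_array_equal(
            vcpa_shrink(X, y, cfg, seed=3), vcpa_shrink(X, y, cfg, seed=3)
        )

    def test_informative_bands_survive_shrinkage(self):
        hits = 0
        for seed in range(5):
            X, y, planted = make_planted_bands(n=80, p=60, n_informative=3, seed=seed)
            cfg = SelectionConfig(**{**FAST, "omega": 12, "bms_draws": 150})
            surv = vcpa_shrink(X, y, cfg, seed=seed)
            hits += np.isin(planted, surv).sum()
        assert hits >= 12  # >= 80% of 15 planted bands survive


class TestGA:
    def test_recovers_enumeration_optimum_on_toy_problem(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((50, 6))
        y = X[:, 1] - 2 * X[:, 4] + rng.normal(0, 0.3, 50)
        cfg = SelectionConfig(
            omega=6, ga_population=12, ga_generations=60,
            edf_runs=6, bms_draws=60, replications=1,
        )
        fid = make_folds(y, 5, 77)
        # independent oracle: brute-force enumeration of all 63 subsets
        best_score, best = np.inf, None
        for code in range(1, 64):
            cols = np.array([b for b in range(6) if code >> b & 1])
            s = cv_score(X[:, cols], y, fid, 10)
            if s < best_score:
                best_score, best = s, cols
        got = ga_optimize(X, y, cfg, seed=0, fold_id=fid)
        np.testing.assert_array_equal(got, best)

    def test_stagnant_population_without_operators(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        cfg = SelectionConfig(
            omega=5, ga_population=4, ga_generations=5,
            ga_crossover=0.0, ga_mutation=0.0,
            edf_runs=6, bms_draws=60, replications=1,
        )
        # every run starts from the seeded random population; with no
        # crossover/mutation the best chromosome can only come from it
        out1 = ga_optimize(X, y, cfg, seed=9)
        out2 = ga_optimize(X, y, cfg, seed=9)
        np.testing.assert_array_equal(out1, out2)


class TestExhaustive:
    def test_finds_true_subset_on_clean_signal(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + 3 * X[:, 3]
        cfg = SelectionConfig(**FAST)
        best = exhaustive_best_subset(X, y, cfg, seed=0)
        assert set(best).issuperset({0, 3})

    def test_cap_enforced(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="capped"):
            exhaustive_best_subset(
                rng.random((10, 20)), rng.random(10), SelectionConfig(**FAST)
            )


@pytest.fixture(scope="module")
def planted_run():
    X, y, planted = make_planted_bands(n=90, p=60, n_informative=3, seed=2)
    cfg = SelectionConfig(**{**FAST, "omega": 15, "bms_draws": 100})
    return X, y, planted, cfg, vcpa_ga_select(X, y, cfg, seed=1)


class TestSelectDrivers:

    def test_variable_count_trajectory(self, planted_run):
        X, _, _, cfg, sel = planted_run
        assert X.shape[1] > cfg.omega > sel.nvar >= 2

    def test_informative_recall(self, planted_run):
        _, _, planted, _, sel = planted_run
        assert np.isin(planted, sel.selected).mean() >= 0.8

    def test_reproducible_under_seed(self, planted_run):
        X, y, _, cfg, sel = planted_run
        again = vcpa_ga_select(X, y, cfg, seed=1)
        np.testing.assert_array_equal(sel.selected, again.selected)
        assert sel.rmsep == again.rmsep
        assert sel.replicates["rmsecv"].tolist() == again.replicates["rmsecv"].tolist()

    def test_replicate_bookkeeping(self, planted_run):
        _, _, _, cfg, sel = planted_run
        assert len(sel.replicates) == cfg.replications
        assert sel.rmsecv == sel.replicates["rmsecv"].min()
        assert sel.frequency.max() <= 1.0 and sel.frequency.min() >= 0.0
        assert np.intersect1d(sel.calibration_index, sel.test_index).size == 0

    def test_plain_vcpa_selects_few_variables(self):
        X, y, planted = make_planted_bands(n=70, p=30, n_informative=2, seed=6)
        cfg = SelectionConfig(
            **{**FAST, "omega": 20, "replications": 1, "plain_terminal_vars": 8}
        )
        sel = vcpa_select(X, y, cfg, seed=0)
        assert 1 <= sel.nvar <= 8
        assert np.isin(planted, sel.selected).all()
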