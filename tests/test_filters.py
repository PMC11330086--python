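import itertools
import math

import numpy as np
import pytest

from chemgroup.descriptors import FeatureMatrix
from chemgroup.filters import (
    GAConfig,
    SAConfig,
    auto_threshold_search,
    column_stats,
    correlation_filter,
    ga_select,
    rfe_select,
    rfe_size_path,
    sa_select,
    variance_filter,
)
from chemgroup.learners import LearnerSpec


def _fm(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"c{i}" for i in range(values.shape[1])]
    return FeatureMatrix([f"r{i}" for i in range(values.shape[0])], names, values)


class TestVarianceFilter:
    def test_constant_column_removed_at_zero(self):
        fm = _fm([[1, 0], [1, 1], [1, 0]])
        res = variance_filter(fm, 0.0)
        assert res.removed_columns == ["c0"] and res.kept_columns == ["c1"]

    def test_half_frequency_bit_kept_at_low_threshold(self):
        col = np.array([0, 1] * 10, dtype=float)  # variance 0.25
        fm = _fm(np.column_stack([col, np.zeros(20)]))
        res = variance_filter(fm, 0.05)
        assert "c0" in res.kept_columns

    def test_partition_invariant_and_projection(self):
        rng = np.random.default_rng(0)
        fm = _fm(rng.random((30, 8)))
        res = variance_filter(fm, 0.05)
        assert sorted(res.kept_columns + res.removed_columns) == sorted(fm.column_names)
        again = variance_filter(res.apply(fm), res.threshold)
        assert again.kept_columns == res.kept_columns  # filters are projections

    def test_all_removed_is_error(self):
        fm = _fm([[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="removed every column"):
            variance_filter(fm, 0.0)


class TestCorrelationFilter:
    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.random(20)
        fm = _fm(np.column_stack([x, x]))
        res = correlation_filter(fm, 0.99)
        assert res.kept_columns == ["c0"] and res.removed_columns == ["c1"]

    def test_orthogonal_columns_both_kept(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # r = 0
        res = correlation_filter(_fm(np.column_stack([x, y])), 0.5)
        assert res.removed_columns == []

    def test_matches_exhaustive_pair_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=40)
        values = np.column_stack(
            [base, base + 0.1 * rng.normal(size=40), rng.normal(size=40),
             -base + 0.15 * rng.normal(size=40)]
        )
        fm = _fm(values)
        threshold = 0.8
        # independent oracle: brute-force all pairs, apply the greedy rule
        corr = np.corrcoef(values, rowvar=False)
        keep = [True] * 4
        for i, j in itertools.combinations(range(4), 2):
            if keep[i] and keep[j] and abs(corr[i, j]) > threshold:
                keep[j] = False
        expected = [f"c{i}" for i in range(4) if keep[i]]
        assert correlation_filter(fm, threshold).kept_columns == expected

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            correlation_filter(_fm(np.eye(3)), 1.5)


class TestAutoThresholdSearch:
    def test_single_value_grid(self, planted_fm):
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        res = auto_threshold_search(fm, y, spec, "variance", grid=[0.01], seed=0)
        assert res.threshold == 0.01 and len(res.search_trace) == 1

    def test_planted_informative_columns_survive(self):
        rng = np.random.default_rng(0)
        n = 300
        informative = rng.normal(scale=np.sqrt(0.2), size=(n, 5))
        noise = rng.normal(scale=np.sqrt(0.005), size=(n, 45))
        logits = 2.0 * informative.sum(axis=1)
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        names = [f"inf{i}" for i in range(5)] + [f"noise{i}" for i in range(45)]
        fm = FeatureMatrix([f"r{i}" for i in range(n)], names,
                           np.column_stack([informative, noise]))
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        res = auto_threshold_search(fm, y, spec, "variance", seed=0)
        assert 0.01 <= res.threshold <= 0.1
        assert set(f"inf{i}" for i in range(5)) <= set(res.kept_columns)

    def test_constant_labels_rejected(self, planted_fm):
        fm, _ = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        with pytest.raises(ValueError, match="constant"):
            auto_threshold_search(fm, np.zeros(fm.n), spec, "variance")


class TestColumnStats:
    def test_constant_column_convention(self):
        stats = column_stats(_fm([[1.0], [1.0], [1.0]]))
        row = stats.frame.loc["c0"]
        assert row["variance"] == 0 and row["skewness"] == 0 and row["kurtosis"] == 0

    def test_symmetric_column_zero_skew(self):
        stats = column_stats(_fm([[-1.0], [0.0], [1.0]]))
        assert abs(stats.frame.loc["c0", "skewness"]) < 1e-12

    def test_moments_match_direct_formulas(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        stats = column_stats(_fm(x[:, None]))
        m = x.mean()
        var = ((x - m) ** 2).mean()
        skew = ((x - m) ** 3).mean() / var**1.5
        kurt = ((x - m) ** 4).mean() / var**2 - 3
        row = stats.frame.loc["c0"]
        assert np.allclose([row["mean"], row["variance"], row["skewness"], row["kurtosis"]],
                           [m, var, skew, kurt])


class TestRFE:
    def test_elimination_size_recurrence(self):
        # independent simulation of max(1, floor(0.2 p)) removal
        def simulate(p):
            sizes = [p]
            while sizes[-1] > 1:
                sizes.append(sizes[-1] - max(1, math.floor(0.2 * sizes[-1])))
            return sizes

        for p in (10, 50, 93, 7):
            assert rfe_size_path(p) == simulate(p)
        assert rfe_size_path(10)[:4] == [10, 8, 7, 6]

    def test_trace_follows_size_path(self, planted_fm):
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        res = rfe_select(fm, y, spec, cv_folds=3)
        assert [p for p, _ in res.score_trace] == rfe_size_path(fm.p)
        assert set(res.selected_columns) <= set(fm.column_names)
        assert res.selected_columns

    def test_single_column_returned_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 1))
        y = (x[:, 0] > 0).astype(int)
        fm = _fm(x)
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        res = rfe_select(fm, y, spec, cv_folds=3)
        assert res.selected_columns == ["c0"]
        assert res.final_score == res.score_trace[0][1]


class TestGA:
    def test_zero_generations_returns_best_initial_member(self, planted_fm):
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        cfg = GAConfig(population_size=6, n_generations=0, cv_folds=3, seed=1)
        res = ga_select(fm, y, spec, cfg)
        assert len(res.score_trace) == 1
        assert res.selected_columns

    def test_best_ever_trace_is_non_decreasing(self, planted_fm):
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        cfg = GAConfig(population_size=8, n_generations=4, cv_folds=3, seed=0)
        res = ga_select(fm, y, spec, cfg)
        scores = [s for _, s in res.score_trace]
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert res.final_score == scores[-1]

    def test_population_smaller_than_tournament_errors(self, planted_fm):
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        with pytest.raises(ValueError, match="tournament"):
            ga_select(fm, y, spec, GAConfig(population_size=2, tournament_size=3))


class TestSA:
    def test_initial_subset_size_ceil_rule(self):
        assert math.ceil(0.5 * 93) == 47  # the rule the implementation applies

    def test_cooling_schedule_hits_iteration_cap_not_floor(self, planted_fm):
        # 0.95^50 ≈ 0.077 > 0.01, so with T0=1 the run ends by iteration cap
        assert 0.95**50 > 0.01
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        cfg = SAConfig(seed=0)
        res = sa_select(fm, y, spec, cfg)
        assert len(res.score_trace) == cfg.max_iterations + 1

    def test_greedy_limit_never_worse_than_start(self, planted_fm):
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        cfg = SAConfig(initial_temperature=1e-12, max_iterations=20, seed=0,
                       min_temperature=0.0)
        res = sa_select(fm, y, spec, cfg)
        assert res.final_score >= res.score_trace[0][1]

    def test_selected_subset_of_inputs_nonempty(self, planted_fm):
        fm, y = planted_fm
        spec = LearnerSpec("logistic_regression", "classification", seed=0)
        res = sa_select(fm, y, spec, SAConfig(max_iterations=10, seed=2))
        assert res.selected_columns and set(res.selected_columns) <= set(fm.column_names)
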