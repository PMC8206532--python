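import numpy as np
import pytest

from miosel.data_model import PredictorMatrix, ResponseVector, Timepoint
from miosel.subset_select import (
    EnumerationCapError,
    EnumerationExhausted,
    SelectionConfig,
    count_candidate_models,
    exhaustive_best_subsets,
    fit_support,
    k_best_subsets,
    solve_best,
    standardize,
)

from conftest import make_design


def _matrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or list(range(values.shape[1]))
    return PredictorMatrix(
        values, ids, [str(i) for i in ids], [Timepoint.BASELINE] * values.shape[1]
    )


class TestStandardize:
    def test_three_point_column(self):
        X = _matrix([[1, 10], [2, 20], [3, 33]])
        d = standardize(X, ResponseVector([5.0, 6.0, 9.0]))
        assert np.allclose(d.Xs[:, 0], [-1, 0, 1])

    def test_constant_column_dropped_with_report(self):
        X = _matrix([[1, 7], [2, 7], [3, 7]])
        d = standardize(X, ResponseVector([1.0, 2.0, 3.0]))
        assert d.dropped_ids == [1]
        assert d.t == 1

    def test_all_constant_fatal(self):
        X = _matrix([[7, 7], [7, 7], [7, 7]])
        with pytest.raises(ValueError, match="constant"):
            standardize(X, ResponseVector([1.0, 2.0, 3.0]))

    def test_random_matrix_moments(self):
        rng = np.random.default_rng(4)
        X = _matrix(rng.normal(2, 3, size=(20, 5)))
        d = standardize(X, ResponseVector(rng.normal(size=20)))
        assert np.abs(d.Xs.mean(axis=0)).max() < 1e-10
        assert np.abs(d.Xs.std(axis=0, ddof=1) - 1).max() < 1e-10
        assert abs(d.ys.mean()) < 1e-10 and abs(d.ys.std(ddof=1) - 1) < 1e-10


class TestFitSupport:
    def test_exact_single_predictor(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(15, 3))
        X = _matrix(vals)
        y = ResponseVector(vals[:, 1].copy())
        d = standardize(X, y)
        coefs, rss, degenerate = fit_support(d, {1})
        assert coefs[1] == pytest.approx(1.0, abs=1e-10)
        assert rss == pytest.approx(0.0, abs=1e-10)
        assert not degenerate

    def test_empty_support_rss_is_n_minus_one(self):
        _, _, d = make_design(2, n=30)
        _, rss, _ = fit_support(d, set())
        assert rss == pytest.approx(29.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        """RSS from the Gram route equals a direct normal-equations solve."""
        rng = np.random.default_rng(7)
        for trial in range(10):
            _, _, d = make_design(100 + trial, n=40, t=8)
            support = sorted(rng.choice(8, size=rng.integers(1, 5), replace=False).tolist())
            coefs, rss, _ = fit_support(d, support)
            A = d.Xs[:, support]
            beta = np.linalg.solve(A.T @ A, A.T @ d.ys)
            resid = d.ys - A @ beta
            assert rss == pytest.approx(float(resid @ resid), abs=1e-8)
            assert np.allclose([coefs[j] for j in support], beta, atol=1e-8)

    def test_rank_deficient_flagged(self):
        vals = np.random.default_rng(3).normal(size=(20, 2))
        X = _matrix(np.column_stack([vals[:, 0], vals[:, 0], vals[:, 1]]))
        d = standardize(X, ResponseVector(vals[:, 1] + 0.1 * vals[:, 0]))
        _, rss, degenerate = fit_support(d, {0, 1, 2})
        assert degenerate
        assert rss == pytest.approx(0.0, abs=1e-8)


class TestCounting:
    def test_study_pool_sizes(self):
        assert count_candidate_models(1170, 3) == 266_251_440
        assert count_candidate_models(1170, 4) == 77_678_857_620

    def test_degenerate_cases(self):
        assert count_candidate_models(5, 0) == 1
        with pytest.raises(ValueError):
            count_candidate_models(3, 4)

    def test_cap_refusal_states_count(self, small_design):
        _, _, d = small_design
        with pytest.raises(EnumerationCapError, match="220"):
            exhaustive_best_subsets(d, 3, 1, cap=100)  # C(12,3) = 220


class TestSolveBest:
    def test_dominant_predictor(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(40, 6))
        X = _matrix(vals)
        y = ResponseVector(vals[:, 3] + rng.normal(0, 1e-3, 40))
        d = standardize(X, y)
        rec = solve_best(d, 1)
        assert rec.support == frozenset({3})

    @pytest.mark.parametrize("backend", ["enumeration", "branch_and_bound"])
    def test_exclusion_constraint_respected(self, backend):
        """Excluding the optimal pair forces a different, no-better support."""
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(40, 6))
        X = _matrix(vals)
        y = ResponseVector(vals[:, 1] + 0.8 * vals[:, 2] + rng.normal(0, 0.1, 40))
        d = standardize(X, y)
        cfg = SelectionConfig(p_max=2, backend=backend)
        free = solve_best(d, 2, config=cfg)
        assert free.support == frozenset({1, 2})
        constrained = solve_best(d, 2, exclusions=[{1, 2}], config=cfg)
        assert constrained.support != frozenset({1, 2})
        assert constrained.rss >= free.rss - 1e-12

    def test_over_exclusion_exhausts(self):
        X = _matrix(np.random.default_rng(8).normal(size=(10, 2)))
        y = ResponseVector(X.values[:, 0] + 0.1 * X.values[:, 1])
        d = standardize(X, y)
        with pytest.raises(EnumerationExhausted):
            solve_best(d, 1, exclusions=[{0}, {1}])

    def test_time_limit_returns_uncertified_incumbent(self, small_design):
        _, _, d = small_design
        cfg = SelectionConfig(p_max=3, backend="branch_and_bound", solver_time_limit_s=0.0)
        rec = solve_best(d, 3, config=cfg)
        assert not rec.certified
        assert rec.n_terms == 3  # greedy incumbent still a valid support


class TestKBest:
    def test_complete_enumeration_tiny(self):
        """t=3, p=2, k=3 returns all three pairs in nondecreasing RSS order."""
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(25, 3))
        X = _matrix(vals)
        y = ResponseVector(vals @ np.array([1.0, 0.5, 0.0]) + rng.normal(0, 0.2, 25))
        d = standardize(X, y)
        models = [
            m
            for m in k_best_subsets(d, SelectionConfig(p_max=2, k=3))
            if m.n_terms == 2
        ]
        assert {m.support for m in models} == {
            frozenset({0, 1}),
            frozenset({0, 2}),
            frozenset({1, 2}),
        }
        assert models[0].rss <= models[1].rss <= models[2].rss

    def test_truncation_warns_when_supports_run_out(self):
        X = _matrix(np.random.default_rng(10).normal(size=(10, 2)))
        y = ResponseVector(X.values[:, 0] + 0.2 * X.values[:, 1])
        d = standardize(X, y)
        with pytest.warns(UserWarning, match="truncated"):
            models = k_best_subsets(d, SelectionConfig(p_max=1, k=5))
        assert len(models) == 2

    @pytest.mark.parametrize("backend", ["enumeration", "branch_and_bound"])
    def test_matches_oracle_ranked_lists(self, backend):
        """Solver-ranked (support, RSS) lists equal the orthogonalization oracle."""
        for seed in range(3):
            _, _, d = make_design(40 + seed, n=60, t=15)
            cfg = SelectionConfig(p_max=3, k=5, backend=backend)
            models = k_best_subsets(d, cfg)
            for p in (1, 2, 3):
                got = [m for m in models if m.n_terms == p]
                want = exhaustive_best_subsets(d, p, 5)
                assert [m.sorted_support for m in got] == [m.sorted_support for m in want]
                assert np.allclose(
                    [m.rss for m in got], [m.rss for m in want], atol=1e-8
                )

    def test_rank_and_size_monotonicity(self, reduced_fit):
        models = reduced_fit.models
        best_by_size = {}
        for p in (1, 2, 3):
            sized = [m for m in models if m.n_terms == p]
            rss = [m.rss for m in sized]
            assert rss == sorted(rss)
            assert len({m.support for m in sized}) == len(sized)
            best_by_size[p] = rss[0]
        assert best_by_size[3] <= best_by_size[2] <= best_by_size[1]


class TestExhaustiveOracle:
    def test_full_support_when_p_equals_t(self):
        _, _, d = make_design(20, n=30, t=5)
        models = exhaustive_best_subsets(d, 5, 3)
        assert len(models) == 1
        assert models[0].support == frozenset(range(5))

    def test_returns_all_supports_when_k_exhausts(self):
        _, _, d = make_design(21, n=30, t=6)
        models = exhaustive_best_subsets(d, 2, count_candidate_models(6, 2))
        assert len(models) == 15
        assert len({m.support for m in models}) == 15

    def test_deterministic_tie_break(self):
        """Duplicate columns create exact RSS ties, resolved lexicographically."""
        rng = np.random.default_rng(12)
        base = rng.normal(size=(30, 2))
        X = _matrix(np.column_stack([base[:, 0], base[:, 0], base[:, 1]]))
        y = ResponseVector(base[:, 0] + rng.normal(0, 0.5, 30))
        d = standardize(X, y)
        models = exhaustive_best_subsets(d, 1, 2)
        assert models[0].support == frozenset({0})
        assert models[1].support == frozenset({1})
        assert models[0].rss == pytest.approx(models[1].rss, abs=1e-12)
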