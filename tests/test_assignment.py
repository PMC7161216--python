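import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lapnet.assignment import (
    Assignment,
    AugmentedCostMatrix,
    CostMatrix,
    assignment_cost,
    build_augmented_matrix,
    classify_outcome,
    load_matrix,
    save_matrix,
    solve_brute_force,
    solve_exact,
)


class TestBuildAugmentedMatrix:
    def test_degenerate_no_predictions(self):
        aug = build_augmented_matrix([], [(0.0, 0.0)], threshold=1.0)
        assert aug.values.shape == (1, 1)
        assert aug.values[0, 0] == 1.0  # pure new-measurement diagonal

    def test_block_layout_2x3(self):
        preds = [(0.0, 0.0), (1.0, 0.0)]
        meas = [(0.0, 0.1), (1.0, 0.1), (5.0, 5.0)]
        aug = build_augmented_matrix(preds, meas, threshold=1.0, big_value=50.0)
        v = aug.values
        assert v.shape == (5, 5)
        # lost block: tau on diagonal, big elsewhere
        assert v[0, 3] == 1.0 and v[1, 4] == 1.0
        assert v[0, 4] == 50.0 and v[1, 3] == 50.0
        # new block diagonal
        assert v[2, 0] == 1.0 and v[3, 1] == 1.0 and v[4, 2] == 1.0
        assert v[2, 1] == 50.0
        # bottom-right mirrors the distance block
        np.testing.assert_allclose(v[2:, 3:], v[:2, :3].T)

    def test_distances_hand_computed(self):
        # independent oracle: hand-computed Euclidean distances
        preds = [(0.0, 0.0), (1.0, 0.0)]
        meas = [(0.0, 0.1), (1.0, 0.1), (5.0, 5.0)]
        aug = build_augmented_matrix(preds, meas, threshold=1.0)
        expected_row0 = [0.1, np.sqrt(1 + 0.01), np.sqrt(50)]
        np.testing.assert_allclose(aug.values[0, :3], expected_row0)

    def test_default_big_value_dominates(self):
        aug = build_augmented_matrix([(0, 0)], [(30, 40)], threshold=2.0)
        assert aug.big_value > aug.threshold
        assert aug.big_value > aug.distance_block.max()

    def test_empty_both_rejected(self):
        with pytest.raises(ValueError):
            build_augmented_matrix([], [], threshold=1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            build_augmented_matrix([(np.nan, 0)], [(0, 0)], threshold=1.0)

    def test_big_value_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            build_augmented_matrix([(0, 0)], [(0, 0)], threshold=5.0, big_value=1.0)


class TestSolveExact:
    def test_identity_case(self):
        a = solve_exact(CostMatrix(np.array([[0.0, 1.0], [1.0, 0.0]])))
        assert a.permutation == (0, 1)
        assert a.total_cost == 0.0

    def test_three_by_three_brute_forced(self):
        # expected values frozen from exhaustive enumeration of all 6 perms
        m = np.array([[4.0, 1, 3], [2, 0, 5], [3, 2, 2]])
        a = solve_exact(CostMatrix(m))
        assert a.total_cost == 5.0
        assert a.permutation == (1, 0, 2)

    def test_one_by_one(self):
        a = solve_exact(CostMatrix(np.array([[7.0]])))
        assert a.permutation == (0,)
        assert a.total_cost == 7.0

    def test_maximize_sense(self):
        m = np.array([[1.0, 10.0], [10.0, 1.0]])
        a = solve_exact(CostMatrix(m, sense="maximize"))
        assert a.permutation == (1, 0)
        assert a.total_cost == 20.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            solve_exact(np.ones((2, 3)))

    def test_tie_break_lexicographic(self):
        a = solve_exact(CostMatrix(np.ones((3, 3))))
        assert a.permutation == (0, 1, 2)


class TestSolveBruteForce:
    def test_one_by_one(self):
        assert solve_brute_force(np.array([[1.0]])).total_cost == 1.0

    def test_size_guard(self):
        with pytest.raises(ValueError, match="refused"):
            solve_brute_force(np.ones((10, 10)))

    def test_agrees_with_exact_on_200_random_5x5(self, rng):
        for _ in range(200):
            m = rng.random((5, 5))
            assert solve_brute_force(m).total_cost == pytest.approx(
                solve_exact(m).total_cost
            )

    @given(n=st.integers(2, 5), seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_property(self, n, seed):
        m = np.random.default_rng(seed).random((n, n))
        bf = solve_brute_force(m)
        ex = solve_exact(m)
        assert ex.total_cost == pytest.approx(bf.total_cost)

    def test_maximize_agrees_with_exact(self, rng):
        for _ in range(50):
            m = CostMatrix(rng.random((4, 4)), sense="maximize")
            assert solve_brute_force(m).total_cost == pytest.approx(
                solve_exact(m).total_cost
            )


class TestAssignmentCost:
    def test_identity(self):
        m = np.array([[4.0, 1.0], [2.0, 0.0]])
        assert assignment_cost(m, [0, 1]) == 4.0

    def test_swap(self):
        m = np.array([[4.0, 1.0], [2.0, 0.0]])
        assert assignment_cost(m, [1, 0]) == 3.0

    def test_zero_diagonal_identity_is_zero(self, rng):
        m = rng.random((6, 6))
        np.fill_diagonal(m, 0.0)
        assert assignment_cost(m, range(6)) == 0.0

    def test_optimal_dominates_random_permutations(self, rng):
        m = rng.random((7, 7))
        best = solve_exact(m).total_cost
        for _ in range(100):
            perm = rng.permutation(7)
            assert best <= assignment_cost(m, perm) + 1e-12

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError):
            assignment_cost(np.eye(3), [0, 0, 1])


class TestClassifyOutcome:
    def test_close_pair_matched(self):
        aug = build_augmented_matrix([(0, 0)], [(0, 0.1)], threshold=1.0)
        out = classify_outcome(aug, solve_exact(aug))
        assert out.matched_pairs == ((0, 0),)
        assert out.lost_predictions == ()
        assert out.new_measurements == ()

    def test_far_pair_lost_and_new(self):
        # 2*tau = 2 < 5, so lost+new beats matching (verified by brute force)
        aug = build_augmented_matrix([(0, 0)], [(5, 0)], threshold=1.0)
        exact = solve_exact(aug)
        assert exact.total_cost == pytest.approx(
            solve_brute_force(aug).total_cost
        )
        out = classify_outcome(aug, exact)
        assert out.matched_pairs == ()
        assert out.lost_predictions == (0,)
        assert out.new_measurements == (0,)

    def test_no_predictions_all_new(self):
        aug = build_augmented_matrix([], [(0, 0), (3, 3)], threshold=1.0)
        out = classify_outcome(aug, solve_exact(aug))
        assert out.new_measurements == (0, 1)
        assert not out.infeasible

    @given(m=st.integers(0, 4), n=st.integers(0, 4), seed=st.integers(0, 9999))
    @settings(max_examples=80, deadline=None)
    def test_partition_property(self, m, n, seed):
        if m + n == 0:
            return
        gen = np.random.default_rng(seed)
        aug = build_augmented_matrix(
            gen.random((m, 2)) * 4, gen.random((n, 2)) * 4, threshold=0.7
        )
        out = classify_outcome(aug, solve_exact(aug))
        preds = sorted([i for i, _ in out.matched_pairs] + list(out.lost_predictions))
        meas = sorted([j for _, j in out.matched_pairs] + list(out.new_measurements))
        assert preds == list(range(m))
        assert meas == list(range(n))
        assert len({j for _, j in out.matched_pairs}) == len(out.matched_pairs)

    def test_optimum_avoids_big_value_cells(self, rng):
        for _ in range(30):
            m, n = rng.integers(1, 5, size=2)
            aug = build_augmented_matrix(
                rng.random((m, 2)) * 3, rng.random((n, 2)) * 3, threshold=0.5
            )
            out = classify_outcome(aug, solve_exact(aug))
            assert not out.infeasible


class TestRoundTrip:
    def test_matrix_round_trip(self, tmp_path, rng):
        m = rng.random((5, 5))
        path = tmp_path / "m.csv"
        save_matrix(m, path)
        np.testing.assert_allclose(load_matrix(path), m, atol=1e-12)


class TestAssignmentType:
    def test_rejects_non_bijection(self):
        with pytest.raises(ValueError):
            Assignment(permutation=(0, 0), total_cost=1.0)

    def test_cost_matrix_rejects_nan(self):
        with pytest.raises(ValueError):
            CostMatrix(np.array([[np.nan]]))
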