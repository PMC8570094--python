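"""Unit and oracle tests for the exact ILP selectors.

The independent oracle is exhaustive subset enumeration: for n <= 15
animals every one of the 2^n selections is scored directly against the
dense incidence matrix, with no reference to the solver path.
"""

import itertools

import numpy as np
import pytest

from seqpick.selector import (
    InfeasibleProblemError,
    SelectionProblem,
    compute_weights,
    coverage_report,
    iterative_budget_select,
    solve_budget,
    solve_min_cover,
)
from tests.conftest import make_incidence, random_instance


def brute_min_cover(A: np.ndarray, b=1) -> int:
    """Smallest subset size covering every row at least b times, by enumeration."""
    p, n = A.shape
    b = np.broadcast_to(np.asarray(b), (p,))
    best = None
    for size in range(n + 1):
        for subset in itertools.combinations(range(n), size):
            cov = A[:, list(subset)].sum(axis=1)
            if np.all(cov >= b):
                return size
    return best


def brute_budget(A: np.ndarray, c: np.ndarray, n_max: int, r_max) -> float:
    """Best feasible weighted subset by enumerating all subsets up to n_max."""
    p, n = A.shape
    r = np.broadcast_to(np.asarray(r_max), (p,))
    best = 0.0
    for size in range(min(n, n_max) + 1):
        for subset in itertools.combinations(range(n), size):
            cov = A[:, list(subset)].sum(axis=1)
            if np.all(cov <= r):
                best = max(best, float(c[list(subset)].sum()))
    return best


class TestComputeWeights:
    def test_two_half_frequency_haplotypes(self):
        M = make_incidence([[1], [1]], h=[0.5, 0.5])
        assert compute_weights(M).tolist() == [1.0]

    def test_carrier_of_nothing(self):
        M = make_incidence([[1, 0], [1, 0]], h=[0.3, 0.2])
        np.testing.assert_allclose(compute_weights(M), [0.5, 0.0])

    def test_matches_double_loop(self):
        rng = np.random.default_rng(5)
        M = random_instance(rng, n_max_animals=6, p_max=6)
        A = M.A.toarray()
        naive = np.array(
            [sum(M.h[i] * A[i, j] for i in range(M.p)) for j in range(M.n)]
        )
        np.testing.assert_allclose(compute_weights(M), naive)


class TestMinCover:
    def test_identity_needs_everyone(self):
        res = solve_min_cover(SelectionProblem(M=make_incidence(np.eye(3, dtype=int))))
        assert res.objective == 3 and res.proven_optimal

    def test_universal_carrier(self):
        A = np.ones((5, 1), dtype=int)
        A = np.hstack([A, np.eye(5, dtype=int)[:, :3]])
        res = solve_min_cover(SelectionProblem(M=make_incidence(A)))
        assert res.objective == 1

    def test_row_requirement_of_two(self):
        A = np.array([[1, 1, 0], [0, 1, 1]])
        b = np.array([2, 1])
        res = solve_min_cover(SelectionProblem(M=make_incidence(A), b=b))
        assert res.coverage_counts[0] >= 2

    def test_zero_row_rejected(self):
        A = np.array([[1, 0], [0, 0]])
        with pytest.raises(InfeasibleProblemError):
            solve_min_cover(SelectionProblem(M=make_incidence(A)))

    def test_unsatisfiable_requirement_names_row(self):
        A = np.array([[1, 0], [0, 1]])
        with pytest.raises(InfeasibleProblemError, match="row 0"):
            solve_min_cover(SelectionProblem(M=make_incidence(A), b=2))

    def test_forced_in_respected(self):
        A = np.eye(4, dtype=int)
        A[:, 0] = 1  # animal 0 covers everything alone
        res = solve_min_cover(SelectionProblem(M=make_incidence(A), forced_in=frozenset({3})))
        assert 3 in res.selected and 0 in res.selected

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        M = random_instance(rng, n_max_animals=10, p_max=14)
        res = solve_min_cover(SelectionProblem(M=M))
        assert res.proven_optimal
        assert res.objective == brute_min_cover(M.A.toarray())


class TestBudget:
    def test_unconstrained_selects_all_positive(self):
        A = np.array([[1, 0, 0], [1, 1, 0]])
        M = make_incidence(A, h=[0.2, 0.4])
        res = solve_budget(SelectionProblem(M=M, n_max=3, r_max=3))
        assert sorted(res.selected) == [0, 1]  # animal 2 has zero weight

    def test_pair_matches_pair_enumeration(self):
        rng = np.random.default_rng(2)
        A = (rng.random((6, 5)) < 0.4).astype(int)
        A[A.sum(axis=1) == 0, 0] = 1
        M = make_incidence(A)
        c = compute_weights(M)
        res = solve_budget(SelectionProblem(M=M, n_max=2, r_max=1))
        assert res.objective == pytest.approx(brute_budget(A, c, 2, 1))

    def test_rmax_one_forbids_shared_haplotypes(self):
        A = np.array([[1, 1], [1, 0], [0, 1]])
        M = make_incidence(A, h=[0.5, 0.25, 0.25])
        res = solve_budget(SelectionProblem(M=M, n_max=2, r_max=1))
        assert len(res.selected) == 1  # the two animals share row 0
        assert res.coverage_counts.max() <= 1

    def test_forced_violating_rmax(self):
        A = np.array([[1, 1]])
        M = make_incidence(A)
        with pytest.raises(InfeasibleProblemError):
            solve_budget(
                SelectionProblem(M=M, n_max=2, r_max=1, forced_in=frozenset({0, 1}))
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        M = random_instance(rng, n_max_animals=9, p_max=12)
        c = compute_weights(M)
        n_max = int(rng.integers(1, 4))
        r_max = int(rng.integers(1, 3))
        try:
            res = solve_budget(SelectionProblem(M=M, n_max=n_max, r_max=r_max))
        except InfeasibleProblemError:
            pytest.skip("instance infeasible")
        assert res.proven_optimal
        assert res.objective == pytest.approx(brute_budget(M.A.toarray(), c, n_max, r_max))

    def test_objective_equals_recomputed_weight_sum(self):
        rng = np.random.default_rng(3)
        M = random_instance(rng)
        c = compute_weights(M)
        res = solve_budget(SelectionProblem(M=M, n_max=4, r_max=4))
        assert res.objective == pytest.approx(c[np.asarray(res.selected)].sum())


class TestIterative:
    def _disjoint_instance(self, groups=6):
        # animal k privately carries rows 2k, 2k+1: no interference between rounds
        A = np.zeros((2 * groups, groups), dtype=int)
        for k in range(groups):
            A[2 * k : 2 * k + 2, k] = 1
        return make_incidence(A)

    def test_round_structure(self):
        M = self._disjoint_instance(6)
        res = iterative_budget_select(M, total_budget=6, batch=2, r_max=2)
        assert len(res.rounds) == 3
        assert res.n_selected == 6

    def test_single_batch_equals_direct_solve(self):
        rng = np.random.default_rng(7)
        M = random_instance(rng, n_max_animals=8, p_max=10)
        direct = solve_budget(SelectionProblem(M=M, n_max=3, r_max=3))
        iterative = iterative_budget_select(M, total_budget=3, batch=3, r_max=3)
        assert iterative.objective == pytest.approx(direct.objective)

    def test_covered_rows_removed_between_rounds(self):
        # each round's objective must count only rows still alive at the
        # start of the round: rows covered earlier contribute no weight
        rng = np.random.default_rng(8)
        M = random_instance(rng, n_max_animals=10, p_max=20)
        res = iterative_budget_select(M, total_budget=6, batch=2, r_max=2)
        A = M.A.toarray()
        id_to_col = {int(a): j for j, a in enumerate(M.animal_ids)}
        alive = np.ones(M.p, dtype=bool)
        for r in res.rounds:
            cols = [id_to_col[a] for a in r.selected_ids]
            expected = sum(float(M.h[alive] @ A[alive][:, j]) for j in cols)
            assert r.objective == pytest.approx(expected)
            covered = A[:, cols].sum(axis=1) > 0
            assert r.rows_removed == int(np.sum(alive & covered))
            alive &= ~covered

    def test_odd_budget_final_round_of_one(self):
        M = self._disjoint_instance(5)
        res = iterative_budget_select(M, total_budget=5, batch=2, r_max=2)
        assert res.n_selected == 5
        assert len(res.rounds[-1].selected_ids) == 1

    def test_budget_capped_at_population(self):
        M = self._disjoint_instance(3)
        with pytest.warns(RuntimeWarning):
            res = iterative_budget_select(M, total_budget=10, batch=2, r_max=2)
        assert res.n_selected == 3

    def test_exhaustion_continues_into_excluded_rows(self):
        common = make_incidence(np.array([[1, 0, 0, 0]]), h=[0.5])
        rare = make_incidence(np.array([[0, 1, 0, 0], [0, 0, 1, 0]]), h=[0.004, 0.004])
        res = iterative_budget_select(common, total_budget=3, batch=2, r_max=2, excluded=rare)
        assert res.n_selected == 3
        assert set(res.selected) == {0, 1, 2}

    def test_exhaustion_early_stop_mode(self):
        common = make_incidence(np.array([[1, 0, 0, 0]]), h=[0.5])
        res = iterative_budget_select(
            common, total_budget=3, batch=2, r_max=2, on_exhausted="stop"
        )
        assert res.n_selected < 3

    def test_budget_monotonicity(self):
        rng = np.random.default_rng(9)
        M = random_instance(rng, n_max_animals=12, p_max=25)
        props = []
        for budget in (2, 4, 6, 8):
            res = iterative_budget_select(M, total_budget=budget, batch=2, r_max=2)
            props.append(coverage_report(res.selected, M).prop_all)
        assert props == sorted(props)


class TestCoverageReport:
    def test_everyone_selected_covers_all(self):
        rng = np.random.default_rng(4)
        M = random_instance(rng)
        rep = coverage_report(list(M.animal_ids), M)
        assert rep.prop_all == 1.0

    def test_empty_selection(self):
        M = make_incidence(np.eye(3, dtype=int))
        assert coverage_report([], M).prop_all == 0.0

    def test_matches_naive_recount(self):
        rng = np.random.default_rng(6)
        M = random_instance(rng)
        sel = list(rng.choice(M.animal_ids, size=3, replace=False))
        rep = coverage_report(sel, M)
        A = M.A.toarray()
        naive = np.mean([any(A[i, s] for s in sel) for i in range(M.p)])
        assert rep.prop_all == pytest.approx(naive)

    def test_unknown_id_rejected(self):
        M = make_incidence(np.eye(2, dtype=int))
        with pytest.raises(KeyError):
            coverage_report([99], M)
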