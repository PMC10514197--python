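"""Exact, greedy and brute-force solvers; nested ranks; lock-in rules."""

import numpy as np
import pytest
from scipy import sparse

from mangroveprio import (
    InfeasibleBudgetError,
    ProblemInstance,
    brute_force,
    lock_protected,
    nested_ranks,
    solve_exact,
    solve_greedy,
)
from conftest import point_units, random_problem, three_unit_problem


class TestProblemInstance:
    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError, match="attainable"):
            ProblemInstance(
                sparse.csr_matrix(np.array([[0.5, 0.3]])),
                np.array([2.0]),
                np.array([1.0]),
                np.ones(2),
                np.arange(2),
                ["f0"],
                frozenset(),
                2.0,
            )

    def test_locked_cost_over_budget_rejected(self):
        with pytest.raises(InfeasibleBudgetError):
            three_unit_problem(locked={0, 1}, budget=1.0)

    def test_objective_of_empty_selection_is_weighted_count(self):
        prob = three_unit_problem()
        assert prob.objective(np.zeros(3, dtype=bool)) == pytest.approx(1.0)


class TestSolveExact:
    def test_full_budget_meets_all_targets(self):
        prob = random_problem(42)
        full = prob.with_budget(float(prob.costs.sum()))
        sel = solve_exact(full)
        assert sel.objective_value <= 1e-9

    def test_three_unit_example_picks_best_unit(self):
        sel = solve_exact(three_unit_problem())
        assert sel.chosen == {0}
        assert sel.objective_value == pytest.approx(0.0)

    def test_locked_unit_consumes_budget(self):
        sel = solve_exact(three_unit_problem(locked={2}, budget=1.0))
        assert sel.chosen == {2}
        assert sel.objective_value == pytest.approx(0.8)

    def test_budget_respected(self):
        prob = random_problem(7)
        sel = solve_exact(prob)
        assert sel.total_cost <= prob.budget * (1 + 1e-9)


class TestSolveGreedy:
    def test_matches_exact_on_three_unit_example(self):
        assert solve_greedy(three_unit_problem()).chosen == {0}

    def test_zero_extra_budget_returns_locked_only(self):
        sel = solve_greedy(three_unit_problem(locked={2}, budget=1.0))
        assert sel.chosen == {2}

    @pytest.mark.parametrize("seed", range(25))
    def test_never_beats_exact(self, seed):
        prob = random_problem(seed)
        greedy = solve_greedy(prob)
        exact = solve_exact(prob)
        assert greedy.objective_value >= exact.objective_value - 1e-9

    def test_no_improvement_stops_before_budget(self):
        # second feature already saturated by unit 0; unit 2 adds nothing
        prob = ProblemInstance(
            sparse.csr_matrix(np.array([[0.6, 0.0, 0.0]])),
            np.array([0.5]),
            np.array([1.0]),
            np.ones(3),
            np.arange(3),
            ["f0"],
            frozenset(),
            3.0,
        )
        sel = solve_greedy(prob)
        assert sel.chosen == {0}


class TestBruteForce:
    def test_single_unit_with_positive_amounts_chosen(self):
        prob = ProblemInstance(
            sparse.csr_matrix(np.array([[0.4]])),
            np.array([0.4]),
            np.array([1.0]),
            np.array([1.0]),
            np.array([0]),
            ["f0"],
            frozenset(),
            1.0,
        )
        assert brute_force(prob).chosen == {0}

    def test_rejects_large_instances(self):
        prob = random_problem(3, max_units=12)
        with pytest.raises(ValueError, match="brute_force"):
            brute_force(prob, max_units=prob.n_units - 1)

    def test_tie_break_prefers_cheaper_then_lexicographic(self):
        # units 0 and 1 are interchangeable; unit 1 is cheaper
        prob = ProblemInstance(
            sparse.csr_matrix(np.array([[0.5, 0.5]])),
            np.array([0.5]),
            np.array([1.0]),
            np.array([2.0, 1.0]),
            np.arange(2),
            ["f0"],
            frozenset(),
            3.0,
        )
        assert brute_force(prob).chosen == {1}


class TestNestedRanks:
    def test_single_full_budget_step_ranks_everything_one(self):
        prob = three_unit_problem(budget=3.0)
        rm = nested_ranks(prob, [1.0])
        assert set(rm.rank_by_unit.values()) == {1}

    def test_three_unit_grid_ranks_best_unit_first(self):
        prob = three_unit_problem(budget=3.0)
        rm = nested_ranks(prob, [1 / 3, 2 / 3, 1.0], solver="brute")
        assert rm.rank_by_unit[0] == 1
        rm.validate_nested()

    def test_initial_locked_gets_rank_zero(self):
        prob = three_unit_problem(budget=3.0)
        rm = nested_ranks(prob, [1 / 3, 2 / 3, 1.0], initial_locked={2}, solver="brute")
        assert rm.rank_by_unit[2] == 0
        # the locked unit exhausts the first-step budget; the best free
        # unit enters as soon as residual budget allows
        assert rm.rank_by_unit[0] == 2
        rm.validate_nested()

    def test_nestedness_holds_across_grid(self):
        prob = random_problem(11).with_budget(0.0)
        prob = prob.with_budget(float(prob.costs.sum()))
        rm = nested_ranks(prob, [0.25, 0.5, 0.75, 1.0])
        rm.validate_nested()
        ranked = [r for r in rm.rank_by_unit.values() if r > 0]
        assert ranked and max(ranked) <= 4

    def test_decreasing_grid_rejected(self):
        prob = three_unit_problem(budget=3.0)
        with pytest.raises(ValueError, match="increasing"):
            nested_ranks(prob, [0.5, 0.25])

    def test_infeasible_first_step_instructs_budget_floor(self):
        prob = three_unit_problem(budget=3.0)
        with pytest.raises(InfeasibleBudgetError, match="budget floor"):
            nested_ranks(prob, [0.2, 1.0], initial_locked={0, 1})


class TestLockProtected:
    def _units(self):
        return point_units(
            [0, 1, 2],
            strict_protected_fraction=[0.50, 0.49, 0.10],
            any_protected_fraction=[0.60, 0.80, 0.10],
        )

    def test_threshold_is_inclusive(self):
        assert lock_protected(self._units(), "strict") == {0}

    def test_just_below_threshold_not_locked(self):
        assert 1 not in lock_protected(self._units(), "strict")

    def test_all_mode_superset_of_strict(self):
        units = self._units()
        assert lock_protected(units, "strict") <= lock_protected(units, "all")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="category_mode"):
            lock_protected(self._units(), "loose")
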