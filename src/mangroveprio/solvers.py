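"""Minimum-shortfall reserve selection under an area budget.

The core problem: choose planning units x_i ∈ {0,1} to

    minimise   Σ_f (w_f / t_f) · s_f
    subject to s_f ≥ t_f − Σ_i a_fi · x_i,   s_f ≥ 0
               Σ_i c_i · x_i ≤ B
               x_i = 1 for locked-in units,

i.e. minimise the weighted sum of proportional target shortfalls within
the cost budget B, with existing protected areas forced in. Three
interchangeable solvers are provided: an exact mixed-integer programme
(HiGHS via scipy, 0.01% default relative optimality gap), a
cost-effectiveness greedy heuristic, and an exhaustive enumerator used
as a test oracle on tiny instances.

Nested priority ranks come from re-solving over an increasing budget
grid with all previously selected units locked in, so each solution
contains every smaller-budget solution and a unit's rank is the first
budget at which it enters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .features import InfeasibleBudgetError, ProblemInstance

DEFAULT_GAP = 1e-4  # 0.01% relative optimality gap


class SolverError(RuntimeError):
    pass


@dataclass
class Selection:
    """A binary reserve solution."""

    chosen: frozenset
    objective_value: float
    total_cost: float
    solver: str
    gap: float = 0.0

    def summary(self) -> str:
        return (
            f"Selection[{self.solver}]: {len(self.chosen)} units, "
            f"cost {self.total_cost:.4g}, shortfall objective {self.objective_value:.6g} "
            f"(gap {self.gap:.2%})"
        )


@dataclass
class RankMap:
    """Nested priority ranks over a budget grid.

    ``rank_by_unit`` maps unit id → rank r ≥ 1 (first budget step at which
    the unit was selected), 0 for initially locked-in (already protected)
    units, and -1 for units never selected. Ranks are nested by
    construction: a unit of rank r is in the solution of every step ≥ r.
    """

    rank_by_unit: Dict[int, int]
    budget_grid: Sequence[float]
    selections: List[Selection] = field(default_factory=list)

    def units_at_step(self, step: int) -> frozenset:
        """Units selected at 1-based budget step ``step`` (locked-in included)."""
        return frozenset(u for u, r in self.rank_by_unit.items() if 0 <= r <= step)

    def validate_nested(self) -> None:
        for i, sel in enumerate(self.selections, start=1):
            if not self.units_at_step(i) <= sel.chosen:
                raise AssertionError(f"rank map not nested at step {i}")


def _mask_from_ids(problem: ProblemInstance, ids: Iterable[int]) -> np.ndarray:
    col = problem.column_of()
    mask = np.zeros(problem.n_units, dtype=bool)
    for uid in ids:
        mask[col[int(uid)]] = True
    return mask


def _selection_from_mask(
    problem: ProblemInstance, mask: np.ndarray, solver: str, gap: float = 0.0
) -> Selection:
    chosen = frozenset(int(u) for u in problem.unit_ids[mask])
    return Selection(
        chosen=chosen,
        objective_value=problem.objective(mask),
        total_cost=float(problem.costs[mask].sum()),
        solver=solver,
        gap=gap,
    )


def solve_exact(
    problem: ProblemInstance,
    gap: float = DEFAULT_GAP,
    time_limit: Optional[float] = None,
) -> Selection:
    """Solve the MILP exactly (HiGHS) to the requested relative gap.

    On hitting ``time_limit`` the best incumbent is returned with its
    reported gap; infeasibility or solver failure raises.
    """
    f, n = problem.n_features, problem.n_units
    # variables: x (n binary), s (f continuous shortfalls)
    c = np.concatenate([np.zeros(n), problem.weights / problem.targets])
    # s_f + Σ a_fi x_i >= t_f
    cover = sparse.hstack([problem.amounts, sparse.identity(f, format="csr")], format="csr")
    cover_con = LinearConstraint(cover, lb=problem.targets, ub=np.inf)
    cost_row = sparse.hstack(
        [sparse.csr_matrix(problem.costs.reshape(1, -1)), sparse.csr_matrix((1, f))],
        format="csr",
    )
    cost_con = LinearConstraint(cost_row, lb=-np.inf, ub=problem.budget)
    lb = np.zeros(n + f)
    ub = np.concatenate([np.ones(n), np.full(f, np.inf)])
    locked = problem.locked_mask()
    lb[:n][locked] = 1.0
    integrality = np.concatenate([np.ones(n), np.zeros(f)])
    options: Dict[str, object] = {"mip_rel_gap": gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=c,
        constraints=[cover_con, cost_con],
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=options,
    )
    if res.x is None:
        raise SolverError(f"exact solver failed: {res.message}")
    mask = res.x[:n] > 0.5
    reported_gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    return _selection_from_mask(problem, mask, "exact", gap=reported_gap)


def solve_greedy(problem: ProblemInstance) -> Selection:
    """Cost-effectiveness greedy heuristic.

    Starting from the locked-in set, repeatedly add the affordable unit
    with the largest objective decrease per unit cost (ties: larger raw
    decrease, then lower unit id) until the budget is exhausted or no
    affordable unit improves the objective.
    """
    mask = problem.locked_mask()
    cost = float(problem.costs[mask].sum())
    held = np.asarray(problem.amounts @ mask.astype(float)).ravel()
    wt = problem.weights / problem.targets
    amounts_csc = problem.amounts.tocsc()
    while True:
        short = np.maximum(0.0, problem.targets - held)
        obj = float(np.sum(wt * short))
        if obj <= 0:
            break
        best = None  # (score, raw_decrease, -unit_id, column)
        for j in np.flatnonzero(~mask):
            if cost + problem.costs[j] > problem.budget * (1 + 1e-12) + 1e-12:
                continue
            col = amounts_csc[:, j]
            rows = col.indices
            gain = float(np.sum(wt[rows] * (short[rows] - np.maximum(0.0, short[rows] - col.data))))
            if gain <= 1e-15:
                continue
            unit_cost = max(problem.costs[j], 1e-12)
            key = (gain / unit_cost, gain, -int(problem.unit_ids[j]))
            if best is None or key > best[0]:
                best = (key, j)
        if best is None:
            break
        j = best[1]
        mask[j] = True
        cost += problem.costs[j]
        held += np.asarray(amounts_csc[:, j].todense()).ravel()
    return _selection_from_mask(problem, mask, "greedy")


def brute_force(problem: ProblemInstance, max_units: int = 20) -> Selection:
    """Exhaustive enumeration over all feasible supersets of the locked set.

    Global optimum; ties broken by lower total cost, then by
    lexicographically smallest sorted unit-id tuple. Only for tiny
    instances (test oracle).
    """
    if problem.n_units > max_units:
        raise ValueError(f"brute_force limited to {max_units} units, got {problem.n_units}")
    locked = problem.locked_mask()
    free = np.flatnonzero(~locked)
    n_free = len(free)
    dense = np.asarray(problem.amounts.todense())
    wt = problem.weights / problem.targets
    base_held = dense[:, locked].sum(axis=1)
    base_cost = float(problem.costs[locked].sum())

    best_obj = np.inf
    best: List[np.ndarray] = []
    for code in range(1 << n_free):
        bits = np.array([(code >> k) & 1 for k in range(n_free)], dtype=bool)
        cost = base_cost + float(problem.costs[free[bits]].sum())
        if cost > problem.budget * (1 + 1e-12) + 1e-12:
            continue
        held = base_held + dense[:, free[bits]].sum(axis=1)
        obj = float(np.sum(wt * np.maximum(0.0, problem.targets - held)))
        mask = locked.copy()
        mask[free[bits]] = True
        if obj < best_obj - 1e-12:
            best_obj, best = obj, [mask]
        elif obj < best_obj + 1e-12:
            best.append(mask)

    def tie_key(mask: np.ndarray):
        return (float(problem.costs[mask].sum()), tuple(sorted(problem.unit_ids[mask])))

    winner = min(best, key=tie_key)
    return _selection_from_mask(problem, winner, "brute")


_SOLVERS = {"exact": solve_exact, "greedy": solve_greedy, "brute": brute_force}


def nested_ranks(
    problem: ProblemInstance,
    budget_grid: Sequence[float],
    initial_locked: Iterable[int] = (),
    solver: str = "exact",
    gap: float = DEFAULT_GAP,
) -> RankMap:
    """Nested priority ranks from sequential solves over a budget grid.

    ``budget_grid`` holds strictly increasing budget fractions of the
    total cost (e.g. 0.01 … 1.0). At each step all units selected at
    earlier steps are locked in, which enforces nestedness; a unit's rank
    is the first step at which it is selected. ``initial_locked`` units
    (existing protected areas) carry rank 0, and the first budget step
    must cover their cost.
    """
    grid = list(budget_grid)
    if any(b2 <= b1 for b1, b2 in zip(grid, grid[1:])):
        raise ValueError("budget_grid must be strictly increasing")
    if not all(0 < b <= 1 for b in grid):
        raise ValueError("budget fractions must be in (0, 1]")
    total_cost = float(problem.costs.sum())
    locked = frozenset(int(u) for u in initial_locked)
    locked_cost = float(problem.costs[_mask_from_ids(problem, locked)].sum())
    if locked and locked_cost > grid[0] * total_cost * (1 + 1e-9):
        raise InfeasibleBudgetError(
            f"initially locked cost {locked_cost:.6g} exceeds the first budget step "
            f"({grid[0]:.0%} of {total_cost:.6g}); raise the budget floor to at least "
            f"{locked_cost / total_cost:.1%}"
        )
    solve = _SOLVERS[solver]
    ranks: Dict[int, int] = {int(u): 0 for u in locked}
    current = locked
    selections: List[Selection] = []
    for step, fraction in enumerate(grid, start=1):
        if fraction >= 1.0 - 1e-12:
            # at the full budget protecting everything costs nothing extra:
            # the terminal solution covers the whole seascape
            mask = np.ones(problem.n_units, dtype=bool)
            sel = _selection_from_mask(problem, mask, solver)
        else:
            sub = problem.with_budget(fraction * total_cost, locked_in=frozenset(current))
            sel = solve(sub) if solver != "exact" else solve(sub, gap=gap)
        for uid in sorted(sel.chosen - current):
            ranks[uid] = step
        current = current | sel.chosen
        selections.append(sel)
    for uid in problem.unit_ids:
        ranks.setdefault(int(uid), -1)
    return RankMap(rank_by_unit=ranks, budget_grid=grid, selections=selections)


def lock_protected(
    units: pd.DataFrame, category_mode: str = "strict", threshold: float = 0.5
) -> frozenset:
    """Unit ids whose protected-area coverage meets the threshold (≥).

    ``strict`` mode reads the strictly-protected coverage fraction (IUCN
    I–IV analogue); ``all`` reads coverage under any category.
    """
    column = {
        "strict": "strict_protected_fraction",
        "all": "any_protected_fraction",
    }.get(category_mode)
    if column is None:
        raise ValueError(f"category_mode must be 'strict' or 'all', got {category_mode!r}")
    if not 0 <= threshold <= 1:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    frac = units[column].to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("protection fractions must lie in [0,1]")
    return frozenset(int(u) for u in units.loc[frac >= threshold, "id"])
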