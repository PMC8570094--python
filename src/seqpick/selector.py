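"""Exact ILP selection of animals for sequencing.

Two problems over the binary incidence matrix A (haplotypes x animals):

* minimum cover -- minimize the number of selected animals subject to
  every haplotype being carried by at least ``b_i`` of them
  (``min  sum_j x_j  s.t.  A x >= b,  x binary``);
* budgeted maximum coverage -- maximize the frequency-weighted content
  ``c = h^T A`` of the selected set subject to a budget ``n_max`` and a
  per-haplotype redundancy cap ``r_max``
  (``max  c^T x  s.t.  sum_j x_j <= n_max,  A x <= r_max,  x binary``).

Both are solved by branch and bound (HiGHS via :func:`scipy.optimize.milp`),
which certifies global optimality.  The large-budget problem is solved by
the batch-iterative decomposition: select a small batch exactly, remove
the selected animals and every haplotype they carry, recompute the
weights on the surviving submatrix, and repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from seqpick.haplib import IncidenceMatrix

__all__ = [
    "SelectionProblem",
    "SelectionResult",
    "RoundLog",
    "compute_weights",
    "solve_min_cover",
    "solve_budget",
    "iterative_budget_select",
    "coverage_report",
]


class InfeasibleProblemError(ValueError):
    """The selection problem has no feasible assignment."""


@dataclass
class SelectionProblem:
    """One ILP instance over an incidence matrix.

    ``r_max`` and ``b`` may be scalars or per-row vectors; ``forced_in``
    lists animal IDs that must appear in the solution.
    """

    M: IncidenceMatrix
    c: np.ndarray | None = None
    n_max: int | None = None
    r_max: int | np.ndarray | None = None
    b: int | np.ndarray = 1
    forced_in: frozenset = frozenset()
    time_limit: float | None = None

    def row_vector(self, value, name: str) -> np.ndarray:
        vec = np.broadcast_to(np.asarray(value, dtype=np.float64), (self.M.p,)).copy()
        if np.any(vec < 1):
            raise ValueError(f"{name} entries must be >= 1")
        return vec

    def forced_index(self) -> np.ndarray:
        if not self.forced_in:
            return np.empty(0, dtype=np.int64)
        id_to_col = {int(a): j for j, a in enumerate(self.M.animal_ids)}
        try:
            return np.array(sorted(id_to_col[int(a)] for a in self.forced_in), dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"forced-in animal {exc.args[0]} not in the matrix") from None


@dataclass
class RoundLog:
    round_index: int
    selected_ids: list
    objective: float
    rows_removed: int
    proven_optimal: bool


@dataclass
class SelectionResult:
    """Outcome of a selection run, with an independent coverage recount."""

    selected: list
    objective: float
    coverage_counts: np.ndarray
    prop_all: float | None = None
    prop_common: float | None = None
    proven_optimal: bool = True
    rounds: list[RoundLog] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def compute_weights(M: IncidenceMatrix) -> np.ndarray:
    """Per-animal weights c = h^T A: larger for animals carrying more
    frequent haplotypes."""
    return np.asarray(M.h @ M.A).ravel()


def _selected_columns(M: IncidenceMatrix, selected_ids) -> np.ndarray:
    id_to_col = {int(a): j for j, a in enumerate(M.animal_ids)}
    try:
        return np.array([id_to_col[int(a)] for a in selected_ids], dtype=np.int64)
    except KeyError as exc:
        raise KeyError(f"unknown animal ID {exc.args[0]}") from None


def _coverage_counts(M: IncidenceMatrix, cols: np.ndarray) -> np.ndarray:
    if len(cols) == 0:
        return np.zeros(M.p, dtype=np.int64)
    x = np.zeros(M.n, dtype=np.int64)
    x[cols] = 1
    return np.asarray(M.A @ x).ravel()


def _run_milp(
    c_obj: np.ndarray,
    constraints: list[LinearConstraint],
    lb: np.ndarray,
    ub: np.ndarray,
    time_limit: float | None,
):
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=c_obj,
        constraints=constraints,
        integrality=np.ones(len(c_obj)),
        bounds=Bounds(lb=lb, ub=ub),
        options=options,
    )
    return res


def solve_min_cover(problem: SelectionProblem) -> SelectionResult:
    """Exact minimum-cover solve: fewest animals covering every haplotype.

    Requires every row to have at least ``b_i`` carriers; zero rows or
    unsatisfiable requirements raise :class:`InfeasibleProblemError`.
    The returned result carries the branch-and-bound optimality
    certificate in ``proven_optimal``.
    """
    M = problem.M
    b = problem.row_vector(problem.b, "b")
    support = np.asarray((M.A > 0).sum(axis=1)).ravel()
    bad = np.flatnonzero(support == 0)
    if bad.size:
        raise InfeasibleProblemError(f"haplotype row {bad[0]} has no carrier")
    short = np.flatnonzero(support < b)
    if short.size:
        i = int(short[0])
        raise InfeasibleProblemError(
            f"row {i} requires coverage {b[i]:.0f} but has only {support[i]} carriers"
        )
    lb = np.zeros(M.n)
    ub = np.ones(M.n)
    lb[problem.forced_index()] = 1.0
    constraints = [LinearConstraint(M.A, lb=b, ub=np.inf)]
    res = _run_milp(np.ones(M.n), constraints, lb, ub, problem.time_limit)
    return _finalize(problem, res, sense=+1)


def solve_budget(problem: SelectionProblem) -> SelectionResult:
    """Exact budgeted maximum-coverage solve.

    Maximizes ``c^T x`` over binary x with at most ``n_max`` selections
    and at most ``r_max_i`` selected carriers per haplotype row.
    """
    M = problem.M
    if problem.n_max is None or problem.n_max < 1:
        raise ValueError("n_max must be a positive budget")
    c = compute_weights(M) if problem.c is None else np.asarray(problem.c, dtype=np.float64)
    if c.shape != (M.n,):
        raise ValueError("weight vector length must equal the number of animals")
    if np.any(c < 0):
        raise ValueError("weights must be non-negative")
    forced = problem.forced_index()
    if len(forced) > problem.n_max:
        raise InfeasibleProblemError("forced-in set exceeds the budget n_max")
    caps_active = False
    r = None
    if problem.r_max is not None:
        r = problem.row_vector(problem.r_max, "r_max")
        # the cap only binds on rows a batch could over-cover
        caps_active = bool(np.any(r < problem.n_max))
        if caps_active and len(forced):
            over = _coverage_counts(M, forced) > r
            if over.any():
                raise InfeasibleProblemError(
                    f"forced-in animals violate r_max on row {int(np.flatnonzero(over)[0])}"
                )

    cols = np.arange(M.n)
    if not caps_active and M.n > problem.n_max:
        # without active row caps the problem is separable, so only the
        # n_max largest weights (plus ties at the threshold and forced
        # columns) can appear in an optimal solution; this dominance
        # reduction is exact and just shrinks the branch-and-bound input
        threshold = np.partition(c, M.n - problem.n_max)[M.n - problem.n_max]
        keep = c >= threshold
        keep[forced] = True
        cols = np.flatnonzero(keep)

    n_sub = len(cols)
    lb = np.zeros(n_sub)
    ub = np.ones(n_sub)
    ub[c[cols] == 0] = 0.0  # a zero-weight animal can never improve z2
    col_pos = {int(j): k for k, j in enumerate(cols)}
    forced_pos = [col_pos[int(j)] for j in forced]
    lb[forced_pos] = 1.0
    ub[forced_pos] = 1.0
    constraints = [LinearConstraint(np.ones((1, n_sub)), lb=-np.inf, ub=problem.n_max)]
    if caps_active:
        constraints.append(LinearConstraint(M.A[:, cols], lb=-np.inf, ub=r))
    res = _run_milp(-c[cols], constraints, lb, ub, problem.time_limit)
    return _finalize(problem, res, sense=-1, weights=c, cols=cols)


def _finalize(
    problem: SelectionProblem,
    res,
    sense: int,
    weights: np.ndarray | None = None,
    cols: np.ndarray | None = None,
):
    M = problem.M
    if res.status not in (0, 1) or res.x is None:
        raise InfeasibleProblemError(f"solver reported: {res.message}")
    proven = res.status == 0
    if not proven:
        warnings.warn(
            "time limit reached without an optimality certificate; "
            "returning the incumbent solution",
            RuntimeWarning,
            stacklevel=3,
        )
    x = np.round(res.x).astype(np.int64)
    picked = np.flatnonzero(x == 1)
    cols = picked if cols is None else cols[picked]
    selected = [int(a) for a in M.animal_ids[cols]]
    if weights is None:
        objective = float(len(cols))
    else:
        objective = float(weights[cols].sum())
    return SelectionResult(
        selected=selected,
        objective=objective,
        coverage_counts=_coverage_counts(M, cols),
        proven_optimal=proven,
    )


def iterative_budget_select(
    M: IncidenceMatrix,
    total_budget: int,
    batch: int = 2,
    r_max: int = 2,
    excluded: IncidenceMatrix | None = None,
    on_exhausted: str = "continue",
    time_limit: float | None = None,
) -> SelectionResult:
    """Batch-iterative budgeted selection.

    Each round solves the exact budgeted problem with ``n_max = batch``
    on the surviving submatrix (remaining haplotype rows x unselected
    animals), using weights recomputed as ``h`` restricted to surviving
    rows times the surviving submatrix.  Selected animals and every row
    they cover are then removed.  Row frequencies themselves are never
    recomputed between rounds.

    If all rows are covered before the budget is spent, behavior depends
    on ``on_exhausted``: ``"continue"`` switches to the ``excluded``
    matrix (the rows dropped by the frequency filter) and keeps
    selecting to cover those next-rarest haplotypes; ``"stop"`` ends
    early.  An odd remainder of the budget is spent with a final smaller
    batch.
    """
    if batch < 1:
        raise ValueError("batch must be >= 1")
    if on_exhausted not in ("continue", "stop"):
        raise ValueError("on_exhausted must be 'continue' or 'stop'")
    if total_budget > M.n:
        warnings.warn(
            f"budget {total_budget} exceeds population size {M.n}; capping",
            RuntimeWarning,
            stacklevel=2,
        )
        total_budget = M.n

    Acsr = M.A.tocsr()
    alive_rows = np.ones(M.p, dtype=bool)
    avail_cols = np.ones(M.n, dtype=bool)
    fallback_rows = None
    current_A, current_h = Acsr, M.h
    selected_all: list[int] = []
    rounds: list[RoundLog] = []
    proven = True
    round_index = 0
    while len(selected_all) < total_budget:
        n_this = min(batch, total_budget - len(selected_all))
        row_idx = np.flatnonzero(alive_rows)
        if row_idx.size == 0:
            if on_exhausted == "stop" or excluded is None or fallback_rows is not None:
                break
            # switch to the filtered-out (rare) rows not yet covered
            fallback = excluded.A.tocsr()
            covered = np.asarray(
                fallback[:, ~avail_cols].sum(axis=1)
            ).ravel() if (~avail_cols).any() else np.zeros(excluded.p)
            current_A, current_h = fallback, excluded.h
            alive_rows = covered == 0
            fallback_rows = True
            row_idx = np.flatnonzero(alive_rows)
            if row_idx.size == 0:
                break
        col_idx = np.flatnonzero(avail_cols)
        sub = current_A[row_idx][:, col_idx]
        subM = IncidenceMatrix(
            A=sub.tocsr(),
            h=current_h[row_idx],
            animal_ids=M.animal_ids[col_idx],
            haplotype_ids=np.arange(row_idx.size),
        )
        res = solve_budget(
            SelectionProblem(M=subM, n_max=n_this, r_max=r_max, time_limit=time_limit)
        )
        proven &= res.proven_optimal
        if not res.selected:
            break
        sel_cols = _selected_columns(M, res.selected)
        avail_cols[sel_cols] = False
        cov = _coverage_counts(
            IncidenceMatrix(A=current_A, h=current_h, animal_ids=M.animal_ids,
                            haplotype_ids=np.arange(current_A.shape[0])),
            sel_cols,
        )
        newly = alive_rows & (cov > 0)
        alive_rows &= cov == 0
        selected_all.extend(res.selected)
        rounds.append(
            RoundLog(
                round_index=round_index,
                selected_ids=list(res.selected),
                objective=res.objective,
                rows_removed=int(newly.sum()),
                proven_optimal=res.proven_optimal,
            )
        )
        round_index += 1

    cols = _selected_columns(M, selected_all)
    result = SelectionResult(
        selected=selected_all,
        objective=float(sum(r.objective for r in rounds)),
        coverage_counts=_coverage_counts(M, cols),
        proven_optimal=proven,
        rounds=rounds,
    )
    return result


def coverage_report(
    selected,
    M_all: IncidenceMatrix,
    M_common: IncidenceMatrix | None = None,
) -> SelectionResult:
    """Recount coverage of a selected set against full and common matrices.

    ``prop_all`` is the fraction of all haplotype rows with at least one
    selected carrier; ``prop_common`` likewise on the common-filtered
    matrix.
    """
    cols = _selected_columns(M_all, selected)
    counts = _coverage_counts(M_all, cols)
    prop_all = float((counts >= 1).sum() / M_all.p)
    prop_common = None
    if M_common is not None:
        cols_c = _selected_columns(M_common, selected)
        counts_c = _coverage_counts(M_common, cols_c)
        prop_common = float((counts_c >= 1).sum() / M_common.p)
    return SelectionResult(
        selected=list(selected),
        objective=float(len(cols)),
        coverage_counts=counts,
        prop_all=prop_all,
        prop_common=prop_common,
    )
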