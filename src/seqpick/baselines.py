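"""Comparison selection schemes.

* AHAP1 -- rank animals once by the static frequency weights c = h^T A
  (both homozygous and heterozygous carriage) and select in descending
  order; no weight updating.
* IWS -- one animal at a time, weighting animals by the summed inverse
  frequency of the haplotypes they carry that are still uncovered, so
  carriers of rare haplotypes are picked first; covered rows are removed
  after each pick.
* greedy cover -- the textbook set-cover heuristic (most uncovered rows
  per pick), used as a test baseline.
* random -- uniformly random selection.

All schemes run either to a fixed budget or until every haplotype row is
covered (``budget=None``); ties are broken by smaller animal ID.
"""

from __future__ import annotations

import numpy as np

from seqpick.haplib import IncidenceMatrix
from seqpick.selector import SelectionResult, _coverage_counts, compute_weights

__all__ = ["ahap1_select", "iws_select", "greedy_cover", "random_select"]


def _result(M: IncidenceMatrix, cols: list[int]) -> SelectionResult:
    cols_arr = np.asarray(cols, dtype=np.int64)
    counts = _coverage_counts(M, cols_arr)
    return SelectionResult(
        selected=[int(a) for a in M.animal_ids[cols_arr]],
        objective=float(len(cols)),
        coverage_counts=counts,
        prop_all=float((counts >= 1).sum() / M.p),
        proven_optimal=False,
    )


def _tie_order(M: IncidenceMatrix) -> np.ndarray:
    """Column permutation placing smaller animal IDs first."""
    return np.argsort(M.animal_ids, kind="stable")


def ahap1_select(M: IncidenceMatrix, budget: int | None = None) -> SelectionResult:
    """Static-weight ranking: compute c = h^T A once, take the top animals.

    With ``budget=None`` animals are added in c order until every
    haplotype row is covered.
    """
    c = compute_weights(M)
    id_order = _tie_order(M)
    order = id_order[np.argsort(-c[id_order], kind="stable")]
    if budget is not None:
        return _result(M, list(order[: min(budget, M.n)]))
    covered = np.zeros(M.p, dtype=bool)
    Acsc = M.A.tocsc()
    picks: list[int] = []
    for col in order:
        picks.append(int(col))
        covered[Acsc.indices[Acsc.indptr[col] : Acsc.indptr[col + 1]]] = True
        if covered.all():
            break
    return _result(M, picks)


def iws_select(M: IncidenceMatrix, budget: int | None = None) -> SelectionResult:
    """Inverse-frequency weighting, one animal at a time.

    weight_j = sum over uncovered rows i of a_ij / h_i; the argmax animal
    is selected, its rows are marked covered, and weights are updated.
    """
    Acsc = M.A.tocsc()
    inv_h = 1.0 / M.h
    covered = np.zeros(M.p, dtype=bool)
    available = np.ones(M.n, dtype=bool)
    # order used only to break exact ties deterministically by ID
    id_rank = np.empty(M.n, dtype=np.int64)
    id_rank[_tie_order(M)] = np.arange(M.n)
    limit = M.n if budget is None else min(budget, M.n)
    picks: list[int] = []
    while len(picks) < limit:
        # weights recomputed from scratch over the uncovered rows, so
        # exact ties are detected without floating-point drift
        weights = np.asarray(np.where(covered, 0.0, inv_h) @ M.A).ravel()
        masked = np.where(available, weights, -np.inf)
        best = masked.max()
        if best == -np.inf:
            break
        cand = np.flatnonzero(masked == best)
        col = int(cand[np.argmin(id_rank[cand])])
        picks.append(col)
        available[col] = False
        rows = Acsc.indices[Acsc.indptr[col] : Acsc.indptr[col + 1]]
        covered[rows] = True
        if budget is None and covered.all():
            break
    return _result(M, picks)


def greedy_cover(M: IncidenceMatrix, budget: int | None = None) -> SelectionResult:
    """Greedy set cover: repeatedly pick the animal covering the most
    still-uncovered haplotype rows."""
    support = np.asarray((M.A > 0).sum(axis=1)).ravel()
    if np.any(support == 0):
        raise ValueError("matrix contains a haplotype with no carrier")
    Acsc = M.A.tocsc()
    Acsr = M.A.tocsr()
    gains = np.asarray(M.A.sum(axis=0)).ravel().astype(np.int64)
    covered = np.zeros(M.p, dtype=bool)
    available = np.ones(M.n, dtype=bool)
    id_rank = np.empty(M.n, dtype=np.int64)
    id_rank[_tie_order(M)] = np.arange(M.n)
    limit = M.n if budget is None else min(budget, M.n)
    picks: list[int] = []
    while len(picks) < limit and not covered.all():
        masked = np.where(available, gains, -1)
        best = masked.max()
        if best <= 0:
            break
        cand = np.flatnonzero(masked == best)
        col = int(cand[np.argmin(id_rank[cand])])
        picks.append(col)
        available[col] = False
        rows = Acsc.indices[Acsc.indptr[col] : Acsc.indptr[col + 1]]
        newly = rows[~covered[rows]]
        if newly.size:
            covered[newly] = True
            gains -= np.asarray(
                Acsr[newly].sum(axis=0), dtype=np.int64
            ).ravel()
    return _result(M, picks)


def random_select(
    M: IncidenceMatrix, budget: int, rng: np.random.Generator | int | None = None
) -> SelectionResult:
    """Uniformly random selection of ``budget`` animals without replacement."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cols = rng.choice(M.n, size=min(budget, M.n), replace=False)
    return _result(M, list(cols))
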