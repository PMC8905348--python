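"""Alternate-optima enumeration by exclusion (integer) cuts.

After each solution with support P, the cut ``sum_{j in P} y_j <= |P|-1``
is added and the MILP re-solved.  The cut forbids P itself and, as a side
effect, every superset of P.  The objective is *not* fixed to the first
optimum, so later solutions may be strictly worse; with an exact solve
(mip_gap = 0) the objective sequence is non-decreasing because the
feasible region only shrinks.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .milp_core import (
    InfeasibleProblemError,
    Solution,
    TransientProblem,
    check_feasibility,
    solve_once,
)

__all__ = ["SolutionSet", "EnumerationError", "exclusion_cut", "enumerate_solutions"]


class EnumerationError(ValueError):
    """Invalid enumeration request."""


@dataclass
class SolutionSet:
    """Ordered enumerated solutions plus the cuts that produced them."""

    solutions: list[Solution] = field(default_factory=list)
    cuts: list[frozenset[int]] = field(default_factory=list)
    termination: str = "count_reached"  # | infeasible | time_budget | degradation
    problem: TransientProblem | None = None

    def __len__(self) -> int:
        return len(self.solutions)

    def supports(self) -> list[frozenset[int]]:
        return [s.support_set() for s in self.solutions]

    def objectives(self) -> list[float]:
        return [s.objective for s in self.solutions]


def exclusion_cut(support: frozenset[int] | set[int] | np.ndarray) -> frozenset[int]:
    """Return the index set P of the cut ``sum_{j in P} y_j <= |P| - 1``.

    The empty support admits no such cut (the all-zero solution, if
    optimal, terminates enumeration instead).
    """
    if isinstance(support, np.ndarray):
        support = frozenset(np.flatnonzero(support).tolist())
    support = frozenset(support)
    if not support:
        raise EnumerationError("cannot cut the empty support")
    return support


def enumerate_solutions(
    p: TransientProblem,
    n_max: int,
    *,
    max_degradation: float | None = None,
    time_budget_s: float | None = None,
    validate: bool = True,
) -> SolutionSet:
    """Enumerate up to ``n_max`` distinct-support solutions.

    Stops when the cut-augmented program becomes infeasible, when the
    per-run time budget is exhausted, or (if ``max_degradation`` is set)
    when a solution's objective exceeds the first objective by more than
    that fraction of |first objective|.  Solutions terminated at the gap
    or time limit are still recorded and cut.
    """
    if n_max < 1:
        raise EnumerationError(f"n_max must be >= 1, got {n_max}")
    ss = SolutionSet(problem=p)
    saved_cuts = list(p.cuts)
    t0 = time.monotonic()
    first_obj: float | None = None
    try:
        while len(ss.solutions) < n_max:
            if time_budget_s is not None and time.monotonic() - t0 > time_budget_s:
                ss.termination = "time_budget"
                return ss
            try:
                sol = solve_once(p)
            except InfeasibleProblemError:
                if not ss.solutions:
                    raise
                ss.termination = "infeasible"
                return ss
            if validate:
                violations = check_feasibility(p, sol)
                if violations:
                    raise AssertionError(
                        f"solver returned an infeasible solution: {violations}"
                    )
            if first_obj is None:
                first_obj = sol.objective
            elif max_degradation is not None:
                allowed = abs(first_obj) * max_degradation
                if sol.objective - first_obj > allowed + 1e-12:
                    ss.termination = "degradation"
                    return ss
            ss.solutions.append(sol)
            support = sol.support_set()
            if not support:
                # the empty solution is globally optimal and cannot be cut away
                ss.termination = "count_reached"
                return ss
            cut = exclusion_cut(support)
            ss.cuts.append(cut)
            p.cuts.append(cut)
        ss.termination = "count_reached"
        return ss
    finally:
        # the problem is handed back with the cuts it came with; the run's
        # own cuts live on the returned SolutionSet
        p.cuts.clear()
        p.cuts.extend(saved_cuts)
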