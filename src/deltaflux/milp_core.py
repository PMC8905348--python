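"""Assembly and single-shot solution of the transient-state MILP.

Decision variables, per split (irreversible) reaction j:

* ``phi_j >= 0`` — moles passed through j over the transition interval,
* ``y_j in {0,1}`` — support indicator, linked by
  ``theta * y_j <= phi_j <= u_j * y_j`` (theta > 0 makes the link an
  equivalence up to theta),

plus one epigraph auxiliary ``a_i >= |(S.phi)_i|`` per non-measured
metabolite i.  Constraints: the per-metabolite interval bounds
``delta_min <= S.phi <= delta_max``, mutual exclusion
``y_j + y_jbar <= 1`` for each forward/backward pair, and any exclusion
cuts added by the enumeration loop.  Objective, for weight
``lam in (0, 1)``:

    min  lam * sum_j y_j
       + (1 - lam) * sum_{i not in X} a_i
       - (1 - lam) * sum_{i in X} s_i * (S.phi)_i

where s_i is the (strict) sign of measured metabolite i's interval, so
the last term equals the explained absolute variation.  ``lam = 1`` is a
separate cardinality-only mode (minimise the number of active reactions
only).  Solved with HiGHS via scipy.optimize.milp: deterministic and
single-threaded, so the ``seed``/``threads`` options are recorded but
have no effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .measurements import BoundVectors
from .network_io import SplitNetwork

__all__ = [
    "SolverOptions",
    "TransientProblem",
    "Solution",
    "ProblemError",
    "InfeasibleProblemError",
    "build_problem",
    "solve_once",
    "evaluate_objective",
    "check_feasibility",
    "write_lp",
]

#: default minimum activity of a selected reaction (theta)
DEFAULT_THETA = 1e-4
#: feasibility checking tolerance
FEASIBILITY_TOL = 1e-6


class ProblemError(ValueError):
    """Invalid problem parameters or assembly failure."""


class InfeasibleProblemError(RuntimeError):
    """The MILP admits no feasible point."""

    def __init__(self, message: str, measured_ids: list[str] | None = None):
        super().__init__(message)
        self.measured_ids = measured_ids or []


@dataclass
class SolverOptions:
    mip_gap: float = 0.0
    time_limit_s: float | None = None
    seed: int = 0  # recorded only; HiGHS via scipy is deterministic
    threads: int = 1  # recorded only; single-threaded backend


@dataclass
class TransientProblem:
    """Solver-ready data for one transient-state inference problem."""

    net: SplitNetwork
    bounds: BoundVectors
    lam: float
    theta: float = DEFAULT_THETA
    options: SolverOptions = field(default_factory=SolverOptions)
    cuts: list[frozenset[int]] = field(default_factory=list)

    @property
    def cardinality_only(self) -> bool:
        return self.lam == 1.0

    @property
    def u(self) -> np.ndarray:
        return self.net.upper_bounds()

    @property
    def support_threshold(self) -> float:
        """Threshold tau for reading a support from a phi vector."""
        return self.theta / 2.0 if self.theta > 0 else FEASIBILITY_TOL


@dataclass
class Solution:
    """One answer: moles-passed vector, support, and predicted variations."""

    phi: np.ndarray
    support: np.ndarray  # bool per split reaction
    objective: float
    predicted_variation: np.ndarray  # S.phi per metabolite
    status: str  # optimal | gap_limit | time_limit
    mip_gap: float = 0.0
    #: raw epigraph auxiliaries a_i (non-measured metabolite order), when solved
    aux: np.ndarray | None = None

    def support_ids(self, net: SplitNetwork) -> list[str]:
        return [net.reactions[j].id for j in np.flatnonzero(self.support)]

    def support_set(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.support).tolist())


def build_problem(
    net: SplitNetwork,
    bounds: BoundVectors,
    lam: float,
    *,
    theta: float = DEFAULT_THETA,
    options: SolverOptions | None = None,
) -> TransientProblem:
    """Validate dimensions/parameters and bundle them into a problem."""
    if not 0.0 < lam <= 1.0:
        raise ProblemError(f"lambda must lie in (0, 1] (1 = cardinality-only), got {lam}")
    if theta < 0:
        raise ProblemError(f"theta must be >= 0, got {theta}")
    m = net.n_metabolites
    if bounds.delta_min.shape != (m,) or bounds.delta_max.shape != (m,):
        raise ProblemError(
            f"bound vectors have length {bounds.delta_min.shape[0]}, "
            f"network has {m} metabolites"
        )
    if np.any(bounds.delta_min > bounds.delta_max):
        raise ProblemError("delta_min > delta_max componentwise: infeasible bounds")
    return TransientProblem(
        net=net, bounds=bounds, lam=lam, theta=theta, options=options or SolverOptions()
    )


# ---------------------------------------------------------------------------
# matrix assembly
#
# variable layout: x = [phi (n), y (n), a (k)] with k = #non-measured metabolites

def _assemble(p: TransientProblem):
    net, b = p.net, p.bounds
    S = net.S
    m, n = S.shape
    nonmeasured = np.flatnonzero(~b.measured_mask)
    k = len(nonmeasured)
    nvar = 2 * n + k
    u = p.u

    blocks_A = []
    lb_rows: list[np.ndarray] = []
    ub_rows: list[np.ndarray] = []

    # interval bounds on S.phi
    A_rows = sparse.hstack([S, sparse.csr_array((m, n + k))])
    blocks_A.append(A_rows)
    lb_rows.append(b.delta_min)
    ub_rows.append(b.delta_max)

    # linking: phi_j - u_j y_j <= 0  and  theta y_j - phi_j <= 0
    eye = sparse.eye_array(n, format="csr")
    A_link_up = sparse.hstack([eye, -sparse.diags_array(u), sparse.csr_array((n, k))])
    blocks_A.append(A_link_up)
    lb_rows.append(np.full(n, -np.inf))
    ub_rows.append(np.zeros(n))
    if p.theta > 0:
        A_link_lo = sparse.hstack([-eye, p.theta * eye, sparse.csr_array((n, k))])
        blocks_A.append(A_link_lo)
        lb_rows.append(np.full(n, -np.inf))
        ub_rows.append(np.zeros(n))

    # mutual exclusion per split pair
    if p.net.pair_map:
        rows, cols, vals = [], [], []
        for r, (j, jb) in enumerate(p.net.pair_map):
            rows += [r, r]
            cols += [n + j, n + jb]
            vals += [1.0, 1.0]
        A_pair = sparse.csr_array(
            (vals, (rows, cols)), shape=(len(p.net.pair_map), nvar)
        )
        blocks_A.append(A_pair)
        lb_rows.append(np.full(len(p.net.pair_map), -np.inf))
        ub_rows.append(np.ones(len(p.net.pair_map)))

    # epigraph: +-(S.phi)_i - a_i <= 0 for non-measured i
    if k:
        S_bar = S[nonmeasured, :]
        I_a = sparse.eye_array(k, format="csr")
        A_pos = sparse.hstack([S_bar, sparse.csr_array((k, n)), -I_a])
        A_neg = sparse.hstack([-S_bar, sparse.csr_array((k, n)), -I_a])
        blocks_A.extend([A_pos, A_neg])
        lb_rows.extend([np.full(k, -np.inf)] * 2)
        ub_rows.extend([np.zeros(k)] * 2)

    # exclusion cuts: sum_{j in P} y_j <= |P| - 1
    for cut in p.cuts:
        row = sparse.csr_array(
            (np.ones(len(cut)), (np.zeros(len(cut), dtype=int), [n + j for j in sorted(cut)])),
            shape=(1, nvar),
        )
        blocks_A.append(row)
        lb_rows.append(np.array([-np.inf]))
        ub_rows.append(np.array([len(cut) - 1.0]))

    A = sparse.vstack(blocks_A, format="csr")
    lb = np.concatenate(lb_rows)
    ub = np.concatenate(ub_rows)

    # objective
    c = np.zeros(nvar)
    if p.cardinality_only:
        c[n : 2 * n] = 1.0
    else:
        sign_X = p.bounds.sign.astype(float)
        # -(1-lam) * sum_X s_i (S.phi)_i  ->  c_phi = -(1-lam) S_X^T s_X
        c[:n] = -(1.0 - p.lam) * (S.T @ sign_X)
        c[n : 2 * n] = p.lam
        c[2 * n :] = 1.0 - p.lam

    var_lb = np.concatenate([np.zeros(n), np.zeros(n), np.zeros(k)])
    var_ub = np.concatenate([u, np.ones(n), np.full(k, np.inf)])
    integrality = np.concatenate([np.zeros(n), np.ones(n), np.zeros(k)])
    return c, LinearConstraint(A, lb, ub), Bounds(var_lb, var_ub), integrality, nonmeasured


def solve_once(p: TransientProblem) -> Solution:
    """Solve the MILP once and return the best solution found.

    Status records whether the search terminated at proven optimality, the
    relative MIP-gap target, or the time limit.  Infeasibility raises
    :class:`InfeasibleProblemError` naming the measured metabolites whose
    interval constraints are the candidate culprits.
    """
    c, constraint, var_bounds, integrality, _ = _assemble(p)
    opts: dict = {"mip_rel_gap": p.options.mip_gap, "presolve": True}
    if p.options.time_limit_s is not None:
        opts["time_limit"] = p.options.time_limit_s
    res = milp(
        c, constraints=constraint, bounds=var_bounds, integrality=integrality, options=opts
    )
    if res.status == 2:
        measured = [
            p.net.metabolites[i].id for i in np.flatnonzero(p.bounds.measured_mask)
        ]
        raise InfeasibleProblemError(
            "problem infeasible: no moles-passed vector satisfies the measured "
            f"interval constraints (measured metabolites: {measured}); consider "
            "raising epsilon or relaxing the intervals",
            measured_ids=measured,
        )
    if res.status == 3:
        raise AssertionError("MILP reported unbounded despite finite upper bounds")
    if res.x is None:
        raise RuntimeError(
            "solver hit its limits before finding any incumbent solution; "
            "raise time_limit_s or mip_gap"
        )

    n = p.net.n_reactions
    phi = np.asarray(res.x[:n], dtype=float)
    y = res.x[n : 2 * n] > 0.5
    tau = p.support_threshold
    support = y & (phi >= tau)
    phi = np.where(phi < tau, 0.0, phi)  # numerical dust
    variation = p.net.S @ phi
    gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    if res.status == 0:
        status = "optimal" if gap <= 1e-9 else "gap_limit"
    else:
        status = "time_limit"
    sol = Solution(
        phi=phi,
        support=support,
        objective=0.0,
        predicted_variation=variation,
        status=status,
        mip_gap=gap,
        aux=np.asarray(res.x[2 * n :], dtype=float),
    )
    sol.objective = evaluate_objective(p, sol)
    return sol


def evaluate_objective(p: TransientProblem, s: Solution) -> float:
    """Re-evaluate the objective from raw phi/y with true absolute values."""
    variation = p.net.S @ s.phi
    card = float(np.count_nonzero(s.support))
    if p.cardinality_only:
        return card
    measured = p.bounds.measured_mask
    abs_bar = float(np.sum(np.abs(variation[~measured])))
    signed_X = float(np.sum(p.bounds.sign[measured] * variation[measured]))
    return p.lam * card + (1.0 - p.lam) * abs_bar - (1.0 - p.lam) * signed_X


def check_feasibility(
    p: TransientProblem, s: Solution, tol: float = FEASIBILITY_TOL
) -> list[str]:
    """Verify every constraint; violations are returned, not raised."""
    violations: list[str] = []
    net = p.net
    variation = net.S @ s.phi
    for i, met in enumerate(net.metabolites):
        if variation[i] < p.bounds.delta_min[i] - tol:
            violations.append(
                f"row {met.id}: S.phi = {variation[i]:.6g} < delta_min = "
                f"{p.bounds.delta_min[i]:.6g}"
            )
        if variation[i] > p.bounds.delta_max[i] + tol:
            violations.append(
                f"row {met.id}: S.phi = {variation[i]:.6g} > delta_max = "
                f"{p.bounds.delta_max[i]:.6g}"
            )
    u = p.u
    for j, rxn in enumerate(net.reactions):
        if s.phi[j] < -tol:
            violations.append(f"{rxn.id}: phi = {s.phi[j]:.6g} < 0")
        if s.phi[j] > u[j] + tol:
            violations.append(f"{rxn.id}: phi = {s.phi[j]:.6g} > u = {u[j]:.6g}")
        if not s.support[j] and s.phi[j] > tol:
            violations.append(f"{rxn.id}: inactive (y=0) but phi = {s.phi[j]:.6g} > 0")
        if s.support[j] and p.theta > 0 and s.phi[j] < p.theta - tol:
            violations.append(
                f"{rxn.id}: active (y=1) but phi = {s.phi[j]:.6g} < theta = {p.theta:.6g}"
            )
    for j, jb in net.pair_map:
        if s.support[j] and s.support[jb]:
            violations.append(
                f"split pair {net.reactions[j].id}/{net.reactions[jb].id} both active"
            )
    sup = s.support_set()
    for cut in p.cuts:
        if cut <= sup:
            violations.append(f"exclusion cut violated: support contains {sorted(cut)}")
    return violations


def write_lp(p: TransientProblem, path: str) -> None:
    """Dump the assembled program in CPLEX LP format for external inspection."""
    c, constraint, var_bounds, integrality, nonmeasured = _assemble(p)
    n = p.net.n_reactions
    names = (
        [f"phi_{r.id}" for r in p.net.reactions]
        + [f"y_{r.id}" for r in p.net.reactions]
        + [f"a_{p.net.metabolites[i].id}" for i in nonmeasured]
    )
    A = sparse.csr_array(constraint.A)
    with open(path, "w") as fh:
        fh.write("Minimize\n obj:")
        for j, cj in enumerate(c):
            if cj != 0:
                fh.write(f" {'+' if cj > 0 else '-'} {abs(cj):.12g} {names[j]}")
        fh.write("\nSubject To\n")
        row_no = 0
        for i in range(A.shape[0]):
            start, end = A.indptr[i], A.indptr[i + 1]
            terms = "".join(
                f" {'+' if v > 0 else '-'} {abs(v):.12g} {names[j]}"
                for j, v in zip(A.indices[start:end], A.data[start:end])
            )
            lo, hi = constraint.lb[i], constraint.ub[i]
            if np.isfinite(hi):
                fh.write(f" c{row_no}:{terms} <= {hi:.12g}\n")
                row_no += 1
            if np.isfinite(lo):
                fh.write(f" c{row_no}:{terms} >= {lo:.12g}\n")
                row_no += 1
        fh.write("Bounds\n")
        for j, name in enumerate(names):
            fh.write(f" {var_bounds.lb[j]:.12g} <= {name} <= {var_bounds.ub[j]:.12g}\n")
        fh.write("Binaries\n")
        for j in np.flatnonzero(integrality):
            fh.write(f" {names[j]}\n")
        fh.write("End\n")
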