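"""Toy networks, planted instances, and exhaustive brute-force oracles.

The generator inverts the core relation: a ground-truth moles-passed
vector phi* is planted on a chosen support, the induced variations
S.phi* become the measured intervals, and the solver is asked to recover
the support.  The brute-force oracle enumerates every support respecting
split-pair exclusivity and solves the continuous restriction as an LP,
certifying the MILP and the cut-enumeration loop on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .measurements import DeltaInterval, MeasurementSet, build_bound_vectors
from .milp_core import TransientProblem
from .network_io import MetabolicNetwork, Metabolite, Reaction, SplitNetwork, split_reversible

__all__ = [
    "PlantedInstance",
    "SyntheticError",
    "make_toy_network",
    "make_planted_instance",
    "brute_force_solve",
    "brute_force_enumerate",
    "BRUTE_FORCE_MAX_REACTIONS",
]

BRUTE_FORCE_MAX_REACTIONS = 14
_OBJ_TOL = 1e-6


class SyntheticError(ValueError):
    """Invalid generator request."""


@dataclass
class PlantedInstance:
    """A toy problem with known ground truth."""

    net: SplitNetwork
    phi_star: np.ndarray
    measured_ids: list[str]
    deltas: dict[str, DeltaInterval]
    noise_halfwidth: float = 0.0
    #: epsilon just large enough to absorb phi*'s spill onto non-measured metabolites
    epsilon_required: float = 0.0

    def support_ids(self) -> list[str]:
        return [
            self.net.reactions[j].id for j in np.flatnonzero(self.phi_star > 0)
        ]

    def support_set(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.phi_star > 0).tolist())

    def measurement_set(self, epsilon: float | None = None) -> MeasurementSet:
        eps = self.epsilon_required if epsilon is None else epsilon
        return MeasurementSet(intervals=dict(self.deltas), epsilon=eps)


def _mets(n: int) -> list[Metabolite]:
    return [Metabolite(id=f"M{i+1}", compartment="c") for i in range(n)]


def make_toy_network(
    kind: str,
    size: int,
    seed: int = 0,
    *,
    reversible_fraction: float = 0.3,
    u_default: float = 1000.0,
) -> SplitNetwork:
    """Named toy topologies, already reversible-split.

    chain: M1 -> M2 -> ... -> Msize (size-1 reactions).
    branch: direct edge M1 -> M2 plus a path through C1..C(size-2).
    cycle: chain closed back onto M1.
    reversible_pair: M1 <=> M2 (one reversible reaction, split into 2).
    random: connected unit-stoichiometry digraph, a seeded fraction of
    the reactions reversible.
    """
    if size < 2:
        raise SyntheticError(f"size must be >= 2, got {size}")
    if kind == "chain":
        mets = _mets(size)
        rxns = [
            Reaction(
                id=f"r{i+1}",
                substrates=((mets[i].id, 1.0),),
                products=((mets[i + 1].id, 1.0),),
                upper_bound=u_default,
            )
            for i in range(size - 1)
        ]
    elif kind == "branch":
        if size < 3:
            raise SyntheticError("branch needs size >= 3")
        mets = _mets(size)  # M1 = source, M2 = target, M3.. = path intermediates
        path = [mets[0].id] + [m.id for m in mets[2:]] + [mets[1].id]
        rxns = [
            Reaction(
                id="r1",
                substrates=((mets[0].id, 1.0),),
                products=((mets[1].id, 1.0),),
                upper_bound=u_default,
            )
        ]
        for i in range(len(path) - 1):
            rxns.append(
                Reaction(
                    id=f"r{i+2}",
                    substrates=((path[i], 1.0),),
                    products=((path[i + 1], 1.0),),
                    upper_bound=u_default,
                )
            )
    elif kind == "cycle":
        mets = _mets(size)
        rxns = [
            Reaction(
                id=f"r{i+1}",
                substrates=((mets[i].id, 1.0),),
                products=((mets[(i + 1) % size].id, 1.0),),
                upper_bound=u_default,
            )
            for i in range(size)
        ]
    elif kind == "reversible_pair":
        mets = _mets(2)
        rxns = [
            Reaction(
                id="r1",
                substrates=((mets[0].id, 1.0),),
                products=((mets[1].id, 1.0),),
                reversible=True,
                upper_bound=u_default,
                reverse_upper_bound=u_default,
            )
        ]
    elif kind == "random":
        rng = np.random.default_rng(seed)
        mets = _mets(size)
        edges: list[tuple[int, int]] = []
        # spanning tree for connectivity, then a few extra arcs
        order = rng.permutation(size)
        for k in range(1, size):
            a = int(order[rng.integers(0, k)])
            b = int(order[k])
            edges.append((a, b))
        n_extra = int(rng.integers(0, max(2, size // 2)))
        for _ in range(n_extra):
            a, b = rng.choice(size, size=2, replace=False)
            if (int(a), int(b)) not in edges and (int(b), int(a)) not in edges:
                edges.append((int(a), int(b)))
        rxns = []
        for j, (a, b) in enumerate(edges):
            rev = bool(rng.random() < reversible_fraction)
            rxns.append(
                Reaction(
                    id=f"r{j+1}",
                    substrates=((mets[a].id, 1.0),),
                    products=((mets[b].id, 1.0),),
                    reversible=rev,
                    upper_bound=u_default,
                    reverse_upper_bound=u_default if rev else None,
                )
            )
    else:
        raise SyntheticError(f"unsupported topology kind {kind!r}")
    return split_reversible(MetabolicNetwork(mets, rxns), u_default=u_default)


def make_planted_instance(
    net: SplitNetwork,
    active_support: list[str] | list[int],
    magnitudes: float | np.ndarray = 2.0,
    measured_fraction: float = 1.0,
    noise_halfwidth: float = 0.0,
    seed: int = 0,
) -> PlantedInstance:
    """Plant phi* on a support and derive measured intervals from S.phi*.

    Metabolites with zero induced variation never qualify as measured; a
    noise half-width large enough to push an interval across zero drops
    that metabolite too (measured changes must be one-signed).
    """
    if noise_halfwidth < 0:
        raise SyntheticError("noise_halfwidth must be >= 0")
    idx = [net.rxn_index[r] if isinstance(r, str) else int(r) for r in active_support]
    support = frozenset(idx)
    for j, jb in net.pair_map:
        if j in support and jb in support:
            raise SyntheticError(
                f"support contains both directions of split pair "
                f"{net.reactions[j].id}/{net.reactions[jb].id}"
            )
    mags = np.broadcast_to(np.asarray(magnitudes, dtype=float), (len(idx),))
    if np.any(mags <= 0):
        raise SyntheticError("magnitudes must be > 0")
    phi_star = np.zeros(net.n_reactions)
    for j, mag in zip(idx, mags):
        phi_star[j] = mag
    v = net.S @ phi_star
    candidates = [
        i
        for i in range(net.n_metabolites)
        if abs(v[i]) > 1e-12 and abs(v[i]) > noise_halfwidth
    ]
    if not candidates:
        raise SyntheticError(
            "planted support induces no one-signed measurable variation; "
            "instance rejected"
        )
    rng = np.random.default_rng(seed)
    n_meas = max(1, int(round(measured_fraction * len(candidates))))
    measured = sorted(rng.choice(candidates, size=min(n_meas, len(candidates)), replace=False))
    deltas = {}
    for i in measured:
        mid = net.metabolites[i].id
        deltas[mid] = DeltaInterval(mid, v[i] - noise_halfwidth, v[i] + noise_halfwidth)
    unmeasured_spill = [abs(v[i]) for i in range(net.n_metabolites) if i not in measured]
    eps_req = float(max(unmeasured_spill)) if unmeasured_spill else 0.0
    return PlantedInstance(
        net=net,
        phi_star=phi_star,
        measured_ids=[net.metabolites[i].id for i in measured],
        deltas=deltas,
        noise_halfwidth=noise_halfwidth,
        epsilon_required=eps_req,
    )


# ---------------------------------------------------------------------------
# exhaustive oracle

def _iter_supports(p: TransientProblem):
    """All supports respecting pair exclusivity (and skipping blocked columns)."""
    n = p.net.n_reactions
    u = p.u
    paired = {j for pair in p.net.pair_map for j in pair}
    singles = [j for j in range(n) if j not in paired]
    # slot choices: per pair (off, fwd, bwd); per single (off, on)
    slot_opts: list[list[tuple[int, ...]]] = []
    for j, jb in p.net.pair_map:
        opts = [()]
        if u[j] >= p.theta:
            opts.append((j,))
        if u[jb] >= p.theta:
            opts.append((jb,))
        slot_opts.append(opts)
    for j in singles:
        opts = [()]
        if u[j] >= p.theta:
            opts.append((j,))
        slot_opts.append(opts)
    for combo in itertools.product(*slot_opts):
        yield frozenset(itertools.chain.from_iterable(combo))


def _support_lp(p: TransientProblem, support: frozenset[int]) -> float | None:
    """Best continuous objective for a fixed support, or None if infeasible.

    Variables: phi_j for j in support (in [theta, u_j]) and epigraph
    auxiliaries for the non-measured metabolites.  Returns the *full*
    objective including the lam * |support| cardinality term.
    """
    net, b = p.net, p.bounds
    card_term = p.lam * len(support)
    cols = sorted(support)
    K = len(cols)
    if K == 0:
        # phi = 0 feasible iff every interval admits 0
        if np.all(b.delta_min <= 1e-12) and np.all(b.delta_max >= -1e-12):
            return 0.0
        return None
    S_sub = p.net.S[:, cols].toarray()
    measured = b.measured_mask
    nonmeas = np.flatnonzero(~measured)
    k = len(nonmeas)

    if p.cardinality_only:
        c = np.zeros(K + k)
    else:
        sign_X = b.sign.astype(float)
        c = np.concatenate(
            [-(1.0 - p.lam) * (S_sub.T @ sign_X), np.full(k, 1.0 - p.lam)]
        )
    A_ub_blocks = [
        np.hstack([S_sub, np.zeros((net.n_metabolites, k))]),   # S.phi <= dmax
        np.hstack([-S_sub, np.zeros((net.n_metabolites, k))]),  # -S.phi <= -dmin
    ]
    b_ub_blocks = [b.delta_max, -b.delta_min]
    if k:
        I = np.eye(k)
        A_ub_blocks.append(np.hstack([S_sub[nonmeas, :], -I]))
        A_ub_blocks.append(np.hstack([-S_sub[nonmeas, :], -I]))
        b_ub_blocks.extend([np.zeros(k), np.zeros(k)])
    A_ub = np.vstack(A_ub_blocks)
    b_ub = np.concatenate(b_ub_blocks)
    bounds = [(p.theta, p.u[j]) for j in cols] + [(0.0, None)] * k
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status != 0:
        return None
    if p.cardinality_only:
        return card_term
    return card_term + float(res.fun)


def brute_force_solve(
    p: TransientProblem,
) -> tuple[float | None, set[frozenset[int]]]:
    """Global optimum by exhaustive support enumeration (oracle).

    Honours any exclusion cuts already attached to the problem.  Returns
    (best objective, all supports attaining it within 1e-6); an
    infeasible instance returns (None, empty set).
    """
    if p.net.n_reactions > BRUTE_FORCE_MAX_REACTIONS:
        raise SyntheticError(
            f"instance has {p.net.n_reactions} split reactions; brute force is "
            f"capped at {BRUTE_FORCE_MAX_REACTIONS}"
        )
    best: float | None = None
    optima: set[frozenset[int]] = set()
    # necessary condition per measured metabolite: the support must contain a
    # reaction contributing in the interval's direction
    b = p.bounds
    S = p.net.S.tocsr()
    needed: list[set[int]] = []
    for i in np.flatnonzero(b.measured_mask):
        row = S[[i], :].toarray().ravel()
        # only when the row's bounds actually exclude zero (a source/sink
        # declaration may have widened one side back across zero)
        if b.delta_min[i] > 0:
            needed.append(set(np.flatnonzero(row > 0).tolist()))
        elif b.delta_max[i] < 0:
            needed.append(set(np.flatnonzero(row < 0).tolist()))
    for support in _iter_supports(p):
        if any(cut <= support for cut in p.cuts):
            continue
        if any(not (req & support) for req in needed):
            continue
        obj = _support_lp(p, support)
        if obj is None:
            continue
        if best is None or obj < best - _OBJ_TOL:
            best = obj
            optima = {support}
        elif obj <= best + _OBJ_TOL:
            optima.add(support)
    return best, optima


def brute_force_enumerate(
    p: TransientProblem, n_max: int
) -> list[frozenset[int]]:
    """Run the cut-and-resolve loop with the oracle as the solver.

    Ties between equally optimal supports are broken lexicographically
    (sorted index tuple) so the oracle sequence is deterministic.
    """
    saved_cuts = list(p.cuts)
    supports: list[frozenset[int]] = []
    try:
        while len(supports) < n_max:
            best, optima = brute_force_solve(p)
            if best is None:
                break
            chosen = min(optima, key=lambda s: tuple(sorted(s)))
            supports.append(chosen)
            if not chosen:
                break
            p.cuts.append(chosen)
    finally:
        p.cuts.clear()
        p.cuts.extend(saved_cuts)
    return supports
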