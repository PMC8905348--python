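# Methods

## Problem statement

Two metabolic states of one organism are measured (e.g., a glucose-grown
baseline and the pseudo-steady state reached seconds after a substrate
pulse). For a subset X of metabolites the change in internal amount between
the states is known as an interval [Delta_min_i, Delta_max_i], strictly
positive (accumulation) or strictly negative (depletion). The task is to
propose minimal sets of reactions, with the moles each passed, that move the
network from the first state to the second — the transient state is never
observed directly.

The key modelling step is integrating the rate equation over the
transition: d[X]/dt = S.v becomes Delta = S.phi, where phi_j >= 0 is the
*moles passed* by reaction j over the whole interval (the area under its
rate curve), not a steady-state flux. No steady-state assumption is made for
the transient; phi is a single displacement vector.

## The optimisation problem

After splitting every reversible reaction into a forward member (original
id) and a backward member (id + `_R`, substrates/products swapped), all
phi_j are non-negative and direction becomes part of the support. Binary
y_j indicates activity, linked by

    theta * y_j <= phi_j <= u_j * y_j,      y_j + y_jbar <= 1 per split pair.

With theta > 0 the link is a true equivalence up to theta; theta = 0
degrades to the one-sided big-M link, where y = 1 with phi = 0 is feasible
but never optimal at lambda > 0. The objective balances three terms with
one weight lambda in (0, 1): the active-reaction count, the total
unexplained slack |S.phi| on non-measured metabolites (minimised, via
epigraph auxiliaries a_i >= +-(S.phi)_i — minimisation with positive
coefficient (1 - lambda) forces them to bind at any optimum), and the
explained change |S.phi| on measured metabolites (maximised). The measured
absolute values are linear only because measured intervals are strictly
one-signed: the sign s_i is precomputed and the term written
s_i * (S.phi)_i. This is exactly why zero-spanning measured intervals are
rejected at input time rather than clamped.

lambda = 1 is exposed as a separate cardinality-only mode (minimise the
count alone); it exists mainly so the exhaustive oracle can compare
support-minimal solutions without continuous terms.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| lambda | weight between count and variation terms | 0.1 | low values favour connected, pathway-like solutions; high values favour small local ones |
| epsilon | allowed \|variation\| of any non-measured metabolite (same amount units as the deltas) | 0 | the strictest assumption; raise it when the measured set is sparse, lower it to force connectivity (too low can make the program infeasible) |
| theta | minimum moles passed by an active reaction | 1e-4 | small enough not to constrain real activity, large enough to separate "on" from numerical zero; support is read back with threshold theta/2 |
| u_default | per-reaction upper bound on moles passed when the SBML gives none | 1000 | a free scale parameter; only needs to dominate the measured deltas |
| mip_gap / time_limit_s | per-iteration solver termination controls | 0 / none | gap 0 gives the monotone-objective guarantee; ~0.05 is a practical setting for genome-scale models, and gap- or time-limited solutions are still recorded and cut |

Boundary reactions (empty substrate or product set, or touching only
boundary-flagged species) are blocked by setting u_j = 0 — columns are kept
so indices stay stable. Virtual sources/sinks are re-introduced per
metabolite by widening delta_min to -M or delta_max to +M; M defaults to
10x the largest measured |delta| so that it stays on the scale of the data.

## Enumeration

After a solution with support P, the cut sum_{j in P} y_j <= |P| - 1
forbids P *and every superset of P* in later iterations; the implementation
follows that printed constraint and the anti-superset side effect is
asserted in the tests. The objective is deliberately not fixed to the first
optimum, so enumeration can walk into slightly suboptimal solutions; with
mip_gap = 0 the objective sequence is non-decreasing because the feasible
region only shrinks. An optional max_degradation fraction stops enumeration
once solutions get worse than a user-chosen fraction of the first
objective. Solution order among exact ties is solver-dependent and is never
asserted on; tests compare sets of supports, or objective sequences when
ties are possible.

## Numerical choices

- Solver: HiGHS through scipy (`milp` for the MILP, `linprog` for oracle
  LPs). It is single-threaded and deterministic, so the seed/threads
  options in `SolverOptions` are recorded for provenance but are no-ops.
- Feasibility tolerance 1e-6 everywhere; `check_feasibility` re-verifies
  every constraint of each returned solution and returns violations as
  data.
- The recorded objective is always re-evaluated from raw phi and y with
  true absolute values (`evaluate_objective`), independent of the solver's
  auxiliary-based value.
- phi entries below theta/2 are zeroed as numerical dust before supports
  are read, so cuts are never built from noise.
- Delta-from-baseline convention: when a baseline mean m, replicate
  deviation d and fold change f are given, the interval is
  m*(f-1) +- d (deviation attributed to the baseline only). This is a
  documented stand-in, isolated in `derive_interval_from_baseline` so a
  multiplicative-propagation variant can be swapped in; intervals that span
  zero are rejected as not significant.
- The epsilon relaxation is symmetric [-eps, +eps] by default, with
  per-metabolite overrides (e.g., to cap it by the largest measured
  change).

## Synthetic instances and what green tests establish

The generator *inverts* the model: it plants a ground-truth phi* on a
chosen support of a toy topology (chain, branch-with-detour, cycle,
reversible pair, seeded random connected unit-stoichiometry networks),
derives measured intervals from S.phi* (optionally widened by a noise
half-width), and reports the epsilon needed to absorb phi*'s spill onto
non-measured metabolites. Instances are certified by an exhaustive oracle
that enumerates every support respecting pair exclusivity (capped at 14
split reactions), solves the continuous restriction of each as an LP, and
replays the identical cut loop with lexicographic tie-breaking.

These toys share the real problem's structure (stoichiometry, splitting,
one-signed intervals, epsilon slack) but not its scale or biology: unit
stoichiometry, no cofactors, no compartments, complete or near-complete
measurement coverage. A green suite therefore establishes that the MILP
and cut loop are *correct* (they match exhaustive search and recover
planted answers), not that parameter defaults are biologically tuned for
any particular organism or dataset. Random acceptance instances are kept
to <= 8 split reactions so the exhaustive cross-check of 50 instances runs
in seconds on one CPU; the cap is a runtime scaling choice, within the
oracle's validity range, not a limitation of the solver path.

## Known limitations

- Concentration-to-amount unit conversion is the user's responsibility;
  all deltas and epsilon share one amount unit.
- No statistical testing across replicates: significance of a measured
  change is taken as given (zero-spanning intervals are simply rejected).
- One solution reports one direction per reversible reaction; oscillating
  activity within the transition interval is integrated away by
  construction.
- Enumeration with exclusion cuts also excludes supersets of earlier
  supports; a strictly-new-combination semantics would require a different
  cut family and is out of scope.
- Infeasibility diagnosis lists the measured metabolites as candidates; no
  irreducible-infeasible-subsystem computation is attempted.
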