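# deltaflux

Constraint-based inference of the reactions active during the **transient
state** between two measured metabolic conditions — for example, before and
shortly after a substrate pulse in a microbial culture.

Metabolomics gives you *differences* in internal metabolite amounts between
two states, but not the route the network took between them. `deltaflux`
integrates those differences into a genome-scale stoichiometric model and
enumerates minimal sets of reactions, each with the moles it passed, that
explain the measured changes. It is aimed at systems-biology practitioners
with an SBML model (BiGG-style or otherwise) and a table of significant
concentration changes.

## Model

Write the network as an m x n stoichiometric matrix S. Over the transition
interval, each reaction j passes a non-negative number of moles
phi_j = integral of its rate (reversible reactions are first split into
forward/backward pairs, so direction is part of the answer). The measured
change of metabolite i must be reproduced by the network:

```
Delta_min <= S . phi <= Delta_max        0 <= phi_j <= u_j
```

Measured metabolites take their (strictly one-signed) intervals
[Delta_min, Delta_max]; every non-measured metabolite is allowed a slack of
at most epsilon in either direction. Binary support indicators y_j
(y_j = 0 <=> phi_j = 0, with y_j + y_jbar <= 1 per split pair) make the
objective a trade-off controlled by a weight lambda in (0, 1):

```
min  lambda * sum_j y_j                              # few active reactions
   + (1 - lambda) * sum_{i not measured} |(S.phi)_i| # little unexplained slack
   - (1 - lambda) * sum_{i measured}     |(S.phi)_i| # much explained change
```

This is a mixed-integer linear program (the measured absolute values are
linear because the intervals are one-signed; the non-measured ones use
epigraph auxiliaries), solved with HiGHS. Alternate optima are enumerated by
adding, after each solution with support P, the exclusion cut
`sum_{j in P} y_j <= |P| - 1` and re-solving until the desired count is
reached or the program becomes infeasible. Low lambda (0.1) favours
connected pathway-like solutions; high lambda favours small local ones;
boundary (source/sink) reactions are blocked by default so imbalances stay
inside the network, and virtual sources/sinks are declared by widening a
metabolite's interval.

## Worked example

Generate a 3-metabolite toy: a direct route `r1: M1 -> M2` in parallel with
a detour `r2: M1 -> M3`, `r3: M3 -> M2`, with 2 moles planted on the direct
route, then ask for all solutions at lambda = 0.1, epsilon = 0:

```
$ deltaflux fixtures --kind branch --size 3 --seed 7 --out fx
$ deltaflux run --model fx/model.xml --deltas fx/deltas.tsv \
    --lam 0.1 --epsilon 0 --num-solutions 10 --no-block-boundary --out run
enumerated 2 solution(s); termination: infeasible
  solution 0: objective -3.5000, 1 active reactions (optimal)
  solution 1: objective -3.4000, 2 active reactions (optimal)
```

The measured input is M1: [-2, -2] (depleted) and M2: [+2, +2]
(accumulated). The first solution routes 2 moles through `r1`
(objective 0.1*1 - 0.9*(2+2) = -3.5); after the cut `y_r1 <= 0` the only
alternative is the detour `{r2, r3}` (one more active reaction, objective
-3.4); a second cut leaves nothing feasible, so enumeration stops. The run
directory reports, per (reaction, direction), how often it was used:

```
$ cat run/occurrence.tsv
reaction_id  direction  occurrence_count  occurrence_pct  mean_phi_active
r1           forward    1                 50.0            2.0
r2           forward    1                 50.0            2.0
r3           forward    1                 50.0            2.0
```

plus per-solution moles-passed and predicted-variation tables and
`escher_data.json`, a signed occurrence map (forward positive, reverse
negative) loadable as reaction data in pathway-map viewers.

The same pipeline is available as a library (`load_sbml`,
`split_reversible`, `block_boundary`, `build_bound_vectors`,
`build_problem`, `enumerate_solutions`, `occurrence_table`,
`robustness_analysis`, ...), including a leave-metabolites-out robustness
analysis that re-runs the enumeration and reports mean absolute
occurrence-percentage distances.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch on a seeded generated instance —
SBML round-trip, measured-interval parsing, MILP assembly, cut enumeration,
reporting — and certifies every returned solution against an exhaustive
brute-force oracle (all supports enumerated, each reduced to a linear
program) before writing the results JSON.
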