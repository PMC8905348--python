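"""Aggregation of enumerated solutions into tables and exports.

Occurrence statistics are direction-resolved: the forward and backward
members of one split reversible reaction are counted as two distinct
rows (they can never co-occur within one solution).  Occurrence
percentages are taken over all enumerated solutions, the convention used
by pathway-map overlays.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .enumeration import SolutionSet, enumerate_solutions
from .measurements import MeasurementSet, build_bound_vectors
from .milp_core import InfeasibleProblemError, SolverOptions, build_problem
from .network_io import SplitNetwork

__all__ = [
    "ReportingError",
    "occurrence_table",
    "predicted_variations",
    "export_escher",
    "occurrence_distance",
    "robustness_analysis",
    "random_exclusion_sets",
    "write_run_outputs",
]


class ReportingError(ValueError):
    """Invalid reporting input."""


def occurrence_table(ss: SolutionSet, net: SplitNetwork | None = None) -> pd.DataFrame:
    """Per-(original reaction, direction) occurrence counts over all solutions.

    Columns: reaction_id, direction, occurrence_count, occurrence_pct,
    mean_phi_active.  Reactions never active are absent.
    """
    if net is None:
        if ss.problem is None:
            raise ReportingError("no network attached to the solution set")
        net = ss.problem.net
    if not ss.solutions:
        raise ReportingError("empty solution set")
    n_sol = len(ss.solutions)
    counts: dict[tuple[str, str], int] = {}
    phi_sums: dict[tuple[str, str], float] = {}
    for sol in ss.solutions:
        for j in np.flatnonzero(sol.support):
            key = net.origin(net.reactions[j].id)
            counts[key] = counts.get(key, 0) + 1
            phi_sums[key] = phi_sums.get(key, 0.0) + float(sol.phi[j])
    rows = [
        {
            "reaction_id": rid,
            "direction": direction,
            "occurrence_count": cnt,
            "occurrence_pct": 100.0 * cnt / n_sol,
            "mean_phi_active": phi_sums[(rid, direction)] / cnt,
        }
        for (rid, direction), cnt in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "reaction_id",
            "direction",
            "occurrence_count",
            "occurrence_pct",
            "mean_phi_active",
        ],
    )


def predicted_variations(ss: SolutionSet, net: SplitNetwork | None = None) -> pd.DataFrame:
    """Per-solution, per-metabolite predicted variation (S.phi).

    Columns: solution, metabolite_id, variation, measured, kind
    (accumulation / depletion / none).
    """
    if net is None:
        if ss.problem is None:
            raise ReportingError("no network attached to the solution set")
        net = ss.problem.net
    measured = (
        ss.problem.bounds.measured_mask
        if ss.problem is not None
        else np.zeros(net.n_metabolites, dtype=bool)
    )
    records = []
    for k, sol in enumerate(ss.solutions):
        v = sol.predicted_variation
        for i, met in enumerate(net.metabolites):
            kind = "accumulation" if v[i] > 1e-9 else "depletion" if v[i] < -1e-9 else "none"
            records.append(
                {
                    "solution": k,
                    "metabolite_id": met.id,
                    "variation": float(v[i]),
                    "measured": bool(measured[i]),
                    "kind": kind,
                }
            )
    return pd.DataFrame(
        records, columns=["solution", "metabolite_id", "variation", "measured", "kind"]
    )


def export_escher(tbl: pd.DataFrame, path: str | None = None) -> dict[str, float]:
    """Reaction-data mapping for pathway-map viewers.

    Forward occurrences are positive percentages, reverse ones negative,
    keyed by the original reaction id.  If both directions of one
    reaction occur (across different solutions), both are kept under
    direction-suffixed ids with a warning.
    """
    data: dict[str, float] = {}
    by_rxn: dict[str, list[tuple[str, float]]] = {}
    for row in tbl.itertuples(index=False):
        by_rxn.setdefault(row.reaction_id, []).append((row.direction, row.occurrence_pct))
    for rid, entries in by_rxn.items():
        if len(entries) == 1:
            direction, pct = entries[0]
            data[rid] = pct if direction == "forward" else -pct
        else:
            warnings.warn(
                f"reaction {rid} occurs in both directions across solutions; "
                f"exporting direction-suffixed entries",
                stacklevel=2,
            )
            for direction, pct in entries:
                suffix = "_fwd" if direction == "forward" else "_rev"
                data[rid + suffix] = pct if direction == "forward" else -pct
    if path is not None:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
    return data


def occurrence_distance(
    tbl_a: pd.DataFrame, tbl_b: pd.DataFrame, aggregate: str = "mean"
) -> float:
    """Distance between two occurrence tables.

    Mean (or max) over the union of (reaction, direction) rows of the
    absolute occurrence-percentage difference; rows missing from one
    table count as 0%.  Symmetric, and zero iff the tables coincide.
    """
    if aggregate not in ("mean", "max"):
        raise ReportingError(f"aggregate must be 'mean' or 'max', got {aggregate!r}")
    a = {(r.reaction_id, r.direction): r.occurrence_pct for r in tbl_a.itertuples(index=False)}
    b = {(r.reaction_id, r.direction): r.occurrence_pct for r in tbl_b.itertuples(index=False)}
    keys = set(a) | set(b)
    if not keys:
        return 0.0
    diffs = [abs(a.get(k, 0.0) - b.get(k, 0.0)) for k in keys]
    return float(np.mean(diffs) if aggregate == "mean" else np.max(diffs))


def robustness_analysis(
    net: SplitNetwork,
    ms: MeasurementSet,
    lam: float,
    exclusions: list[set[str]],
    n_max: int,
    *,
    theta: float | None = None,
    options: SolverOptions | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Leave-subset-out robustness of the occurrence statistics.

    For each exclusion set, re-runs the full enumeration on the reduced
    measured set and reports the occurrence distance to the complete-set
    run.  Columns: excluded, distance, n_solutions.
    """
    kwargs = {}
    if theta is not None:
        kwargs["theta"] = theta

    def _run(mset: MeasurementSet) -> SolutionSet:
        bounds = build_bound_vectors(net, mset)
        prob = build_problem(
            net, bounds, lam, options=options or SolverOptions(), **kwargs
        )
        return enumerate_solutions(prob, n_max)

    full_tbl = occurrence_table(_run(ms), net)
    records = []
    for excl in exclusions:
        excl = set(excl)
        if excl:
            reduced = ms.without(excl)
        else:
            reduced = ms
        try:
            ss_red = _run(reduced)
        except InfeasibleProblemError:
            # the reduced measured set admits no solution at all: compare
            # against an empty occurrence table (every row drops to 0%)
            ss_red = SolutionSet()
        red_tbl = occurrence_table(ss_red, net) if ss_red.solutions else pd.DataFrame(
            columns=full_tbl.columns
        )
        records.append(
            {
                "excluded": ",".join(sorted(excl)) if excl else "",
                "distance": occurrence_distance(full_tbl, red_tbl, aggregate),
                "n_solutions": len(ss_red.solutions),
            }
        )
    return pd.DataFrame(records, columns=["excluded", "distance", "n_solutions"])


def random_exclusion_sets(
    measured_ids: list[str], k: int, size: int, seed: int
) -> list[set[str]]:
    """k seeded random exclusion subsets of the measured metabolites."""
    if size >= len(measured_ids):
        raise ReportingError(
            f"exclusion size {size} would remove all {len(measured_ids)} measurements"
        )
    rng = np.random.default_rng(seed)
    return [
        set(rng.choice(measured_ids, size=size, replace=False).tolist()) for _ in range(k)
    ]


def write_run_outputs(
    outdir: str,
    ss: SolutionSet,
    net: SplitNetwork,
    config: dict | None = None,
) -> Path:
    """Write the one-directory-per-run layout.

    solutions/solution_k.tsv (reaction, direction, phi), variations/
    solution_k.tsv, occurrence.tsv, escher_data.json, run_log.txt and a
    config echo.
    """
    out = Path(outdir)
    (out / "solutions").mkdir(parents=True, exist_ok=True)
    (out / "variations").mkdir(exist_ok=True)
    var_tbl = predicted_variations(ss, net)
    for k, sol in enumerate(ss.solutions):
        rows = []
        for j in np.flatnonzero(sol.support):
            rid, direction = net.origin(net.reactions[j].id)
            rows.append((rid, direction, float(sol.phi[j])))
        pd.DataFrame(rows, columns=["reaction_id", "direction", "phi"]).to_csv(
            out / "solutions" / f"solution_{k}.tsv", sep="\t", index=False
        )
        var_tbl[var_tbl["solution"] == k].drop(columns="solution").to_csv(
            out / "variations" / f"solution_{k}.tsv", sep="\t", index=False
        )
    tbl = occurrence_table(ss, net)
    tbl.to_csv(out / "occurrence.tsv", sep="\t", index=False)
    export_escher(tbl, str(out / "escher_data.json"))
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"n_solutions\t{len(ss.solutions)}\n")
        fh.write(f"termination\t{ss.termination}\n")
        for k, sol in enumerate(ss.solutions):
            fh.write(
                f"solution_{k}\tobjective={sol.objective:.6f}\tstatus={sol.status}"
                f"\tgap={sol.mip_gap:.4g}\tsize={int(np.count_nonzero(sol.support))}\n"
            )
    if config is not None:
        with open(out / "config.json", "w") as fh:
            json.dump(config, fh, indent=1, sort_keys=True, default=str)
    return out
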