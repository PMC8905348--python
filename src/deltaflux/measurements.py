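"""Measured concentration-change intervals and bound-vector assembly.

Each measured metabolite carries an interval [delta_min, delta_max] for
its change in amount between the two states; the interval must be
strictly one-signed (an interval spanning zero would make the maximised
absolute-value term in the objective non-linear, so such metabolites are
rejected as "no significant change").  Non-measured metabolites are
relaxed to [-epsilon, +epsilon].  Virtual sources/sinks are expressed by
widening one side of a metabolite's interval to a large magnitude M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_io import SplitNetwork

__all__ = [
    "DeltaInterval",
    "MeasurementSet",
    "BoundVectors",
    "MeasurementError",
    "SignViolationError",
    "NotSignificantError",
    "UnknownMetaboliteError",
    "read_deltas",
    "write_deltas",
    "derive_interval_from_baseline",
    "build_bound_vectors",
]

logger = logging.getLogger(__name__)


class MeasurementError(ValueError):
    """Invalid measurement input."""


class SignViolationError(MeasurementError):
    """Interval spans zero (or sign is inconsistent)."""


class NotSignificantError(SignViolationError):
    """Derived interval spans zero: the change is not significant."""


class UnknownMetaboliteError(MeasurementError):
    """A measurement refers to a metabolite absent from the network."""


@dataclass(frozen=True)
class DeltaInterval:
    """One measured metabolite's change in amount, as a signed interval."""

    metabolite_id: str
    delta_min: float
    delta_max: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta_min", float(self.delta_min))
        object.__setattr__(self, "delta_max", float(self.delta_max))
        if self.delta_min > self.delta_max:
            raise MeasurementError(
                f"{self.metabolite_id}: delta_min ({self.delta_min}) > "
                f"delta_max ({self.delta_max})"
            )
        if self.delta_min <= 0 <= self.delta_max:
            raise SignViolationError(
                f"{self.metabolite_id}: interval [{self.delta_min}, {self.delta_max}] "
                f"spans zero; a measured change must be strictly positive or negative"
            )

    @property
    def sign(self) -> int:
        return 1 if self.delta_min > 0 else -1


@dataclass
class MeasurementSet:
    """The measured set X plus the relaxation policy for everything else."""

    intervals: dict[str, DeltaInterval]
    epsilon: float = 0.0
    epsilon_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    sources: list[tuple[str, float | None]] = field(default_factory=list)
    sinks: list[tuple[str, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise MeasurementError(f"epsilon must be >= 0, got {self.epsilon}")
        overlap = set(self.intervals) & set(self.epsilon_overrides)
        if overlap:
            raise MeasurementError(
                f"metabolite(s) both measured and epsilon-overridden: {sorted(overlap)}"
            )
        for mid, (lo, hi) in self.epsilon_overrides.items():
            if lo > hi:
                raise MeasurementError(f"epsilon override for {mid}: {lo} > {hi}")
        for mid, mag in (*self.sources, *self.sinks):
            if mag is not None and not mag > 0:
                raise MeasurementError(f"source/sink magnitude for {mid} must be > 0")

    @property
    def measured_ids(self) -> list[str]:
        return list(self.intervals)

    def default_magnitude(self) -> float:
        """Default virtual source/sink magnitude: 10x the largest measured |delta|."""
        if not self.intervals:
            return 10.0 * max(self.epsilon, 1.0)
        biggest = max(
            max(abs(iv.delta_min), abs(iv.delta_max)) for iv in self.intervals.values()
        )
        return 10.0 * biggest

    def without(self, excluded: set[str] | list[str]) -> "MeasurementSet":
        """Copy with some measured metabolites removed (robustness analysis)."""
        excluded = set(excluded)
        unknown = excluded - set(self.intervals)
        if unknown:
            raise UnknownMetaboliteError(f"cannot exclude unmeasured: {sorted(unknown)}")
        kept = {k: v for k, v in self.intervals.items() if k not in excluded}
        if not kept:
            raise MeasurementError("exclusion would remove every measurement")
        return MeasurementSet(
            intervals=kept,
            epsilon=self.epsilon,
            epsilon_overrides=dict(self.epsilon_overrides),
            sources=list(self.sources),
            sinks=list(self.sinks),
        )


@dataclass
class BoundVectors:
    """Per-metabolite bounds on S.phi, aligned to the network's order."""

    delta_min: np.ndarray
    delta_max: np.ndarray
    measured_mask: np.ndarray  # bool, True on X
    sign: np.ndarray  # +1/-1 on X, 0 elsewhere

    def __post_init__(self) -> None:
        if np.any(self.delta_min > self.delta_max):
            bad = np.where(self.delta_min > self.delta_max)[0]
            raise MeasurementError(f"delta_min > delta_max at rows {bad.tolist()}")


# ---------------------------------------------------------------------------
# TSV input / output

_COLUMNS = ["metabolite_id", "delta_min", "delta_max"]


def read_deltas(path: str) -> dict[str, DeltaInterval]:
    """Read a deltas TSV (columns metabolite_id, delta_min, delta_max).

    '#'-prefixed lines are comments.  Zero-spanning intervals and duplicate
    metabolite ids are rejected.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"metabolite_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    dup = df["metabolite_id"][df["metabolite_id"].duplicated()].tolist()
    if dup:
        raise MeasurementError(f"{path}: duplicate metabolite id(s) {sorted(set(dup))}")
    out: dict[str, DeltaInterval] = {}
    for row in df.itertuples(index=False):
        iv = DeltaInterval(
            metabolite_id=row.metabolite_id,
            delta_min=float(row.delta_min),
            delta_max=float(row.delta_max),
        )
        out[iv.metabolite_id] = iv
    return out


def write_deltas(intervals: dict[str, DeltaInterval], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for iv in intervals.values():
            fh.write(f"{iv.metabolite_id}\t{iv.delta_min!r}\t{iv.delta_max!r}\n")


def derive_interval_from_baseline(
    metabolite_id: str,
    baseline_mean: float,
    baseline_dev: float,
    fold_change: float,
) -> DeltaInterval:
    """Derive a change interval from a baseline measurement and a fold change.

    Convention: the change centre is baseline_mean * (fold_change - 1) and
    the replicate deviation (attributed to the baseline measurement) widens
    it symmetrically: delta = centre +/- baseline_dev.  If the resulting
    interval spans zero the change is not significant and the metabolite
    should be dropped from the measured set.
    """
    if not baseline_mean > 0:
        raise MeasurementError(f"{metabolite_id}: baseline mean must be > 0")
    if baseline_dev < 0:
        raise MeasurementError(f"{metabolite_id}: baseline deviation must be >= 0")
    if not fold_change > 0:
        raise MeasurementError(f"{metabolite_id}: fold change must be > 0")
    center = baseline_mean * (fold_change - 1.0)
    lo, hi = center - baseline_dev, center + baseline_dev
    if lo <= 0 <= hi:
        raise NotSignificantError(
            f"{metabolite_id}: derived interval [{lo}, {hi}] spans zero "
            f"(change not significant)"
        )
    return DeltaInterval(metabolite_id, lo, hi)


# ---------------------------------------------------------------------------
# bound-vector assembly

def build_bound_vectors(net: SplitNetwork, ms: MeasurementSet) -> BoundVectors:
    """Assemble the full delta_min/delta_max vectors over all metabolites.

    Measured metabolites take their intervals; non-measured ones take
    [-epsilon, +epsilon] unless overridden.  Declared sources widen
    delta_min to -M and sinks widen delta_max to +M (M defaulting to 10x
    the largest measured |delta|).
    """
    m = net.n_metabolites
    idx = net.met_index
    for mid in (*ms.intervals, *ms.epsilon_overrides):
        if mid not in idx:
            raise UnknownMetaboliteError(f"measured metabolite {mid} not in network")
    for mid, _ in (*ms.sources, *ms.sinks):
        if mid not in idx:
            raise UnknownMetaboliteError(f"source/sink metabolite {mid} not in network")

    dmin = np.full(m, -ms.epsilon, dtype=float)
    dmax = np.full(m, ms.epsilon, dtype=float)
    measured = np.zeros(m, dtype=bool)
    sign = np.zeros(m, dtype=int)
    for mid, (lo, hi) in ms.epsilon_overrides.items():
        dmin[idx[mid]] = lo
        dmax[idx[mid]] = hi
    for mid, iv in ms.intervals.items():
        i = idx[mid]
        dmin[i], dmax[i] = iv.delta_min, iv.delta_max
        measured[i] = True
        sign[i] = iv.sign

    default_M = ms.default_magnitude()
    for mid, mag in ms.sources:
        dmin[idx[mid]] = -(mag if mag is not None else default_M)
    for mid, mag in ms.sinks:
        dmax[idx[mid]] = +(mag if mag is not None else default_M)
    return BoundVectors(delta_min=dmin, delta_max=dmax, measured_mask=measured, sign=sign)
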