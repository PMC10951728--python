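"""Average positive power per joint and contributor, and its distribution.

The average positive power of a joint over a hop cycle is the trapezium
integral of the positive part of its power trace divided by the cycle
duration; where the trace changes sign between samples the positive
triangular sub-area is included via linear interpolation of the zero
crossing, so the result does not depend on where the grid happens to cut a
burst of positive work.  Totals sum ankle + knee + hip overall powers
(P_tot), and every joint-by-contributor average is also expressed as a
percentage of P_tot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .exo import JOINTS, KineticsDecomposition
from .signals import HopCycleSet

__all__ = ["PowerSummary", "average_positive_power", "summarize"]

CONTRIBUTORS = ("overall", "exo", "mtu")


class UndefinedDistributionError(ZeroDivisionError):
    """Total average positive power is zero; percentages are undefined."""


def _positive_trapezoid(p: np.ndarray, dt: float) -> float:
    """Integral of max(p, 0) with sign-change sub-areas interpolated."""
    a, b = p[:-1], p[1:]
    both_pos = (a >= 0) & (b >= 0)
    area = np.where(both_pos, 0.5 * (a + b) * dt, 0.0)
    mixed = (a > 0) ^ (b > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tri = 0.5 * np.maximum(a, b) ** 2 / (np.abs(a) + np.abs(b)) * dt
    area = np.where(mixed & ~both_pos, tri, area)
    return float(area.sum())


def average_positive_power(power: np.ndarray, rate: float, cycle: tuple) -> float:
    """Average positive power (W) of one series over one hop cycle.

    ``cycle`` is a half-open [start, stop) sample range; the integral runs
    to the first sample of the next cycle so consecutive cycles tile the
    trial without gaps.
    """
    s, e = cycle
    if e <= s:
        raise ValueError("zero-length cycle")
    p = np.asarray(power, float)
    stop = min(e + 1, p.shape[0])  # include the right edge sample
    seg = p[s:stop]
    if seg.size < 2:
        raise ValueError("cycle too short for integration")
    dt = 1.0 / rate
    duration = (e - s) * dt
    return _positive_trapezoid(seg, dt) / duration


@dataclass
class PowerSummary:
    """Per joint x contributor average positive power and distribution.

    ``table`` is tidy: one row per (joint, contributor) with absolute (W),
    mass-normalised (W/kg of biological mass) and percentage-of-total
    columns; ``total_w`` is P_tot (sum of the three overall joint means).
    """

    table: pd.DataFrame
    total_w: float
    mass_kg: float
    n_cycles: int

    def mean(self, joint: str, contributor: str = "overall") -> float:
        row = self.table[(self.table.joint == joint) & (self.table.contributor == contributor)]
        return float(row["power_w"].iloc[0])

    def percent(self, joint: str, contributor: str = "overall") -> float:
        row = self.table[(self.table.joint == joint) & (self.table.contributor == contributor)]
        return float(row["percent_of_total"].iloc[0])


def summarize(
    decomposition: KineticsDecomposition,
    cycles: HopCycleSet,
    mass: float,
    per_leg_powers: Optional[Dict[str, Dict[str, Dict[str, np.ndarray]]]] = None,
    n_cycles: int = 20,
) -> PowerSummary:
    """Cycle-averaged positive power per joint and contributor.

    If ``per_leg_powers`` is given (``{leg: {contributor: {joint: series}}}``),
    the positive-power integral is computed separately for each leg and
    then summed, mirroring force plates under each foot; otherwise the
    decomposition's series are treated as already-summed legs.  The last
    ``n_cycles`` complete cycles are analysed (all, if fewer).
    """
    if cycles.n_cycles < 1:
        raise ValueError("at least one complete hop cycle is required")
    if mass <= 0:
        raise ValueError("mass must be > 0")
    use = cycles.cycles[-n_cycles:] if n_cycles else cycles.cycles
    rate = cycles.rate

    def cycle_mean(series_by_leg) -> float:
        vals = []
        for cyc in use:
            vals.append(
                sum(average_positive_power(s, rate, cyc) for s in series_by_leg)
            )
        return float(np.mean(vals))

    means: Dict[str, Dict[str, float]] = {}
    for contrib in CONTRIBUTORS:
        means[contrib] = {}
        for joint in JOINTS:
            if per_leg_powers is not None:
                series = [per_leg_powers[leg][contrib][joint] for leg in per_leg_powers]
            else:
                series = [decomposition.contributor(contrib)[joint]]
            means[contrib][joint] = cycle_mean(series)

    total = sum(means["overall"][j] for j in JOINTS)
    rows = []
    for contrib in CONTRIBUTORS:
        for joint in JOINTS:
            p = means[contrib][joint]
            if total == 0:
                raise UndefinedDistributionError(
                    "total average positive power is zero; P%% undefined"
                )
            rows.append(
                {
                    "joint": joint,
                    "contributor": contrib,
                    "power_w": p,
                    "power_w_per_kg": p / mass,
                    "percent_of_total": 100.0 * p / total,
                }
            )
    return PowerSummary(
        table=pd.DataFrame(rows), total_w=total, mass_kg=mass, n_cycles=len(use)
    )
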