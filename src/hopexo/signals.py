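"""Filtering, resampling and hop-cycle segmentation.

Marker and ground-reaction-force streams are low-pass filtered with a
zero-phase (forward–backward) Butterworth filter — effective 4th order at a
20 Hz cut-off by default, the biomechanics norm — before any
differentiation.  Ground contact events are detected with a 20 N vertical
GRF threshold, and hop cycles run from one contact onset to the next
(contact phase + following aerial phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "HopCycleSet",
    "lowpass",
    "lowpass_series",
    "detect_contacts",
    "resample_to",
    "time_normalize",
]


class SignalValidationError(ValueError):
    pass


@dataclass
class TimeSeries:
    """Uniformly sampled channel matrix."""

    time: np.ndarray          # (n,) s, strictly increasing, uniform
    values: np.ndarray        # (n,) or (n, k)
    rate: float               # Hz
    names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.values.shape[0]:
            raise SignalValidationError("time and values lengths disagree")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise SignalValidationError("time must be strictly increasing")
        if dt.size and np.max(np.abs(dt - 1.0 / self.rate)) > 1e-9:
            raise SignalValidationError("sample spacing does not match rate")


@dataclass
class HopCycleSet:
    """Contact events and complete hop cycles, as sample indices.

    A cycle is the half-open index range [onset_i, onset_{i+1}); it
    contains exactly one contact phase and the following aerial phase.
    """

    contact_onsets: np.ndarray
    toe_offs: np.ndarray
    cycles: list  # list[(start, stop)] half-open
    rate: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def aerial_fractions(self) -> np.ndarray:
        fr = []
        for (s, e), off in zip(self.cycles, self.toe_offs):
            fr.append((e - off) / (e - s))
        return np.asarray(fr)

    def contact_times(self) -> np.ndarray:
        return np.asarray(
            [(off - s) / self.rate for (s, _), off in zip(self.cycles, self.toe_offs)]
        )

    def cycle_durations(self) -> np.ndarray:
        return np.asarray([(e - s) / self.rate for s, e in self.cycles])

    def scaled_to(self, rate: float) -> "HopCycleSet":
        """Map events onto another uniform clock sharing the time origin."""
        r = rate / self.rate
        on = np.round(self.contact_onsets * r).astype(int)
        off = np.round(self.toe_offs * r).astype(int)
        cyc = [(int(round(s * r)), int(round(e * r))) for s, e in self.cycles]
        return HopCycleSet(on, off, cyc, rate)


def lowpass(x: np.ndarray, cutoff_hz: float, rate: float, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of effective ``order``.

    Realised as two passes (filtfilt) of an order/2 filter, so the stated
    order is the effective order and the gain at the cut-off is 0.5.
    Edges are handled by odd-reflection padding of >= 3 filter lengths.
    """
    if cutoff_hz >= rate / 2:
        raise SignalValidationError("cutoff must be below the Nyquist frequency")
    if cutoff_hz <= 0:
        raise SignalValidationError("cutoff must be > 0")
    if order < 2 or order % 2:
        raise SignalValidationError("order must be a positive even integer")
    x = np.asarray(x, dtype=float)
    b, a = sps.butter(order // 2, cutoff_hz / (rate / 2.0))
    padlen = min(x.shape[0] - 1, max(int(3 * rate / cutoff_hz), 3 * max(len(a), len(b))))
    return sps.filtfilt(b, a, x, axis=0, padtype="odd", padlen=padlen)


def lowpass_series(series: TimeSeries, cutoff_hz: float, order: int = 4) -> TimeSeries:
    return TimeSeries(
        series.time, lowpass(series.values, cutoff_hz, series.rate, order),
        series.rate, series.names,
    )


def detect_contacts(
    vgrf: np.ndarray,
    rate: float,
    threshold_n: float = 20.0,
    debounce_s: float = 0.010,
) -> HopCycleSet:
    """Segment a vertical-GRF trace into hop cycles.

    Contact onset is the first sample >= threshold following a
    sub-threshold run; toe-off is the first sample < threshold following
    contact.  Contact or aerial runs shorter than the debounce window are
    discarded (merged), and partial first/last cycles are dropped.  If no
    complete cycle exists, an empty HopCycleSet is returned.
    """
    if threshold_n <= 0:
        raise SignalValidationError("threshold must be > 0")
    v = np.asarray(vgrf, dtype=float).ravel()
    above = v >= threshold_n
    if not above.any():
        return HopCycleSet(np.array([], int), np.array([], int), [], rate)

    debounce = max(1, int(round(debounce_s * rate)))
    # run-length encode
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, above.size]
    states = above[starts]
    # merge runs shorter than the debounce window into their neighbours
    # (interior runs only; boundary runs are handled by partial-cycle drop)
    keep_states, keep_starts, keep_ends = [], [], []
    for st, s, e in zip(states, starts, ends):
        if keep_states and (e - s) < debounce and 0 < s and e < above.size:
            # absorb the short run into the previous state
            keep_ends[-1] = e
            continue
        if keep_states and keep_states[-1] == st:
            keep_ends[-1] = e
            continue
        keep_states.append(st)
        keep_starts.append(s)
        keep_ends.append(e)
    # re-merge identical neighbours created by absorption
    states2, starts2, ends2 = [], [], []
    for st, s, e in zip(keep_states, keep_starts, keep_ends):
        if states2 and states2[-1] == st:
            ends2[-1] = e
        else:
            states2.append(st)
            starts2.append(s)
            ends2.append(e)

    onsets, toeoffs = [], []
    for st, s, e in zip(states2, starts2, ends2):
        if st:
            onsets.append(s)
            toeoffs.append(e)
    onsets = np.asarray(onsets, int)
    toeoffs = np.asarray(toeoffs, int)
    # a contact starting at sample 0 has no observed onset; drop it
    if onsets.size and onsets[0] == 0:
        onsets, toeoffs = onsets[1:], toeoffs[1:]
    # a trailing contact running to the end has no toe-off inside the data
    if toeoffs.size and toeoffs[-1] >= v.size:
        onsets, toeoffs = onsets[:-1], toeoffs[:-1]

    cycles = []
    cyc_offs = []
    for i in range(len(onsets) - 1):
        cycles.append((int(onsets[i]), int(onsets[i + 1])))
        cyc_offs.append(int(toeoffs[i]))
    return HopCycleSet(
        contact_onsets=onsets,
        toe_offs=np.asarray(cyc_offs, int) if cycles else np.array([], int),
        cycles=cycles,
        rate=rate,
    )


def resample_to(series: TimeSeries, target_rate: float) -> TimeSeries:
    """Integer-ratio decimation with zero-phase anti-alias filtering."""
    ratio = series.rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise SignalValidationError(
            f"rate ratio {series.rate}/{target_rate} is not a positive integer"
        )
    if q == 1:
        return series
    filtered = lowpass(series.values, 0.4 * target_rate, series.rate, order=8)
    return TimeSeries(series.time[::q], filtered[::q], target_rate, series.names)


def time_normalize(values: np.ndarray, cycle: tuple, n_points: int = 101) -> np.ndarray:
    """Linear interpolation of one cycle onto ``n_points`` spanning 0–100%.

    ``cycle`` is a half-open [start, stop) sample range; the right edge of
    the normalised axis is the first sample of the next cycle.
    """
    if n_points < 2:
        raise SignalValidationError("n_points must be >= 2")
    s, e = cycle
    v = np.asarray(values, dtype=float)
    if e - s < 2 or e > v.shape[0]:
        raise SignalValidationError("cycle range invalid for this series")
    x = np.arange(s, min(e + 1, v.shape[0]))
    xi = np.linspace(s, e if e < v.shape[0] else v.shape[0] - 1, n_points)
    if v.ndim == 1:
        return np.interp(xi, x, v[x[0]:x[-1] + 1])
    return np.column_stack(
        [np.interp(xi, x, v[x[0]:x[-1] + 1, j]) for j in range(v.shape[1])]
    )
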