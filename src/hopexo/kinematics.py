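"""Sagittal-plane joint angles and spatiotemporal summaries.

Angle conventions: joint angles are inter-segment angles in degrees where
an *increase* means extension (hip, knee) or plantarflexion (ankle); a 90
degree ankle angle is the anatomical reference (foot perpendicular to the
shank) and a straight knee is 180 degrees.  The pelvis is represented by
the global vertical through the hip marker (upright-trunk assumption of
this single-hip-marker sagittal marker set), so the hip angle is the angle
between the upward vertical and the thigh.

Angles are averaged over the two legs for reporting; with the mirrored
bilateral marker set of the synthetic hopper both legs share one marker
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .signals import HopCycleSet

__all__ = [
    "JointAngleSeries",
    "SpatiotemporalSummary",
    "joint_angles",
    "rom_and_peaks",
    "spatiotemporal",
    "JOINTS",
]

JOINTS = ("ankle", "knee", "hip")
G = 9.81  # m s^-2


class MissingLandmarkError(KeyError):
    pass


@dataclass
class JointAngleSeries:
    """Per-joint angle (deg) and angular velocity (rad/s, extension-positive)."""

    angles_deg: Dict[str, np.ndarray]
    angvel_rad: Dict[str, np.ndarray]
    rate: float


@dataclass
class SpatiotemporalSummary:
    hop_frequency_hz: float
    contact_time_s: float
    peak_vgrf_n: float
    hop_height_cm: float           # force-integration (Cavagna) route
    hop_height_flight_cm: float    # flight-time cross-check


def _angle_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Unsigned angle (deg) between per-sample 2-d vectors."""
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    c = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def joint_angles(markers: Dict[str, np.ndarray], rate: float) -> JointAngleSeries:
    """Ankle, knee and hip angles from sagittal marker trajectories.

    Requires the ``hip``, ``knee``, ``ankle`` and ``toe`` landmarks, each an
    (n, 2) array of (forward, up) coordinates in metres.
    """
    for name in ("hip", "knee", "ankle", "toe"):
        if name not in markers:
            raise MissingLandmarkError(f"required marker {name!r} is missing")
    hip = np.asarray(markers["hip"], float)
    knee = np.asarray(markers["knee"], float)
    ankle = np.asarray(markers["ankle"], float)
    toe = np.asarray(markers["toe"], float)

    up = np.zeros_like(hip)
    up[:, 1] = 1.0
    angles = {
        "hip": _angle_between(up, knee - hip),
        "knee": _angle_between(hip - knee, ankle - knee),
        "ankle": _angle_between(knee - ankle, toe - ankle),
    }
    dt = 1.0 / rate
    angvel = {j: np.gradient(np.radians(a), dt) for j, a in angles.items()}
    return JointAngleSeries(angles_deg=angles, angvel_rad=angvel, rate=rate)


def rom_and_peaks(series: JointAngleSeries, cycles: HopCycleSet) -> pd.DataFrame:
    """Cycle-averaged range of motion and peak flexion per joint.

    ROM is (max - min) within each hop cycle, then averaged across cycles;
    peak flexion is the per-cycle minimum angle (flexion decreases the
    angle under these conventions), averaged across cycles.
    """
    if cycles.n_cycles < 1:
        raise ValueError("at least one complete hop cycle is required")
    rows = []
    for joint in JOINTS:
        a = series.angles_deg[joint]
        roms, peaks = [], []
        for s, e in cycles.cycles:
            seg = a[s:e]
            roms.append(seg.max() - seg.min())
            peaks.append(seg.min())
        rows.append((joint, float(np.mean(roms)), float(np.mean(peaks))))
    return pd.DataFrame(rows, columns=["joint", "rom_deg", "peak_flexion_deg"])


def spatiotemporal(
    vgrf_summed: np.ndarray,
    cycles: HopCycleSet,
    mass: float,
    rate: Optional[float] = None,
) -> SpatiotemporalSummary:
    """Hop frequency, contact time, peak summed vGRF and hop height.

    Hop height follows the force-integration route: the net vertical
    acceleration (F/m - g) is integrated over each cycle with the
    integration constant fixed by stationarity (zero mean vertical
    velocity over the cycle); the takeoff velocity v gives h = v^2 / 2g.
    The ballistic flight-time route g*t_a^2/8 is reported as a
    cross-check.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    if cycles.n_cycles < 2:
        raise ValueError("at least two complete hop cycles are required")
    rate = rate or cycles.rate
    v = np.asarray(vgrf_summed, float).ravel()

    freq = 1.0 / float(np.mean(cycles.cycle_durations()))
    t_contact = float(np.mean(cycles.contact_times()))
    peaks = [float(v[s:e].max()) for s, e in cycles.cycles]

    dt = 1.0 / rate
    heights = []
    flight_heights = []
    for (s, e), off in zip(cycles.cycles, cycles.toe_offs):
        a = v[s:e] / mass - G
        vel = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) * 0.5 * dt)])
        vel -= vel.mean()  # stationarity: zero net displacement over the cycle
        v_to = vel[off - s]
        heights.append(v_to**2 / (2 * G) if v_to > 0 else 0.0)
        t_aerial = (e - off) * dt
        flight_heights.append(G * t_aerial**2 / 8.0)
    return SpatiotemporalSummary(
        hop_frequency_hz=freq,
        contact_time_s=t_contact,
        peak_vgrf_n=float(np.mean(peaks)),
        hop_height_cm=float(np.mean(heights)) * 100.0,
        hop_height_flight_cm=float(np.mean(flight_heights)) * 100.0,
    )


def hop_height_from_flight(t_aerial_s: float) -> float:
    """Ballistic rise (m) of the CoM apex above takeoff height."""
    return G * t_aerial_s**2 / 8.0
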