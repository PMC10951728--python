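"""End-to-end analysis of one hopping trial.

Chain: zero-phase low-pass filtering of markers and GRFs (20 Hz, effective
4th order) -> contact detection on the summed vertical GRF (20 N) -> GRF
decimation onto the 200 Hz marker clock (the analysis grid) -> joint
angles -> link-segment inverse dynamics per leg (overall moments/powers,
including the exoskeleton's weight) -> exoskeleton moment/power estimation
from the attachment markers and the spring law -> MTU residual ->
cycle-averaged positive-power summary and spatiotemporal outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import exo as exo_mod
from . import inverse_dynamics as id_mod
from .config import load_config
from .exo import ExoGeometry, KineticsDecomposition
from .hopper import HopTrial
from .kinematics import (
    JointAngleSeries,
    SpatiotemporalSummary,
    joint_angles,
    rom_and_peaks,
    spatiotemporal,
)
from .power import PowerSummary, summarize
from .signals import HopCycleSet, detect_contacts, lowpass, time_normalize

JOINTS = ("ankle", "knee", "hip")


@dataclass
class TrialResult:
    """Everything the per-trial analysis produces."""

    condition: str
    participant: Dict[str, float]
    cycles_marker: HopCycleSet
    cycles_grf: HopCycleSet
    angles: JointAngleSeries
    rom_peaks: pd.DataFrame
    spatiotemporal: SpatiotemporalSummary
    decomposition: KineticsDecomposition          # legs summed
    per_leg: Dict[str, KineticsDecomposition]
    power: PowerSummary
    exo_report: Optional[exo_mod.ExoPowerReport]
    contact_mask: np.ndarray                      # marker clock
    rate: float
    meta: Dict = field(default_factory=dict)

    def outcome_row(self) -> Dict[str, float]:
        """Flat per-trial outcome dict for cohort-level statistics."""
        mass = self.participant["mass"]
        row = {
            "condition": self.condition,
            "hop_frequency_hz": self.spatiotemporal.hop_frequency_hz,
            "contact_time_s": self.spatiotemporal.contact_time_s,
            "peak_vgrf_n": self.spatiotemporal.peak_vgrf_n,
            "hop_height_cm": self.spatiotemporal.hop_height_cm,
            "total_avg_pos_power_w_per_kg": self.power.total_w / mass,
        }
        for _, r in self.rom_peaks.iterrows():
            row[f"rom_{r.joint}_deg"] = r.rom_deg
            row[f"peak_flexion_{r.joint}_deg"] = r.peak_flexion_deg
        use = self.cycles_marker.cycles[-self.power.n_cycles:]
        for j in JOINTS:
            m_mtu = self.decomposition.moments_mtu[j]
            vals = [np.mean(m_mtu[s:e]) for s, e in use]
            row[f"mtu_avg_moment_{j}_nm_per_kg"] = float(np.mean(vals)) / mass
            for contrib in ("overall", "exo", "mtu"):
                row[f"{contrib}_avg_pos_power_{j}_w_per_kg"] = (
                    self.power.mean(j, contrib) / mass
                )
                row[f"percent_{contrib}_{j}"] = self.power.percent(j, contrib)
        return row

    def normalized_curves(self, n_points: int = 101) -> pd.DataFrame:
        """Cycle-mean time-normalised moment/power curves per joint and
        contributor (legs summed)."""
        use = self.cycles_marker.cycles
        rows = []
        pct = np.linspace(0.0, 100.0, n_points)
        for quantity in ("moments", "powers"):
            for contrib in ("overall", "exo", "mtu"):
                series = getattr(self.decomposition, f"{quantity}_{contrib}")
                for j in JOINTS:
                    curves = np.stack(
                        [time_normalize(series[j], cyc, n_points) for cyc in use]
                    )
                    mean_curve = curves.mean(axis=0)
                    for p, v in zip(pct, mean_curve):
                        rows.append(
                            {"quantity": quantity, "contributor": contrib,
                             "joint": j, "percent_cycle": p, "value": v}
                        )
        return pd.DataFrame(rows)


def _decimate_to_marker_clock(x: np.ndarray, grf_rate: float, marker_rate: float,
                              n_marker: int) -> np.ndarray:
    q = int(round(grf_rate / marker_rate))
    out = x[::q]
    return out[:n_marker]


def analyze_trial(trial: HopTrial, config: Optional[dict] = None) -> TrialResult:
    """Run the full joint-mechanics chain on one trial."""
    cfg = config or load_config()
    cutoff = cfg["filter"]["cutoff_hz"]
    order = cfg["filter"]["order"]
    thr = cfg["contact"]["threshold_n"]
    debounce = cfg["contact"]["debounce_s"]
    n_cycles = cfg["analysis"]["n_cycles"]

    m_rate = trial.marker_rate
    g_rate = trial.grf_rate
    n_m = next(iter(trial.markers.values())).shape[0]

    markers_f = {
        name: lowpass(xy, cutoff, m_rate, order) for name, xy in trial.markers.items()
    }
    grf_f = {}
    for leg, df in trial.grf.items():
        grf_f[leg] = {
            "fz": lowpass(df["fz_N"].to_numpy(), cutoff, g_rate, order),
            "fx": lowpass(df["fx_N"].to_numpy(), cutoff, g_rate, order),
            "cop": df["cop_x_m"].to_numpy(),
        }
    vgrf_sum = sum(g["fz"] for g in grf_f.values())

    cycles_g = detect_contacts(vgrf_sum, g_rate, thr, debounce)
    cycles_m = cycles_g.scaled_to(m_rate)

    vgrf_sum_m = _decimate_to_marker_clock(vgrf_sum, g_rate, m_rate, n_m)
    contact_mask = vgrf_sum_m >= thr
    # The threshold crossing sits inside the true contact (the GRF pulse
    # needs ~10 ms to exceed 20 N), and a high-initial-stiffness spring
    # already carries substantial force there; null the spring only in the
    # interior of aerial phases, beyond a short guard around each event.
    guard = int(round(cfg["contact"].get("exo_guard_s", 0.025) * m_rate))
    if guard > 0:
        kernel = np.ones(2 * guard + 1, dtype=int)
        exo_mask = np.convolve(contact_mask.astype(int), kernel, mode="same") > 0
    else:
        exo_mask = contact_mask

    angles = joint_angles(markers_f, m_rate)

    seg_lengths = {
        "thigh": float(np.median(np.linalg.norm(markers_f["knee"] - markers_f["hip"], axis=1))),
        "shank": float(np.median(np.linalg.norm(markers_f["ankle"] - markers_f["knee"], axis=1))),
        "foot": float(np.median(np.linalg.norm(markers_f["toe"] - markers_f["ankle"], axis=1))),
    }
    params = id_mod.segment_parameters(
        trial.participant["mass"], seg_lengths,
        table_id=cfg["inverse_dynamics"]["anthropometry_table"],
        exo_leg_mass=trial.exo_leg_mass,
        exo_foot_split=cfg["inverse_dynamics"]["exo_foot_split"],
    )

    exo_foot = markers_f.get("exo_foot")
    per_leg: Dict[str, KineticsDecomposition] = {}
    per_leg_powers: Dict[str, Dict[str, Dict[str, np.ndarray]]] = {}
    for leg, g in grf_f.items():
        fz = _decimate_to_marker_clock(g["fz"], g_rate, m_rate, n_m)
        fx = _decimate_to_marker_clock(g["fx"], g_rate, m_rate, n_m)
        cop = _decimate_to_marker_clock(g["cop"], g_rate, m_rate, n_m)
        overall = id_mod.inverse_dynamics(
            angles, markers_f, np.column_stack([fx, fz]), cop, params,
            contact_mask=contact_mask, exo_foot_attach=exo_foot,
        )
        if trial.spring is not None:
            geometry = ExoGeometry(
                hip_attach=markers_f["exo_hip"], foot_attach=markers_f["exo_foot"],
                rest_length=trial.spring.rest_length
                or exo_mod.estimate_rest_length(
                    np.linalg.norm(markers_f["exo_foot"] - markers_f["exo_hip"], axis=1),
                    contact_mask,
                ),
            )
            exo_kin = exo_mod.exo_joint_kinetics(
                geometry, trial.spring,
                {j: markers_f[j] for j in JOINTS},
                angles.angvel_rad, contact_mask=exo_mask,
            )
        else:
            geometry = None
            exo_kin = exo_mod.zero_exo_kinetics(n_m)
        per_leg[leg] = exo_mod.decompose(overall.moments, overall.powers, exo_kin)
        per_leg_powers[leg] = {
            c: per_leg[leg].contributor(c) for c in ("overall", "exo", "mtu")
        }

    legs = list(per_leg)
    summed = KineticsDecomposition(
        **{
            f"{q}_{c}": {
                j: sum(getattr(per_leg[leg], f"{q}_{c}")[j] for leg in legs)
                for j in JOINTS
            }
            for q in ("moments", "powers")
            for c in ("overall", "exo", "mtu")
        }
    )

    if cycles_m.n_cycles < 1:
        raise ValueError("no complete hop cycles detected in this trial")

    power = summarize(
        summed, cycles_m, trial.participant["mass"],
        per_leg_powers=per_leg_powers, n_cycles=n_cycles,
    )
    total_mass = trial.participant["mass"] + 2 * trial.exo_leg_mass
    st = spatiotemporal(vgrf_sum, cycles_g, total_mass)
    rp = rom_and_peaks(angles, cycles_m)

    exo_report = None
    if trial.spring is not None and geometry is not None:
        # audit against the spring's own delivery (legs are mirrored, so a
        # single-leg geometry audit covers both)
        d = exo_mod.spring_displacement(geometry)
        d = np.where(exo_mask, d, 0.0)
        from .springs import spring_force_branched

        f = spring_force_branched(trial.spring, d, exo_mod.loading_mask(d))
        exo_report = exo_mod.exo_power_check(
            per_leg[legs[0]].powers_exo, f, geometry.attachment_distance(),
            cycles_m, m_rate,
        )

    return TrialResult(
        condition=trial.condition,
        participant=dict(trial.participant),
        cycles_marker=cycles_m,
        cycles_grf=cycles_g,
        angles=angles,
        rom_peaks=rp,
        spatiotemporal=st,
        decomposition=summed,
        per_leg=per_leg,
        power=power,
        exo_report=exo_report,
        contact_mask=contact_mask,
        rate=m_rate,
        meta=dict(trial.meta),
    )


def cohort_outcomes(results, participant_ids=None) -> pd.DataFrame:
    """Stack per-trial outcome rows into a long cohort table."""
    rows = []
    for i, res in enumerate(results):
        row = res.outcome_row()
        row["participant"] = (
            participant_ids[i] if participant_ids is not None
            else res.meta.get("participant_id", i)
        )
        rows.append(row)
    return pd.DataFrame(rows)
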