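"""Planar link-segment inverse dynamics of the hopping leg.

Bottom-up Newton–Euler over foot -> shank -> thigh in the sagittal plane:
each segment's proximal joint reaction force and net joint moment follow
from the segment's linear and angular accelerations, gravity, and the
loads applied distally (the ground reaction force at the centre of
pressure for the foot; the already-solved joint reaction for the others).
Net moments are reported in the extensor/plantarflexor-positive convention
(see `hopexo.exo` for the sign truth table) and joint power is the product
of the net moment and the joint's angular velocity, so P = M * omega holds
at every sample.

The weight of the exoskeleton is carried as point masses: half of each exo
leg's mass rides at the foot attachment (entering the foot segment's
equations as an inertial + gravitational load) and half at the hip
attachment on the pelvis, which sits proximal to every leg joint and
therefore never enters the bottom-up pass.  Segment inertial parameters
come from a versioned anthropometric table (Winter-style fractions by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import numpy as np
import yaml

from .exo import EXTENSOR_SIGN
from .kinematics import JointAngleSeries

G = 9.81
JOINTS = ("ankle", "knee", "hip")

__all__ = ["SegmentParams", "JointKinetics", "segment_parameters", "inverse_dynamics"]


class AnthropometryError(ValueError):
    pass


def _load_tables() -> dict:
    with resources.files("hopexo.data").joinpath("anthropometry.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class SegmentParams:
    """Per-segment inertial parameters for one leg."""

    masses: Dict[str, float]          # kg
    com_fracs: Dict[str, float]       # from proximal end
    gyration_fracs: Dict[str, float]  # about the CoM
    lengths: Dict[str, float]         # m
    table_id: str
    exo_point_mass: float = 0.0       # kg at the foot attachment

    def moment_of_inertia(self, segment: str) -> float:
        return self.masses[segment] * (
            self.gyration_fracs[segment] * self.lengths[segment]
        ) ** 2


def segment_parameters(
    mass: float,
    segment_lengths: Dict[str, float],
    table_id: str = "winter",
    exo_leg_mass: float = 0.0,
    exo_foot_split: float = 0.5,
) -> SegmentParams:
    """Inertial parameters of one leg from an anthropometric table.

    ``exo_leg_mass`` adds one exoskeleton leg's mass as point masses,
    split ``exo_foot_split`` at the foot attachment (the remainder at the
    hip attachment on the pelvis, which does not load the leg joints).
    """
    if mass <= 0:
        raise AnthropometryError("mass must be > 0")
    tables = _load_tables()
    if table_id not in tables:
        raise AnthropometryError(f"unknown anthropometric table {table_id!r}")
    table = tables[table_id]
    for seg in ("foot", "shank", "thigh"):
        if seg not in segment_lengths or segment_lengths[seg] <= 0:
            raise AnthropometryError(f"segment length for {seg!r} missing or <= 0")
    return SegmentParams(
        masses={s: table[s]["mass_frac"] * mass for s in table},
        com_fracs={s: table[s]["com_frac"] for s in table},
        gyration_fracs={s: table[s]["gyration_frac"] for s in table},
        lengths=dict(segment_lengths),
        table_id=table_id,
        exo_point_mass=exo_leg_mass * exo_foot_split,
    )


@dataclass
class JointKinetics:
    """Net (overall) joint moments and powers for one leg.

    Extensor/plantarflexor-positive; ``P = M * omega`` per sample.
    """

    moments: Dict[str, np.ndarray]   # N m
    powers: Dict[str, np.ndarray]    # W
    rate: float


def _derivatives(x: np.ndarray, dt: float, order: int = 2) -> np.ndarray:
    out = x
    for _ in range(order):
        out = np.gradient(out, dt, axis=0)
    return out


def inverse_dynamics(
    angles: JointAngleSeries,
    markers: Dict[str, np.ndarray],
    grf: np.ndarray,
    cop_x: np.ndarray,
    params: SegmentParams,
    contact_mask: Optional[np.ndarray] = None,
    exo_foot_attach: Optional[np.ndarray] = None,
) -> JointKinetics:
    """Overall joint moments and powers of one leg.

    ``grf`` is (n, 2) per-leg (fx, fz) on the analysis clock; ``cop_x``
    the centre-of-pressure forward coordinate (ground height 0).  The GRF
    is applied only where ``contact_mask`` is true (everywhere if None).
    ``exo_foot_attach`` is the foot-attachment trajectory carrying the
    distal exoskeleton point mass.
    """
    rate = angles.rate
    dt = 1.0 / rate
    n = markers["ankle"].shape[0]
    grf = np.asarray(grf, float)
    fvec = grf.copy()
    if contact_mask is not None:
        fvec[~np.asarray(contact_mask, bool)] = 0.0
    cop = np.column_stack([np.asarray(cop_x, float), np.zeros(n)])

    # centre-of-pressure plausibility: should lie within the foot's
    # ground-plane footprint during contact
    if contact_mask is not None and contact_mask.any():
        heel = markers.get("heel", markers["ankle"])
        lo = np.minimum(heel[:, 0], markers["toe"][:, 0]) - 0.05
        hi = np.maximum(heel[:, 0], markers["toe"][:, 0]) + 0.05
        m = np.asarray(contact_mask, bool)
        if np.any((cop[m, 0] < lo[m]) | (cop[m, 0] > hi[m])):
            warnings.warn("centre of pressure outside the foot segment during contact")

    g_vec = np.array([0.0, -G])
    segments = (
        ("foot", "ankle", "toe"),
        ("shank", "knee", "ankle"),
        ("thigh", "hip", "knee"),
    )

    # load applied ON the current segment at its distal end: the GRF for
    # the foot, minus the previously solved proximal reaction afterwards
    dist_load = fvec
    dist_point = cop
    dist_load_moment = np.zeros(n)

    moments_ccw: Dict[str, np.ndarray] = {}
    for seg, prox_joint, dist_joint in segments:
        prox = np.asarray(markers[prox_joint], float)
        dist = np.asarray(markers[dist_joint], float)
        com = prox + params.com_fracs[seg] * (dist - prox)
        a_com = _derivatives(com, dt)
        seg_vec = dist - prox
        theta = np.unwrap(np.arctan2(seg_vec[:, 1], seg_vec[:, 0]))
        alpha = _derivatives(theta[:, None], dt)[:, 0]
        m_seg = params.masses[seg]
        I_seg = params.moment_of_inertia(seg)

        ext_forces = [(dist_load, dist_point)]
        if seg == "foot" and params.exo_point_mass > 0 and exo_foot_attach is not None:
            att = np.asarray(exo_foot_attach, float)
            a_att = _derivatives(att, dt)
            f_pt = -params.exo_point_mass * (a_att - g_vec)  # load from the point mass
            ext_forces.append((f_pt, att))

        f_ext_sum = sum(f for f, _ in ext_forces)
        r_prox = m_seg * a_com - m_seg * g_vec - f_ext_sum   # proximal joint force

        m_prox = I_seg * alpha
        rp = prox - com
        m_prox -= rp[:, 0] * r_prox[:, 1] - rp[:, 1] * r_prox[:, 0]
        for f, p in ext_forces:
            rd = p - com
            m_prox -= rd[:, 0] * f[:, 1] - rd[:, 1] * f[:, 0]
        m_prox -= dist_load_moment

        moments_ccw[prox_joint] = m_prox
        dist_load = -r_prox           # reaction onto the next segment
        dist_point = prox
        dist_load_moment = -m_prox

    moments = {j: EXTENSOR_SIGN[j] * moments_ccw[j] for j in JOINTS}
    powers = {j: moments[j] * angles.angvel_rad[j] for j in JOINTS}
    return JointKinetics(moments=moments, powers=powers, rate=rate)


def statics_moments(
    markers: Dict[str, np.ndarray],
    grf: np.ndarray,
    cop_x: np.ndarray,
    params: SegmentParams,
    exo_foot_attach: Optional[np.ndarray] = None,
) -> Dict[str, np.ndarray]:
    """Zero-acceleration joint moments (independent statics oracle).

    For each joint, the moment of the GRF about the joint plus the
    gravitational moments of the segments (and exo point mass) distal to
    it, signed into the extensor-positive convention.
    """
    n = markers["ankle"].shape[0]
    grf = np.asarray(grf, float)
    cop = np.column_stack([np.asarray(cop_x, float), np.zeros(n)])
    distal_segments = {
        "ankle": ["foot"],
        "knee": ["foot", "shank"],
        "hip": ["foot", "shank", "thigh"],
    }
    seg_ends = {"foot": ("ankle", "toe"), "shank": ("knee", "ankle"),
                "thigh": ("hip", "knee")}
    out = {}
    for joint in JOINTS:
        jpos = np.asarray(markers[joint], float)
        r = cop - jpos
        tau = r[:, 0] * grf[:, 1] - r[:, 1] * grf[:, 0]
        for seg in distal_segments[joint]:
            prox, dist = seg_ends[seg]
            com = markers[prox] + params.com_fracs[seg] * (
                np.asarray(markers[dist], float) - np.asarray(markers[prox], float)
            )
            rc = com - jpos
            tau += rc[:, 0] * (-params.masses[seg] * G)
        if exo_foot_attach is not None and params.exo_point_mass > 0:
            rc = np.asarray(exo_foot_attach, float) - jpos
            tau += rc[:, 0] * (-params.exo_point_mass * G)
        out[joint] = -EXTENSOR_SIGN[joint] * tau
    return out
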