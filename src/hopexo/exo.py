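"""Exoskeleton contribution to joint moments and powers, and the MTU residual.

The passive exoskeleton 'leg' is a spring between a hip attachment (on the
waist harness) and a foot attachment (on the shoe, near the
metatarsal-phalangeal joint).  Both attachments are low-friction pin
joints, so the spring force is purely axial along the line through the two
attachment markers.  Per joint, the exoskeleton moment is the force times
the perpendicular distance from the joint centre to that line, signed into
the extensor/plantarflexor-positive convention; the exoskeleton power is
that moment times the joint's angular velocity.  The muscle–tendon-unit
(MTU) contribution is the residual:

    M_mtu = M_overall - M_exo,    P_mtu = P_overall - P_exo,

sample by sample.

Sign truth table.  With x forward, y up and the leg facing +x, let
tau = cross(foot_attachment - joint, F_exo) be the out-of-plane moment of
the axial force (directed hip->foot, i.e. the push of the compressed
spring on the distal side), taken about each joint.  An *increase* of the
inter-segment joint angle is extension (hip, knee) or plantarflexion
(ankle), and the knee flexes posteriorly while the hip and ankle flex
anteriorly, so the mapping from tau (counter-clockwise positive) onto the
extension-positive convention is

    ankle: -tau    knee: +tau    hip: -tau

the same mapping used for the net inverse-dynamics moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .springs import SpringProfile, spring_force_branched

__all__ = [
    "EXTENSOR_SIGN",
    "ExoGeometry",
    "KineticsDecomposition",
    "ExoPowerReport",
    "loading_mask",
    "spring_displacement",
    "moment_arm",
    "exo_joint_kinetics",
    "decompose",
    "exo_power_check",
]

JOINTS = ("ankle", "knee", "hip")

#: Mapping from counter-clockwise moments (leg facing +x) to the
#: extensor/plantarflexor-positive convention.
EXTENSOR_SIGN = {"ankle": -1.0, "knee": 1.0, "hip": -1.0}


class ExoValidationError(ValueError):
    pass


class DegenerateGeometryError(ExoValidationError):
    pass


@dataclass
class ExoGeometry:
    """Attachment trajectories and the spring's rest length."""

    hip_attach: np.ndarray    # (n, 2) m
    foot_attach: np.ndarray   # (n, 2) m
    rest_length: float        # m

    def __post_init__(self) -> None:
        self.hip_attach = np.asarray(self.hip_attach, float)
        self.foot_attach = np.asarray(self.foot_attach, float)
        if self.hip_attach.shape != self.foot_attach.shape:
            raise ExoValidationError("attachment trajectories must have equal shapes")

    def attachment_distance(self) -> np.ndarray:
        return np.linalg.norm(self.foot_attach - self.hip_attach, axis=1)

    def line_of_action(self):
        """Per-sample unit direction hip->foot attachment."""
        vec = self.foot_attach - self.hip_attach
        L = np.linalg.norm(vec, axis=1)
        if np.any(L < 1e-9):
            raise DegenerateGeometryError("coincident exoskeleton attachments")
        return vec / L[:, None]


def spring_displacement(geometry: ExoGeometry) -> np.ndarray:
    """Spring compression d(t) = max(0, L0 - attachment distance).

    The compression plates cannot stretch the spring, so displacement is
    clamped at zero when the attachments are farther apart than the rest
    length.
    """
    if geometry.rest_length <= 0:
        raise ExoValidationError("rest_length must be > 0")
    return np.clip(geometry.rest_length - geometry.attachment_distance(), 0.0, None)


def estimate_rest_length(geometry_distance: np.ndarray, contact_mask: np.ndarray) -> float:
    """Rest length from the aerial-phase attachment distance (the spring is
    slack whenever the leg is airborne)."""
    aerial = ~np.asarray(contact_mask, bool)
    if not aerial.any():
        raise ExoValidationError("no aerial samples to estimate the rest length from")
    return float(np.mean(np.asarray(geometry_distance)[aerial]))


def loading_mask(displacement: np.ndarray, rate: Optional[float] = None,
                 tol: float = 1e-12) -> np.ndarray:
    """True where the spring is on its loading branch.

    Loading while the compression increases, unloading while it decreases;
    where the rate is (numerically) zero, the previous branch is held.
    Starts on the loading branch.
    """
    d = np.asarray(displacement, float)
    rate_d = np.gradient(d) if d.size > 1 else np.zeros_like(d)
    mask = np.empty(d.size, dtype=bool)
    current = True
    for i in range(d.size):
        if rate_d[i] > tol:
            current = True
        elif rate_d[i] < -tol:
            current = False
        mask[i] = current
    return mask


def moment_arm(joint_centre: np.ndarray, geometry: ExoGeometry):
    """Perpendicular distance from a joint centre to the line of action.

    Returns ``(arm, side)`` where ``arm`` >= 0 and ``side`` is the sign of
    the out-of-plane cross product of (joint->foot attachment) with the
    line direction: +1 when the line passes such that the axial push turns
    the distal side counter-clockwise about the joint, -1 otherwise, 0 on
    the line.
    """
    u = geometry.line_of_action()
    r = geometry.foot_attach - np.asarray(joint_centre, float)
    cross = r[:, 0] * u[:, 1] - r[:, 1] * u[:, 0]
    return np.abs(cross), np.sign(cross)


@dataclass
class KineticsDecomposition:
    """Per-joint overall / exoskeleton / MTU moments (N m) and powers (W),
    per leg; ``summed`` variants add the two legs."""

    moments_overall: Dict[str, np.ndarray]
    moments_exo: Dict[str, np.ndarray]
    moments_mtu: Dict[str, np.ndarray]
    powers_overall: Dict[str, np.ndarray]
    powers_exo: Dict[str, np.ndarray]
    powers_mtu: Dict[str, np.ndarray]

    def contributor(self, which: str, quantity: str = "powers") -> Dict[str, np.ndarray]:
        return getattr(self, f"{quantity}_{which}")


def exo_joint_kinetics(
    geometry: ExoGeometry,
    profile: SpringProfile,
    joint_centres: Dict[str, np.ndarray],
    angular_velocities: Dict[str, np.ndarray],
    contact_mask: Optional[np.ndarray] = None,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-joint exoskeleton moments and powers from attachment geometry.

    The spring force follows the profile's loading branch while the
    compression grows and the unloading branch while it recoils; the force
    and all derived moments are zero outside ground contact (and wherever
    the compression is zero).  Returns ``{"moments": ..., "powers": ...,
    "force": ..., "displacement": ...}``.
    """
    if profile is None:
        raise ExoValidationError("an exoskeleton condition requires a spring profile")
    d = spring_displacement(geometry)
    if contact_mask is not None:
        d = np.where(np.asarray(contact_mask, bool), d, 0.0)
    f = spring_force_branched(profile, d, loading_mask(d))
    u = geometry.line_of_action()
    moments, powers = {}, {}
    for joint in JOINTS:
        r = geometry.foot_attach - np.asarray(joint_centres[joint], float)
        cross = r[:, 0] * u[:, 1] - r[:, 1] * u[:, 0]
        m = EXTENSOR_SIGN[joint] * cross * f
        moments[joint] = m
        powers[joint] = m * np.asarray(angular_velocities[joint], float)
    return {"moments": moments, "powers": powers, "force": f, "displacement": d}


def zero_exo_kinetics(n: int) -> Dict[str, Dict[str, np.ndarray]]:
    """Null exoskeleton contribution (NH condition)."""
    z = {j: np.zeros(n) for j in JOINTS}
    return {
        "moments": z,
        "powers": {j: np.zeros(n) for j in JOINTS},
        "force": np.zeros(n),
        "displacement": np.zeros(n),
    }


def decompose(
    moments_overall: Dict[str, np.ndarray],
    powers_overall: Dict[str, np.ndarray],
    exo_kinetics: Dict[str, Dict[str, np.ndarray]],
) -> KineticsDecomposition:
    """MTU = overall - exoskeleton, sample by sample (per joint, moment and
    power)."""
    m_exo = exo_kinetics["moments"]
    p_exo = exo_kinetics["powers"]
    for j in JOINTS:
        if moments_overall[j].shape != m_exo[j].shape:
            raise ExoValidationError("overall and exo series are misaligned")
    return KineticsDecomposition(
        moments_overall={j: np.asarray(moments_overall[j], float) for j in JOINTS},
        moments_exo={j: np.asarray(m_exo[j], float) for j in JOINTS},
        moments_mtu={j: np.asarray(moments_overall[j], float) - m_exo[j] for j in JOINTS},
        powers_overall={j: np.asarray(powers_overall[j], float) for j in JOINTS},
        powers_exo={j: np.asarray(p_exo[j], float) for j in JOINTS},
        powers_mtu={j: np.asarray(powers_overall[j], float) - p_exo[j] for j in JOINTS},
    )


@dataclass
class ExoPowerReport:
    """Per-cycle audit that the estimated per-joint assistance does not
    exceed what the spring itself delivered."""

    joint_positive_power: np.ndarray   # per cycle, summed across joints, W
    spring_positive_power: np.ndarray  # per cycle, W
    rel_tol: float
    violations: np.ndarray             # boolean per cycle (diagnostic)

    @property
    def passed(self) -> bool:
        """Trial-level verdict: the cycle-mean joint assistance must not
        exceed the cycle-mean spring delivery (marker noise makes single
        cycles fluctuate both ways; the audit is per trial)."""
        j = float(np.mean(self.joint_positive_power))
        s = float(np.mean(self.spring_positive_power))
        return j <= s + self.rel_tol * max(s, 1e-9) + 1e-9


def exo_power_check(
    exo_powers: Dict[str, np.ndarray],
    force: np.ndarray,
    attachment_distance: np.ndarray,
    cycles,
    rate: float,
    rel_tol: float = 0.01,
) -> ExoPowerReport:
    """Check sum-of-joints exo positive power against spring delivery.

    The spring's delivered power is F * dL/dt (positive while the
    attachments recoil apart); in the continuum the per-joint exoskeleton
    powers sum to exactly that, so the summed per-joint average positive
    power can exceed the spring's only through estimation error.
    ``rel_tol`` absorbs the finite-difference discretisation of the two
    velocity estimates.
    """
    from .power import average_positive_power  # local import; no cycle at module load

    L_rate = np.gradient(np.asarray(attachment_distance, float), 1.0 / rate)
    spring_power = np.asarray(force, float) * L_rate
    joint_vals, spring_vals = [], []
    for cyc in cycles.cycles:
        joint_vals.append(
            sum(average_positive_power(exo_powers[j], rate, cyc) for j in JOINTS)
        )
        spring_vals.append(average_positive_power(spring_power, rate, cyc))
    joint_vals = np.asarray(joint_vals)
    spring_vals = np.asarray(spring_vals)
    scale = np.maximum(spring_vals, 1e-9)
    violations = joint_vals > spring_vals + rel_tol * scale + 1e-9
    return ExoPowerReport(
        joint_positive_power=joint_vals,
        spring_positive_power=spring_vals,
        rel_tol=rel_tol,
        violations=violations,
    )
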