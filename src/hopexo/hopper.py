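"""Synthetic stationary bilateral hopping trials with ground truth.

The generator emulates hopping in place at 2.4 Hz: the summed vertical
ground reaction force during contact is a pulse

    F(t) = F_peak * sin(pi * t / t_c) ** gamma,

with F_peak fixed by impulse balance (mean force over a full cycle equals
body weight), the centre of mass follows from twice-integrating
(F/m - g), and the sagittal leg posture is a one-parameter family that
distributes the leg-length change over ankle, knee and hip by configurable
weights.  Markers come from forward kinematics about the fixed toe contact
point; legs are mirrored (per-leg GRF is half the summed pulse, centre of
pressure at the toe — forefoot contact).  An optional exoskeleton 'leg'
compresses along the hip-attachment-to-foot-attachment line, with the
spring law evaluated analytically into the emitted ground truth.

The point-mass construction guarantees kinematic/kinetic consistency
without a forward-dynamics solver; segment inertial effects are neglected
in generation, which downstream overall-moment checks absorb with a
documented tolerance (exoskeleton-geometry checks are exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn

from .springs import (
    CONDITION_CODES,
    SpringProfile,
    profile_for_condition,
    spring_force_branched,
    with_rest_length,
)
from .exo import EXTENSOR_SIGN, loading_mask

G = 9.81

__all__ = [
    "ExoConfig",
    "HopperParams",
    "HopTrial",
    "GroundTruth",
    "simulate_trial",
    "simulate_quasistatic_trial",
    "emit_cohort",
    "peak_vgrf_half_sine",
]


class HopperValidationError(ValueError):
    pass


class InfeasibleGeometryError(HopperValidationError):
    pass


@dataclass(frozen=True)
class ExoConfig:
    """Exoskeleton 'leg': per-leg spring profile plus attachment geometry.

    ``hip_offset`` is the hip-attachment position relative to the hip
    joint centre in world axes (the waist mount rides on the pelvis,
    assumed upright); ``foot_offset`` is the foot-attachment position in
    the foot frame (x along ankle->toe, y its left-hand normal, i.e.
    upward out of the shoe plate).  ``leg_mass`` (kg) is the mass of one
    exoskeleton leg.
    """

    profile: SpringProfile
    hip_offset: Tuple[float, float] = (0.0, 0.0)
    foot_offset: Tuple[float, float] = (0.0, 0.02)
    leg_mass: float = 1.0


@dataclass(frozen=True)
class HopperParams:
    mass: float = 66.0                 # kg, biological
    leg_length: float = 0.90           # m, greater trochanter to floor
    thigh: float = 0.42                # m
    shank: float = 0.40                # m
    foot: float = 0.16                 # m, ankle to toe
    hop_frequency: float = 2.4         # Hz
    contact_time: float = 0.26         # s
    n_hops: int = 20
    grf_shape_exponent: float = 2.7    # gamma of the sin^gamma pulse
    joint_amplitude_weights: Tuple[float, float, float] = (0.6, 0.3, 0.1)
    amplitude_scale_deg: float = 120.0
    touchdown_angles_deg: Tuple[float, float, float] = (135.0, 165.0, 177.0)
    marker_rate: float = 200.0         # Hz
    grf_rate: float = 1000.0           # Hz
    marker_noise_sd: float = 0.0       # m
    seed: int = 0
    exo: Optional[ExoConfig] = None

    def __post_init__(self) -> None:
        if self.contact_time >= 1.0 / self.hop_frequency:
            raise HopperValidationError("contact_time must be shorter than the hop period")
        for name in ("mass", "leg_length", "thigh", "shank", "foot"):
            if getattr(self, name) <= 0:
                raise HopperValidationError(f"{name} must be > 0")
        w = np.asarray(self.joint_amplitude_weights, float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise HopperValidationError("joint_amplitude_weights must be 3 non-negative values summing to 1")
        if self.grf_shape_exponent < 1:
            raise HopperValidationError("grf_shape_exponent must be >= 1")
        ratio = self.grf_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise HopperValidationError("grf_rate must be an integer multiple of marker_rate")
        if self.n_hops < 1:
            raise HopperValidationError("n_hops must be >= 1")

    @property
    def condition(self) -> str:
        if self.exo is None:
            return "NH"
        return CONDITION_CODES.get(self.exo.profile.kind, "EXO")

    @property
    def total_mass(self) -> float:
        return self.mass + (2 * self.exo.leg_mass if self.exo else 0.0)


@dataclass
class HopTrial:
    """Synchronized markers + per-leg GRFs for one hopping trial.

    Marker and force streams share the time origin t = 0; both legs are
    mirrored onto one sagittal marker set.
    """

    markers: Dict[str, np.ndarray]      # name -> (n, 2) m, (forward, up)
    marker_rate: float
    grf: Dict[str, pd.DataFrame]        # 'left'/'right' -> time_s, fz_N, fx_N, cop_x_m
    grf_rate: float
    participant: Dict[str, float]       # mass (biological), leg_length
    condition: str
    spring: Optional[SpringProfile] = None   # per-leg law with rest_length set
    exo_leg_mass: float = 0.0
    exo_hip_offset: Tuple[float, float] = (0.0, 0.0)
    exo_foot_offset: Tuple[float, float] = (0.0, 0.02)
    meta: Dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        n = next(iter(self.markers.values())).shape[0]
        return np.arange(n) / self.marker_rate

    def summed_vgrf(self) -> np.ndarray:
        return sum(df["fz_N"].to_numpy() for df in self.grf.values())


@dataclass
class GroundTruth:
    """Simulator-emitted truth for parameter-recovery tests (per leg,
    sampled on the marker clock)."""

    time: np.ndarray
    contact_mask: np.ndarray            # true contact (pulse support)
    displacement: np.ndarray            # spring compression d(t), m
    force: np.ndarray                   # per-leg exo force, N
    line_point: np.ndarray              # (n, 2) hip attachment
    line_dir: np.ndarray                # (n, 2) unit hip->foot attachment
    arms: Dict[str, np.ndarray]         # per-joint perpendicular distance, m
    moments: Dict[str, np.ndarray]      # per-leg signed exo moments, N m
    com_y: np.ndarray                   # hip-height proxy of the CoM, m
    rest_length: float
    threshold_onsets: np.ndarray        # analytic 20 N crossing times, s
    threshold_toeoffs: np.ndarray
    true_contact_time: float            # pulse width t_c
    angles_deg: Dict[str, np.ndarray]   # generating joint waveforms


# ---------------------------------------------------------------------------
# posture family and forward kinematics
# ---------------------------------------------------------------------------

def _posture_angles(params: HopperParams, c: np.ndarray) -> Dict[str, np.ndarray]:
    """Joint angles (deg) of the one-parameter compression family."""
    c = np.asarray(c, float)
    w = np.asarray(params.joint_amplitude_weights, float)
    a0, k0, h0 = params.touchdown_angles_deg
    S = params.amplitude_scale_deg
    return {
        "ankle": a0 - w[0] * S * c,
        "knee": k0 - w[1] * S * c,
        "hip": h0 - w[2] * S * c,
    }


def _unit(theta_deg: np.ndarray) -> np.ndarray:
    th = np.radians(theta_deg)
    return np.stack([np.cos(th), np.sin(th)], axis=-1)


def fk_relative(params: HopperParams, angles: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Segment endpoints relative to the hip, from joint angles.

    Conventions: x forward, y up; angle increase = extension /
    plantarflexion; straight knee/hip = 180 deg, anatomical ankle = 90 deg.
    The pelvis is upright, the knee flexes posteriorly and the hip
    anteriorly.  Returns knee/ankle/toe offsets and the foot's absolute
    direction angle (deg, toe direction from the ankle).
    """
    beta_h = 180.0 - np.asarray(angles["hip"], float)
    beta_k = 180.0 - np.asarray(angles["knee"], float)
    alpha = np.asarray(angles["ankle"], float)
    theta_t = -90.0 + beta_h
    theta_s = theta_t - beta_k
    theta_f = theta_s + 180.0 - alpha
    knee = params.thigh * _unit(theta_t)
    ankle = knee + params.shank * _unit(theta_s)
    toe = ankle + params.foot * _unit(theta_f)
    return {"knee": knee, "ankle": ankle, "toe": toe, "theta_f": theta_f}


def _posture_tables(params: HopperParams, c_max: float = 1.5, n: int = 3001):
    c_grid = np.linspace(0.0, c_max, n)
    rel = fk_relative(params, _posture_angles(params, c_grid))
    H = -rel["toe"][:, 1]           # hip height above toe
    X = rel["toe"][:, 0]            # toe forward of hip
    if np.any(np.diff(H) >= 0):
        raise InfeasibleGeometryError(
            "posture family is not monotonically shortening; adjust touchdown "
            "angles or amplitude weights"
        )
    if H[0] <= 0:
        raise InfeasibleGeometryError("extended leg has non-positive hip height")
    return c_grid, H, X


# ---------------------------------------------------------------------------
# pulse dynamics
# ---------------------------------------------------------------------------

def _pulse_mean_factor(gamma_exp: float) -> float:
    """Mean of sin^gamma over a half period."""
    g = gamma_exp
    return float(np.sqrt(np.pi) * _gamma_fn((g + 1) / 2) / (_gamma_fn(g / 2 + 1) * np.pi))


def peak_vgrf_half_sine(mass: float, hop_frequency: float, contact_time: float,
                        gamma_exp: float = 1.0) -> float:
    """Closed-form impulse-balanced pulse peak: F_peak = m g T / (t_c M_gamma)."""
    T = 1.0 / hop_frequency
    return mass * G * T / (contact_time * _pulse_mean_factor(gamma_exp))


def _contact_com(params: HopperParams, n_fine: int = 20001):
    """CoM height/velocity over one contact phase, relative to touchdown."""
    T = 1.0 / params.hop_frequency
    t_c = params.contact_time
    t_a = T - t_c
    f_peak = peak_vgrf_half_sine(params.total_mass, params.hop_frequency, t_c,
                                 params.grf_shape_exponent)
    s = np.linspace(0.0, t_c, n_fine)
    a = f_peak * np.sin(np.pi * s / t_c) ** params.grf_shape_exponent / params.total_mass - G
    dt = s[1] - s[0]
    v = -G * t_a / 2.0 + np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) * 0.5 * dt)])
    y = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) * 0.5 * dt)])
    return s, y, v, f_peak


def _phase(t: np.ndarray, T: float) -> np.ndarray:
    return np.mod(t, T)


def _com_height_rel(t: np.ndarray, params: HopperParams, s, y_c) -> np.ndarray:
    """CoM height relative to the touchdown height, at arbitrary times.

    Phase 0 is the aerial apex; touchdown at t_a/2, toe-off at t_a/2+t_c.
    """
    T = 1.0 / params.hop_frequency
    t_c = params.contact_time
    t_a = T - t_c
    tau = _phase(t, T)
    apex = G * t_a**2 / 8.0
    y = np.empty_like(tau)
    early = tau < t_a / 2.0
    late = tau >= t_a / 2.0 + t_c
    contact = ~(early | late)
    y[early] = apex - G * tau[early] ** 2 / 2.0
    y[late] = apex - G * (T - tau[late]) ** 2 / 2.0
    y[contact] = np.interp(tau[contact] - t_a / 2.0, s, y_c)
    return y


# ---------------------------------------------------------------------------
# trial assembly
# ---------------------------------------------------------------------------

def _exo_geometry(params: HopperParams, hip: np.ndarray, toe: np.ndarray,
                  theta_f: np.ndarray):
    exo = params.exo
    hip_att = hip + np.asarray(exo.hip_offset, float)
    ox, oy = exo.foot_offset
    foot_att = toe + ox * _unit(theta_f) + oy * _unit(theta_f + 90.0)
    return hip_att, foot_att


def _ground_truth(params: HopperParams, time: np.ndarray, contact: np.ndarray,
                  markers: Dict[str, np.ndarray], theta_f: np.ndarray,
                  angles: Dict[str, np.ndarray]) -> Tuple[GroundTruth, Optional[SpringProfile]]:
    hip = markers["hip"]
    n = hip.shape[0]
    gt_kwargs = dict(
        time=time, contact_mask=contact, com_y=hip[:, 1].copy(),
        angles_deg={k: v.copy() for k, v in angles.items()},
    )
    if params.exo is None:
        zeros = np.zeros(n)
        return (
            GroundTruth(
                displacement=zeros, force=zeros.copy(),
                line_point=hip.copy(), line_dir=np.zeros((n, 2)),
                arms={j: zeros.copy() for j in ("ankle", "knee", "hip")},
                moments={j: zeros.copy() for j in ("ankle", "knee", "hip")},
                rest_length=0.0, threshold_onsets=np.array([]),
                threshold_toeoffs=np.array([]),
                true_contact_time=params.contact_time, **gt_kwargs,
            ),
            None,
        )
    hip_att, foot_att = _exo_geometry(params, hip, markers["toe"], theta_f)
    vec = foot_att - hip_att
    L = np.linalg.norm(vec, axis=1)
    L0 = float(np.max(L))  # extended (touchdown/aerial) posture
    d = np.clip(L0 - L, 0.0, None)
    u = vec / L[:, None]
    profile = with_rest_length(params.exo.profile, L0)
    f = spring_force_branched(profile, d, loading_mask(d))
    arms, moments = {}, {}
    for joint in ("ankle", "knee", "hip"):
        r = foot_att - markers[joint]
        cross_u = r[:, 0] * u[:, 1] - r[:, 1] * u[:, 0]
        arms[joint] = np.abs(cross_u)
        moments[joint] = EXTENSOR_SIGN[joint] * cross_u * f
    return (
        GroundTruth(
            displacement=d, force=f, line_point=hip_att, line_dir=u,
            arms=arms, moments=moments, rest_length=L0,
            threshold_onsets=np.array([]), threshold_toeoffs=np.array([]),
            true_contact_time=params.contact_time, **gt_kwargs,
        ),
        profile,
    )


def _threshold_crossings(params: HopperParams, f_peak: float, duration: float,
                         threshold: float = 20.0):
    """Analytic times at which the summed pulse crosses the threshold."""
    T = 1.0 / params.hop_frequency
    t_c = params.contact_time
    t_a = T - t_c
    frac = (threshold / f_peak) ** (1.0 / params.grf_shape_exponent)
    s_on = t_c / np.pi * np.arcsin(min(frac, 1.0))
    onsets, toeoffs = [], []
    k = 0
    while True:
        td = k * T + t_a / 2.0
        if td + s_on > duration:
            break
        onsets.append(td + s_on)
        toeoffs.append(td + t_c - s_on)
        k += 1
    return np.asarray(onsets), np.asarray(toeoffs)


def simulate_trial(params: HopperParams) -> Tuple[HopTrial, GroundTruth]:
    """Generate one dynamically consistent synthetic hopping trial.

    Returns the trial plus analytic ground truth (exoskeleton force and
    moments, contact events, generating joint waveforms).  Reproducible
    for a fixed seed; two padding cycles are simulated around the
    ``n_hops`` analysed hops so that filter edges and partial cycles fall
    outside the analysis window.
    """
    T = 1.0 / params.hop_frequency
    t_a = T - params.contact_time
    n_cycles = params.n_hops + 2
    duration = n_cycles * T

    c_grid, H_grid, X_grid = _posture_tables(params)
    H0, X0 = H_grid[0], X_grid[0]
    drop_grid = H0 - H_grid

    s, y_c, v_c, f_peak = _contact_com(params)
    max_drop_needed = float(-np.min(y_c))
    if max_drop_needed > drop_grid[-1] - 1e-6:
        raise InfeasibleGeometryError(
            f"required leg shortening {max_drop_needed:.3f} m exceeds the "
            f"posture family range {drop_grid[-1]:.3f} m"
        )

    def posture_at(t: np.ndarray):
        tau = _phase(t, T)
        contact = (tau >= t_a / 2.0) & (tau < t_a / 2.0 + params.contact_time)
        y_rel = _com_height_rel(t, params, s, y_c)
        drop = np.clip(-y_rel, 0.0, None)
        c = np.where(contact, np.interp(drop, drop_grid, c_grid), 0.0)
        return c, y_rel, contact

    # marker clock
    n_m = int(round(duration * params.marker_rate))
    t_m = np.arange(n_m) / params.marker_rate
    c_m, y_rel_m, contact_m = posture_at(t_m)
    angles = _posture_angles(params, c_m)
    rel = fk_relative(params, angles)
    hip = np.empty((n_m, 2))
    hip[:, 0] = X0 - np.interp(c_m, c_grid, X_grid)
    hip[:, 1] = H0 + y_rel_m
    markers = {
        "hip": hip,
        "knee": hip + rel["knee"],
        "ankle": hip + rel["ankle"],
        "toe": hip + rel["toe"],
    }
    markers["heel"] = markers["ankle"] + 0.06 * _unit(rel["theta_f"] + 180.0)

    gt, spring = _ground_truth(params, t_m, contact_m, markers, rel["theta_f"], angles)
    if params.exo is not None:
        hip_att, foot_att = _exo_geometry(params, hip, markers["toe"], rel["theta_f"])
        markers["exo_hip"] = hip_att
        markers["exo_foot"] = foot_att

    # force clock
    n_g = int(round(duration * params.grf_rate))
    t_g = np.arange(n_g) / params.grf_rate
    tau_g = _phase(t_g, T)
    contact_g = (tau_g >= t_a / 2.0) & (tau_g < t_a / 2.0 + params.contact_time)
    fz = np.zeros(n_g)
    fz[contact_g] = f_peak * np.sin(
        np.pi * (tau_g[contact_g] - t_a / 2.0) / params.contact_time
    ) ** params.grf_shape_exponent
    c_g, _, _ = posture_at(t_g)
    x_hip_g = X0 - np.interp(c_g, c_grid, X_grid)
    dt_g = 1.0 / params.grf_rate
    fx = params.total_mass * np.gradient(np.gradient(x_hip_g, dt_g), dt_g)
    fx[~contact_g] = 0.0
    cop = np.full(n_g, X0)

    grf = {}
    for leg in ("left", "right"):
        grf[leg] = pd.DataFrame(
            {"time_s": t_g, "fz_N": fz / 2.0, "fx_N": fx / 2.0, "cop_x_m": cop}
        )

    gt.threshold_onsets, gt.threshold_toeoffs = _threshold_crossings(
        params, f_peak, duration
    )

    if params.marker_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, params.marker_noise_sd, markers[name].shape
            )

    trial = HopTrial(
        markers=markers,
        marker_rate=params.marker_rate,
        grf=grf,
        grf_rate=params.grf_rate,
        participant={"mass": params.mass, "leg_length": params.leg_length},
        condition=params.condition,
        spring=spring,
        exo_leg_mass=params.exo.leg_mass if params.exo else 0.0,
        exo_hip_offset=params.exo.hip_offset if params.exo else (0.0, 0.0),
        exo_foot_offset=params.exo.foot_offset if params.exo else (0.0, 0.02),
        meta={
            "seed": params.seed,
            "n_hops": params.n_hops,
            "hop_frequency": params.hop_frequency,
            "contact_time": params.contact_time,
            "grf_shape_exponent": params.grf_shape_exponent,
            "peak_vgrf_summed": float(f_peak),
        },
    )
    return trial, gt


def simulate_quasistatic_trial(
    params: HopperParams,
    period_s: float = 10.0,
    n_cycles: int = 2,
    c_amp: float = 0.8,
) -> Tuple[HopTrial, GroundTruth]:
    """Grounded slow-squat trial for quasi-static (statics-oracle) checks.

    The toe stays on the ground throughout; the posture parameter follows
    a slow raised cosine so accelerations are negligible and inverse
    dynamics should match a pure statics computation.  GRF is the
    point-mass-consistent m(a+g).
    """
    duration = n_cycles * period_s
    c_grid, H_grid, X_grid = _posture_tables(params)
    H0, X0 = H_grid[0], X_grid[0]

    def c_of(t):
        return c_amp * (1.0 - np.cos(2 * np.pi * t / period_s)) / 2.0

    n_m = int(round(duration * params.marker_rate))
    t_m = np.arange(n_m) / params.marker_rate
    c_m = c_of(t_m)
    angles = _posture_angles(params, c_m)
    rel = fk_relative(params, angles)
    hip = np.empty((n_m, 2))
    hip[:, 0] = X0 - np.interp(c_m, c_grid, X_grid)
    hip[:, 1] = np.interp(c_m, c_grid, H_grid)
    markers = {
        "hip": hip,
        "knee": hip + rel["knee"],
        "ankle": hip + rel["ankle"],
        "toe": hip + rel["toe"],
    }
    markers["heel"] = markers["ankle"] + 0.06 * _unit(rel["theta_f"] + 180.0)
    contact_m = np.ones(n_m, dtype=bool)
    gt, spring = _ground_truth(params, t_m, contact_m, markers, rel["theta_f"], angles)
    if params.exo is not None:
        hip_att, foot_att = _exo_geometry(params, hip, markers["toe"], rel["theta_f"])
        markers["exo_hip"] = hip_att
        markers["exo_foot"] = foot_att

    n_g = int(round(duration * params.grf_rate))
    t_g = np.arange(n_g) / params.grf_rate
    c_g = c_of(t_g)
    y_g = np.interp(c_g, c_grid, H_grid)
    x_g = X0 - np.interp(c_g, c_grid, X_grid)
    dt_g = 1.0 / params.grf_rate
    fz = params.total_mass * (np.gradient(np.gradient(y_g, dt_g), dt_g) + G)
    fx = params.total_mass * np.gradient(np.gradient(x_g, dt_g), dt_g)
    grf = {
        leg: pd.DataFrame(
            {"time_s": t_g, "fz_N": fz / 2.0, "fx_N": fx / 2.0,
             "cop_x_m": np.full(n_g, X0)}
        )
        for leg in ("left", "right")
    }
    trial = HopTrial(
        markers=markers, marker_rate=params.marker_rate, grf=grf,
        grf_rate=params.grf_rate,
        participant={"mass": params.mass, "leg_length": params.leg_length},
        condition=params.condition, spring=spring,
        exo_leg_mass=params.exo.leg_mass if params.exo else 0.0,
        exo_hip_offset=params.exo.hip_offset if params.exo else (0.0, 0.0),
        exo_foot_offset=params.exo.foot_offset if params.exo else (0.0, 0.02),
        meta={"seed": params.seed, "quasistatic": True, "period_s": period_s},
    )
    return trial, gt


def emit_cohort(
    n_participants: int,
    condition_list: Sequence[str],
    params_template: Optional[HopperParams] = None,
    seed: int = 0,
    condition_effects: Optional[Dict[str, Dict[str, float]]] = None,
    hysteresis_fraction: float = 0.0,
) -> List[Tuple[HopTrial, GroundTruth]]:
    """Simulate a crossed cohort: every participant hops every condition.

    Participant mass and leg geometry are drawn around the study cohort's
    distribution (mass ~ N(66, 5.7) kg, leg length ~ N(0.90, 0.04) m,
    segment lengths scaled with leg length); each exo condition's per-leg
    spring follows the body-mass stiffness prescription.
    ``condition_effects`` maps a condition to additive offsets on numeric
    generator parameters (zero offsets give a null cohort).  Deterministic
    under ``seed``.
    """
    if n_participants < 2:
        raise HopperValidationError("n_participants must be >= 2")
    if not condition_list:
        raise HopperValidationError("condition list must not be empty")
    template = params_template or HopperParams()
    rng = np.random.default_rng(seed)
    condition_effects = condition_effects or {}

    trials: List[Tuple[HopTrial, GroundTruth]] = []
    for pid in range(n_participants):
        mass = float(np.clip(rng.normal(66.0, 5.7), 50.0, 90.0))
        leg = float(np.clip(rng.normal(0.90, 0.04), 0.78, 1.02))
        scale = leg / 0.90
        for cond in condition_list:
            fields = dict(
                mass=mass,
                leg_length=leg,
                thigh=template.thigh * scale,
                shank=template.shank * scale,
                foot=template.foot * scale,
                seed=int(rng.integers(2**31)),
            )
            for key, delta in condition_effects.get(cond, {}).items():
                fields[key] = getattr(template, key) + delta
            if cond.upper() == "NH":
                exo = None
            else:
                profile = profile_for_condition(
                    cond, mass, hysteresis_fraction=hysteresis_fraction
                )
                exo = ExoConfig(profile=profile)
            params = replace(template, exo=exo, **fields)
            trial, gt = simulate_trial(params)
            trial.meta["participant_id"] = pid
            trials.append((trial, gt))
    return trials
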