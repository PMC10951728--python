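"""Link-segment inverse dynamics against statics oracles."""

import numpy as np
import pytest

from hopexo.hopper import HopperParams, simulate_quasistatic_trial
from hopexo.inverse_dynamics import (
    AnthropometryError,
    SegmentParams,
    inverse_dynamics,
    segment_parameters,
    statics_moments,
)
from hopexo.kinematics import joint_angles
from hopexo.signals import lowpass

G = 9.81
JOINTS = ("ankle", "knee", "hip")


class TestSegmentParameters:
    def test_masses_follow_table_fractions(self):
        p = segment_parameters(66.0, {"foot": 0.16, "shank": 0.40, "thigh": 0.42})
        assert p.masses["foot"] == pytest.approx(0.0145 * 66.0)
        assert p.masses["shank"] == pytest.approx(0.0465 * 66.0)
        assert p.masses["thigh"] == pytest.approx(0.100 * 66.0)
        assert sum(p.masses.values()) < 66.0

    def test_zero_exo_mass_is_identity(self):
        lengths = {"foot": 0.16, "shank": 0.40, "thigh": 0.42}
        a = segment_parameters(66.0, lengths, exo_leg_mass=0.0)
        b = segment_parameters(66.0, lengths)
        assert a == b

    def test_unknown_table_rejected(self):
        with pytest.raises(AnthropometryError):
            segment_parameters(66.0, {"foot": 0.16, "shank": 0.4, "thigh": 0.42},
                               table_id="nosuch")

    def test_invalid_mass_rejected(self):
        with pytest.raises(AnthropometryError):
            segment_parameters(-1.0, {"foot": 0.16, "shank": 0.4, "thigh": 0.42})


def _static_chain(n=64):
    """Static toe-stand markers: shank vertical, plantarflexed foot."""
    mk = {
        "hip": (0.0, 0.95), "knee": (0.02, 0.52), "ankle": (0.0, 0.12),
        "toe": (0.10, 0.0), "heel": (-0.04, 0.10),
    }
    return {k: np.tile(np.asarray(v), (n, 1)) for k, v in mk.items()}


class TestStaticsOracle:
    def test_massless_toe_stand_ankle_moment_is_force_times_arm(self):
        n = 64
        mk = _static_chain(n)
        ang = joint_angles(mk, 200.0)
        params = SegmentParams(
            masses={s: 0.0 for s in ("foot", "shank", "thigh")},
            com_fracs={s: 0.5 for s in ("foot", "shank", "thigh")},
            gyration_fracs={s: 0.3 for s in ("foot", "shank", "thigh")},
            lengths={"foot": 0.16, "shank": 0.4, "thigh": 0.43},
            table_id="test",
        )
        F = 500.0
        grf = np.tile([0.0, F], (n, 1))
        cop = np.full(n, 0.10)  # at the toe
        jk = inverse_dynamics(ang, mk, grf, cop, params)
        r = 0.10 - 0.0  # horizontal arm cop -> ankle
        assert jk.moments["ankle"][n // 2] == pytest.approx(F * r, rel=1e-9)
        # plantarflexor-assisting: positive under the sign convention
        assert jk.moments["ankle"][n // 2] > 0
        for j in JOINTS:
            np.testing.assert_allclose(jk.powers[j], 0.0, atol=1e-9)

    def test_zero_grf_moments_equal_gravity_of_distal_segments(self):
        n = 64
        mk = _static_chain(n)
        ang = joint_angles(mk, 200.0)
        params = segment_parameters(66.0, {"foot": 0.16, "shank": 0.4, "thigh": 0.43})
        grf = np.zeros((n, 2))
        cop = np.zeros(n)
        jk = inverse_dynamics(ang, mk, grf, cop, params)
        oracle = statics_moments(mk, grf, cop, params)
        for j in JOINTS:
            assert jk.moments[j][n // 2] == pytest.approx(oracle[j][n // 2], abs=1e-9)


def test_quasistatic_trial_matches_statics_within_2_percent():
    """A 10x-slowed grounded squat: inverse dynamics vs pure statics."""
    trial, _ = simulate_quasistatic_trial(HopperParams(), period_s=10.0, n_cycles=1)
    rate = trial.marker_rate
    mk = {k: lowpass(v, 20.0, rate, 4) for k, v in trial.markers.items()}
    ang = joint_angles(mk, rate)
    params = segment_parameters(
        66.0, {"foot": 0.16, "shank": 0.40, "thigh": 0.42}
    )
    n = next(iter(mk.values())).shape[0]
    q = int(trial.grf_rate // rate)
    fz = lowpass(trial.grf["left"]["fz_N"].to_numpy(), 20.0, trial.grf_rate, 4)[::q][:n]
    fx = lowpass(trial.grf["left"]["fx_N"].to_numpy(), 20.0, trial.grf_rate, 4)[::q][:n]
    cop = trial.grf["left"]["cop_x_m"].to_numpy()[::q][:n]
    grf = np.column_stack([fx, fz])
    jk = inverse_dynamics(ang, mk, grf, cop, params)
    oracle = statics_moments(mk, grf, cop, params)
    sl = slice(100, n - 100)
    for j in JOINTS:
        peak = np.max(np.abs(oracle[j][sl]))
        rms = np.sqrt(np.mean((jk.moments[j][sl] - oracle[j][sl]) ** 2))
        assert rms < 0.02 * peak, j


def test_power_is_moment_times_angular_velocity(nh_result):
    for j in JOINTS:
        for leg in nh_result.per_leg.values():
            np.testing.assert_allclose(
                leg.powers_overall[j],
                leg.moments_overall[j] * nh_result.angles.angvel_rad[j],
                atol=1e-9,
            )


def test_summed_ankle_moment_tracks_grf_lever_at_speed(nh_trial, nh_result):
    """At hopping speed the summed-leg overall ankle moment stays within
    5% RMS of the point-mass GRF x lever-arm prediction (the tolerance
    documents the generator's neglect of segment inertia)."""
    trial, _ = nh_trial
    res = nh_result
    n = next(iter(trial.markers.values())).shape[0]
    mk = {k: lowpass(v, 20.0, trial.marker_rate, 4) for k, v in trial.markers.items()}
    q = int(trial.grf_rate // trial.marker_rate)
    fzs = lowpass(trial.summed_vgrf(), 20.0, trial.grf_rate, 4)[::q][:n]
    fxs = lowpass(sum(df["fx_N"].to_numpy() for df in trial.grf.values()),
                  20.0, trial.grf_rate, 4)[::q][:n]
    cop = trial.grf["left"]["cop_x_m"].to_numpy()[::q][:n]
    r = np.column_stack([cop, np.zeros(n)]) - mk["ankle"]
    pred = r[:, 0] * fzs - r[:, 1] * fxs   # plantarflexor-positive
    use = res.cycles_marker.cycles[1:-1]
    sl = slice(use[0][0], use[-1][1])
    m = res.decomposition.moments_overall["ankle"]
    rms = np.sqrt(np.mean((m[sl] - pred[sl]) ** 2))
    assert rms < 0.05 * np.max(np.abs(m[sl]))
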