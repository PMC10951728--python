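"""Synthetic hopper: dynamics consistency, geometry, determinism, cohort."""

import numpy as np
import pytest

from hopexo.hopper import (
    ExoConfig,
    HopperParams,
    HopperValidationError,
    InfeasibleGeometryError,
    emit_cohort,
    peak_vgrf_half_sine,
    simulate_trial,
)
from hopexo.springs import profile_for_condition, spring_force

G = 9.81


class TestPulseDynamics:
    def test_impulse_balance_over_integer_cycles(self, nh_trial):
        """Mean summed vGRF over the (integer-cycle) trial equals body weight."""
        trial, _ = nh_trial
        mean_f = trial.summed_vgrf().mean()
        assert mean_f == pytest.approx(66.0 * G, rel=1e-3)

    def test_half_sine_peak_closed_form(self):
        expect = (np.pi / 2) * 66.0 * G * (1 / 2.4) / 0.26
        assert peak_vgrf_half_sine(66.0, 2.4, 0.26, 1.0) == pytest.approx(expect)
        assert expect == pytest.approx(1630.0, abs=2.0)

    def test_default_pulse_brackets_study_conditions(self, nh_trial):
        """gamma = 2.7 at 66 kg: peak vGRF 2.0-2.6 kN, CoM drop 8-12 cm."""
        trial, gt = nh_trial
        assert 2000.0 < trial.summed_vgrf().max() < 2600.0
        td_height = gt.com_y[~gt.contact_mask].min()
        drop = td_height - gt.com_y[gt.contact_mask].min()
        assert 0.08 < drop < 0.12

    def test_aerial_ballistic_apex(self, nh_trial):
        trial, gt = nh_trial
        t_a = 1 / 2.4 - 0.26
        apex = gt.com_y.max() - gt.com_y[~gt.contact_mask].min()
        assert apex == pytest.approx(G * t_a**2 / 8.0, rel=1e-3)


class TestExoGroundTruth:
    def test_exo_force_matches_spring_law_exactly(self, dg_trial):
        trial, gt = dg_trial
        f_expect = spring_force(trial.spring, gt.displacement, "loading")
        np.testing.assert_allclose(gt.force, f_expect, atol=1e-9)

    def test_exo_force_zero_in_aerial_phases(self, dg_trial):
        _, gt = dg_trial
        assert np.all(gt.force[~gt.contact_mask] == 0.0)
        assert np.all(gt.displacement[~gt.contact_mask] == 0.0)

    def test_rest_length_is_touchdown_attachment_distance(self, dg_trial):
        trial, gt = dg_trial
        d_att = np.linalg.norm(
            trial.markers["exo_foot"] - trial.markers["exo_hip"], axis=1
        )
        assert gt.rest_length == pytest.approx(d_att[~gt.contact_mask].max())

    def test_moments_equal_force_times_arm(self, dg_trial):
        _, gt = dg_trial
        for j in ("ankle", "knee", "hip"):
            np.testing.assert_allclose(
                np.abs(gt.moments[j]), gt.arms[j] * gt.force, atol=1e-9
            )


class TestDeterminism:
    def test_same_seed_identical_trials(self):
        p = HopperParams(n_hops=3, marker_noise_sd=0.001, seed=11)
        t1, _ = simulate_trial(p)
        t2, _ = simulate_trial(p)
        for k in t1.markers:
            np.testing.assert_array_equal(t1.markers[k], t2.markers[k])
        for leg in t1.grf:
            np.testing.assert_array_equal(
                t1.grf[leg].to_numpy(), t2.grf[leg].to_numpy()
            )

    def test_different_seed_differs_under_noise(self):
        t1, _ = simulate_trial(HopperParams(n_hops=3, marker_noise_sd=0.001, seed=1))
        t2, _ = simulate_trial(HopperParams(n_hops=3, marker_noise_sd=0.001, seed=2))
        assert not np.array_equal(t1.markers["hip"], t2.markers["hip"])


class TestValidation:
    def test_contact_time_must_fit_in_period(self):
        with pytest.raises(HopperValidationError):
            HopperParams(hop_frequency=2.4, contact_time=0.45)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(HopperValidationError):
            HopperParams(joint_amplitude_weights=(0.5, 0.5, 0.5))

    def test_rates_must_be_integer_ratio(self):
        with pytest.raises(HopperValidationError):
            HopperParams(marker_rate=200.0, grf_rate=900.0)

    def test_infeasible_shortening_raises(self):
        with pytest.raises(InfeasibleGeometryError):
            simulate_trial(HopperParams(n_hops=2, amplitude_scale_deg=15.0))


class TestCohort:
    def test_counts_and_conditions(self):
        trials = emit_cohort(3, ["NH", "DG", "LN", "PG"],
                             HopperParams(n_hops=3), seed=9)
        assert len(trials) == 12
        assert {t.condition for t, _ in trials} == {"NH", "DG", "LN", "PG"}
        pids = {t.meta["participant_id"] for t, _ in trials}
        assert pids == {0, 1, 2}

    def test_deterministic_under_seed(self):
        a = emit_cohort(2, ["NH", "DG"], HopperParams(n_hops=2), seed=5)
        b = emit_cohort(2, ["NH", "DG"], HopperParams(n_hops=2), seed=5)
        for (ta, _), (tb, _) in zip(a, b):
            np.testing.assert_array_equal(ta.markers["hip"], tb.markers["hip"])
            assert ta.participant == tb.participant

    def test_validation(self):
        with pytest.raises(HopperValidationError):
            emit_cohort(1, ["NH"])
        with pytest.raises(HopperValidationError):
            emit_cohort(2, [])

    def test_condition_effects_shift_parameters(self):
        trials = emit_cohort(
            2, ["NH", "PG"], HopperParams(n_hops=2), seed=3,
            condition_effects={"PG": {"contact_time": -0.02}},
        )
        nh = [t for t, _ in trials if t.condition == "NH"][0]
        pg = [t for t, _ in trials if t.condition == "PG"][0]
        assert pg.meta["contact_time"] == pytest.approx(nh.meta["contact_time"] - 0.02)
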