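"""Joint angle conventions, ROM/peaks and spatiotemporal summaries."""

import numpy as np
import pytest

from hopexo import kinematics as kin
from hopexo.signals import HopCycleSet, detect_contacts, lowpass


def _static_markers(hip, knee, ankle, toe, n=16):
    return {
        name: np.tile(np.asarray(xy, float), (n, 1))
        for name, xy in [("hip", hip), ("knee", knee), ("ankle", ankle), ("toe", toe)]
    }


class TestAngleConventions:
    def test_collinear_leg_gives_straight_knee(self):
        mk = _static_markers((0, 1.0), (0, 0.6), (0, 0.2), (0.15, 0.2))
        a = kin.joint_angles(mk, 200.0)
        assert a.angles_deg["knee"][0] == pytest.approx(180.0)

    def test_foot_perpendicular_to_shank_is_anatomical_90(self):
        mk = _static_markers((0, 1.0), (0, 0.6), (0, 0.2), (0.15, 0.2))
        a = kin.joint_angles(mk, 200.0)
        assert a.angles_deg["ankle"][0] == pytest.approx(90.0)

    def test_toes_down_20_deg_reads_110_plantarflexion(self):
        toe = (0.15 * np.cos(np.radians(20)), 0.2 - 0.15 * np.sin(np.radians(20)))
        mk = _static_markers((0, 1.0), (0, 0.6), (0, 0.2), toe)
        a = kin.joint_angles(mk, 200.0)
        assert a.angles_deg["ankle"][0] == pytest.approx(110.0)

    def test_vertical_thigh_gives_extended_hip(self):
        mk = _static_markers((0, 1.0), (0, 0.6), (0, 0.2), (0.15, 0.2))
        a = kin.joint_angles(mk, 200.0)
        assert a.angles_deg["hip"][0] == pytest.approx(180.0)

    def test_missing_landmark_error_names_marker(self):
        mk = _static_markers((0, 1.0), (0, 0.6), (0, 0.2), (0.15, 0.2))
        del mk["knee"]
        with pytest.raises(kin.MissingLandmarkError, match="knee"):
            kin.joint_angles(mk, 200.0)


def test_generator_waveforms_recovered_to_machine_precision(nh_trial):
    """Re-deriving angles from noiseless emitted markers reproduces the
    generating waveforms."""
    trial, gt = nh_trial
    a = kin.joint_angles(trial.markers, trial.marker_rate)
    for j in ("ankle", "knee", "hip"):
        np.testing.assert_allclose(a.angles_deg[j], gt.angles_deg[j], atol=1e-9)


class TestRomAndPeaks:
    def _cycles(self, n, rate=200.0):
        return HopCycleSet(
            contact_onsets=np.array([0]), toe_offs=np.array([n // 2]),
            cycles=[(0, n)], rate=rate,
        )

    def test_constant_angle_zero_rom(self):
        n = 200
        series = kin.JointAngleSeries(
            {j: np.full(n, 150.0) for j in kin.JOINTS},
            {j: np.zeros(n) for j in kin.JOINTS}, 200.0,
        )
        out = kin.rom_and_peaks(series, self._cycles(n))
        assert (out.rom_deg == 0).all()

    def test_sinusoid_rom_is_twice_amplitude(self):
        n, amp = 200, 12.0
        wave = 150.0 + amp * np.sin(2 * np.pi * np.arange(n) / n)
        series = kin.JointAngleSeries(
            {j: wave for j in kin.JOINTS}, {j: np.zeros(n) for j in kin.JOINTS}, 200.0
        )
        out = kin.rom_and_peaks(series, self._cycles(n))
        assert out.rom_deg.iloc[0] == pytest.approx(2 * amp, rel=1e-3)
        assert out.peak_flexion_deg.iloc[0] == pytest.approx(150.0 - amp, rel=1e-3)

    def test_generator_extremes_recovered(self, nh_trial):
        trial, gt = nh_trial
        a = kin.joint_angles(trial.markers, trial.marker_rate)
        vg = lowpass(trial.summed_vgrf(), 20.0, trial.grf_rate, 4)
        cycles = detect_contacts(vg, trial.grf_rate).scaled_to(trial.marker_rate)
        out = kin.rom_and_peaks(a, cycles)
        for _, r in out.iterrows():
            true_min = gt.angles_deg[r.joint].min()
            assert r.peak_flexion_deg == pytest.approx(true_min, abs=0.1)


class TestSpatiotemporal:
    def test_ballistic_hop_height_closed_form(self):
        assert kin.hop_height_from_flight(0.157) * 100 == pytest.approx(3.02, abs=0.01)
        assert kin.hop_height_from_flight(0.0) == 0.0

    def test_generator_frequency_recovered(self, nh_trial):
        trial, _ = nh_trial
        vg = lowpass(trial.summed_vgrf(), 20.0, trial.grf_rate, 4)
        cycles = detect_contacts(vg, trial.grf_rate)
        st = kin.spatiotemporal(vg, cycles, mass=66.0)
        assert st.hop_frequency_hz == pytest.approx(2.40, abs=0.005)
        assert st.hop_height_cm == pytest.approx(st.hop_height_flight_cm, rel=0.05)

    def test_mass_validation(self, nh_trial):
        trial, _ = nh_trial
        vg = trial.summed_vgrf()
        cycles = detect_contacts(vg, trial.grf_rate)
        with pytest.raises(ValueError):
            kin.spatiotemporal(vg, cycles, mass=0.0)
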