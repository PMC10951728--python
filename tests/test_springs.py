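"""Spring profile laws, energetics, hysteresis and the stiffness prescription."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopexo import springs as sp

REF_F = 844.0   # N at 10 cm for an 8.44 kN/m linear spring
D_REF = 0.10


@pytest.mark.parametrize(
    "kind,exponent,d,expected",
    [
        ("linear", 1.0, 0.10, 844.0),
        ("linear", 1.0, 0.05, 422.0),
        ("degressive", 0.47, 0.05, 844.0 * 0.5**0.47),   # ~609.3 N
        ("progressive", 3.21, 0.05, 844.0 * 0.5**3.21),  # ~91.2 N
        ("linear", 1.0, 0.0, 0.0),
        ("linear", 1.0, -0.02, 0.0),
    ],
)
def test_parametric_loading_force(kind, exponent, d, expected):
    prof = sp.make_profile(kind, REF_F, D_REF, exponent)
    assert sp.spring_force(prof, d) == pytest.approx(expected, abs=1e-9)


def test_equal_secant_constraint_exact():
    profiles = [sp.make_profile(k, REF_F, D_REF) for k in sp.CANONICAL_EXPONENTS]
    forces = [sp.spring_force(p, D_REF) for p in profiles]
    assert forces[0] == forces[1] == forces[2] == REF_F


@given(st.floats(0.001, 0.099))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_profile_ordering_inside_reference(d):
    """Equal-secant DG > LN > PG everywhere strictly inside (0, d_ref)."""
    dg, ln, pg = (sp.make_profile(k, REF_F, D_REF) for k in
                  ("degressive", "linear", "progressive"))
    assert sp.spring_force(dg, d) > sp.spring_force(ln, d) > sp.spring_force(pg, d)


@pytest.mark.parametrize("kind,exponent", [("degressive", 1.2), ("progressive", 0.9),
                                           ("linear", 2.0)])
def test_exponent_kind_mismatch_rejected(kind, exponent):
    with pytest.raises(sp.SpringValidationError):
        sp.make_profile(kind, REF_F, D_REF, exponent)


@pytest.mark.parametrize("kind,q", [("degressive", 0.47), ("linear", 1.0),
                                    ("progressive", 3.21)])
def test_stored_energy_quadrature_matches_closed_form(kind, q):
    prof = sp.make_profile(kind, REF_F, D_REF, q)
    closed = REF_F * D_REF / (q + 1.0)
    assert sp.stored_energy(prof, D_REF, n_points=10_001) == pytest.approx(
        closed, rel=1e-4
    )


def test_linear_energy_is_half_k_d_squared():
    prof = sp.make_profile("linear", REF_F, D_REF)
    assert sp.stored_energy(prof, D_REF) == pytest.approx(42.2, rel=1e-4)


def test_negative_displacement_energy_rejected():
    prof = sp.make_profile("linear", REF_F, D_REF)
    with pytest.raises(sp.SpringValidationError):
        sp.stored_energy(prof, -0.01)


@pytest.mark.parametrize("h", [0.0, 0.1, 0.35])
def test_hysteresis_energy_budget(h):
    """Unloading energy = (1 - h) x loading energy; h = 0 is lossless."""
    prof = sp.make_profile("degressive", REF_F, D_REF, hysteresis_fraction=h)
    e_load = sp.stored_energy(prof, D_REF)
    e_unload = sp.returned_energy(prof, D_REF)
    assert e_unload == pytest.approx((1 - h) * e_load, rel=1e-3)
    d = np.linspace(0, D_REF, 11)
    fl = sp.spring_force(prof, d, "loading")
    fu = sp.spring_force(prof, d, "unloading")
    np.testing.assert_allclose(fu, (1 - h) * fl, rtol=1e-12)


@pytest.mark.parametrize(
    "ratio,expected",
    [(1.0, 1.0), (1.36, 2 / 1.36 - 1), (2 / 4.21, 3.21)],
)
def test_calibrate_exponent(ratio, expected):
    assert sp.calibrate_exponent(ratio) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("bad", [0.0, -1.0, 2.0, 2.5])
def test_calibrate_exponent_rejects_degenerate_ratio(bad):
    with pytest.raises(sp.SpringValidationError):
        sp.calibrate_exponent(bad)


@pytest.mark.parametrize("mass,expected", [(58.9, 7.84), (77.7, 10.34)])
def test_prescription_worked_rows(mass, expected):
    assert sp.prescribe_stiffness(mass) == pytest.approx(expected, abs=0.005)


def test_prescription_proportional_to_mass():
    model = sp.PrescriptionModel(constant=0.133, rounding=6)
    assert sp.prescribe_stiffness(120.0, model) == pytest.approx(
        2 * sp.prescribe_stiffness(60.0, model), rel=1e-9
    )
    with pytest.raises(sp.SpringValidationError):
        sp.prescribe_stiffness(-10.0)


def test_tabulated_profile_interpolation_and_range():
    d = np.array([0.0, 0.05, 0.10])
    f = np.array([0.0, 500.0, 844.0])
    prof = sp.tabulated_profile(d, f)
    assert sp.spring_force(prof, 0.025) == pytest.approx(250.0)
    with pytest.raises(sp.ExtrapolationError):
        sp.spring_force(prof, 0.15)


def test_tabulated_profile_rejects_ties_and_disorder():
    with pytest.raises(sp.SpringValidationError):
        sp.tabulated_profile([0.0, 0.05, 0.05], [0.0, 1.0, 2.0])
    with pytest.raises(sp.SpringValidationError):
        sp.tabulated_profile([0.0, 0.06, 0.05], [0.0, 1.0, 2.0])


def test_condition_profiles_halve_prescription_per_leg():
    prof = sp.profile_for_condition("LN", 66.0)
    k_total = sp.prescribe_stiffness(66.0) * 1e3
    assert prof.reference_force == pytest.approx(0.5 * k_total * 0.10)
    assert sp.profile_for_condition("NH", 66.0) is None
    with pytest.raises(sp.SpringValidationError):
        sp.profile_for_condition("XX", 66.0)
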