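"""Spring stiffness profiles of a passive full-leg hopping exoskeleton.

The device prescribes three interchangeable spring families — degressive
(DG: stiff early, compliant late), linear (LN) and progressive (PG:
compliant early, stiff late) — that all exert the *same* force at a
reference compression of 10 cm (equal secant stiffness).  The canonical
parametric family used here is a power law through the origin,

    F(d) = F_ref * (d / d_ref) ** q,

with q < 1 degressive, q = 1 linear and q > 1 progressive.  Under the
equal-secant constraint the elastic energy stored at the reference
compression is F_ref * d_ref / (q + 1), so the stored-energy ratio of any
profile against the linear one is 2 / (q + 1) — which is how the default
exponents (0.47 and 3.21) are calibrated.

Spring stiffness is prescribed per participant in proportion to body mass
(~0.133 kN m^-1 per kg for both legs' springs summed, characterised at
10 cm of compression).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpringProfile",
    "PrescriptionModel",
    "make_profile",
    "spring_force",
    "stored_energy",
    "returned_energy",
    "calibrate_exponent",
    "prescribe_stiffness",
    "participant_table",
    "calibrated_prescription",
    "profile_for_condition",
    "CANONICAL_EXPONENTS",
]

#: Canonical power-law exponents per profile kind.  Calibrated so the
#: equal-secant stored-energy ratios are 1.36 (DG vs LN) and 2/4.21 (PG vs
#: LN), i.e. a DG spring stores 36% more energy than LN and 186% more than
#: PG at the reference compression.
CANONICAL_EXPONENTS = {"degressive": 0.47, "linear": 1.0, "progressive": 3.21}

#: Condition code used in trial metadata per profile kind.
CONDITION_CODES = {"degressive": "DG", "linear": "LN", "progressive": "PG"}

# Participant characteristics and per-participant exoskeleton stiffness
# (sum of both legs' springs, characterised at 10 cm of compression).
# Columns: sex, age (yr), height (m), leg length (m), mass (kg),
# k_calc, k_DG, k_LN, k_PG (kN/m).
_PARTICIPANTS = [
    ("F", 37, 1.70, 0.92, 58.9, 7.84, 7.8, 7.00, 8.00),
    ("F", 22, 1.53, 0.86, 60.0, 7.98, 8.4, 8.44, 8.00),
    ("F", 23, 1.70, 0.87, 60.6, 8.08, 7.8, 8.44, 8.00),
    ("F", 25, 1.65, 0.87, 62.0, 8.24, 7.8, 8.44, 8.00),
    ("F", 26, 1.73, 0.93, 62.8, 8.36, 8.2, 8.44, 8.00),
    ("F", 26, 1.62, 0.84, 62.9, 8.38, 7.8, 8.44, 8.00),
    ("F", 23, 1.59, 0.85, 63.6, 8.46, 7.8, 8.44, 8.00),
    ("M", 43, 1.63, 0.94, 65.4, 8.70, 8.2, 8.44, 8.00),
    ("M", 20, 1.67, 0.90, 65.9, 8.80, 9.0, 8.44, 9.00),
    ("M", 24, 1.73, 0.94, 67.5, 8.98, 8.2, 8.44, 9.00),
    ("M", 30, 1.79, 0.94, 69.2, 9.22, 8.2, 9.46, 9.00),
    ("M", 25, 1.80, 0.98, 71.6, 9.50, 9.4, 9.46, 10.00),
    ("M", 20, 1.64, 0.86, 75.3, 9.96, 10.6, 9.46, 10.00),
    ("M", 30, 1.73, 0.88, 77.7, 10.34, 10.6, 10.6, 10.00),
]


class SpringValidationError(ValueError):
    """Invalid spring specification or query."""


class ExtrapolationError(SpringValidationError):
    """Tabulated profile queried outside its measured range."""


@dataclass(frozen=True)
class SpringProfile:
    """Force–displacement law with loading and unloading branches.

    ``reference_force`` is the loading-branch force (N) at
    ``reference_displacement`` (m); ``exponent`` shapes the power law
    (ignored for tabulated profiles).  ``hysteresis_fraction`` is the
    fraction of stored energy lost per loading–unloading cycle; the
    unloading branch is the loading branch scaled by
    ``1 - hysteresis_fraction`` in force, which preserves shape and makes
    the energy budget exact.  ``rest_length`` (m) is the attachment
    distance at which compression starts (0 means "not set").
    """

    kind: str
    reference_force: float = 0.0
    reference_displacement: float = 0.10
    exponent: float = 1.0
    hysteresis_fraction: float = 0.0
    rest_length: float = 0.0
    table: Optional[tuple] = None  # (d_load, f_load[, d_unload, f_unload])

    def __post_init__(self) -> None:
        if self.kind not in ("degressive", "linear", "progressive", "tabulated"):
            raise SpringValidationError(f"unknown spring kind {self.kind!r}")
        if not 0.0 <= self.hysteresis_fraction < 1.0:
            raise SpringValidationError("hysteresis_fraction must be in [0, 1)")
        if self.kind != "tabulated":
            if self.reference_force <= 0:
                raise SpringValidationError("reference_force must be > 0")
            if self.reference_displacement <= 0:
                raise SpringValidationError("reference_displacement must be > 0")
            if self.exponent <= 0:
                raise SpringValidationError("exponent must be > 0")
            _check_exponent_kind(self.kind, self.exponent)
        else:
            if self.table is None:
                raise SpringValidationError("tabulated profile requires a table")
            d = np.asarray(self.table[0], dtype=float)
            f = np.asarray(self.table[1], dtype=float)
            if d.ndim != 1 or d.shape != f.shape or d.size < 2:
                raise SpringValidationError("table must be two equal 1-d columns")
            if not np.all(np.diff(d) > 0):
                raise SpringValidationError(
                    "table displacements must be strictly increasing (ties rejected)"
                )
            if d[0] != 0.0 or f[0] != 0.0:
                raise SpringValidationError("table must start at (0, 0)")
            if np.any(f < 0) or np.any(np.diff(f) < 0):
                raise SpringValidationError("table force must be non-negative, non-decreasing")

    @property
    def secant_stiffness(self) -> float:
        """Secant stiffness (N/m) at the reference displacement."""
        if self.kind == "tabulated":
            d = np.asarray(self.table[0], dtype=float)
            f = np.asarray(self.table[1], dtype=float)
            dmax = d[-1]
            return float(np.interp(dmax, d, f) / dmax)
        return self.reference_force / self.reference_displacement


def _check_exponent_kind(kind: str, exponent: float) -> None:
    if kind == "degressive" and not exponent < 1:
        raise SpringValidationError("degressive profile requires exponent < 1")
    if kind == "progressive" and not exponent > 1:
        raise SpringValidationError("progressive profile requires exponent > 1")
    if kind == "linear" and exponent != 1:
        raise SpringValidationError("linear profile requires exponent == 1")


def make_profile(
    kind: str,
    reference_force: float,
    reference_displacement: float = 0.10,
    exponent: Optional[float] = None,
    hysteresis_fraction: float = 0.0,
    rest_length: float = 0.0,
) -> SpringProfile:
    """Build a canonical parametric profile.

    If ``exponent`` is omitted, the canonical calibrated exponent for the
    kind is used (0.47 / 1 / 3.21).
    """
    if exponent is None:
        exponent = CANONICAL_EXPONENTS[kind]
    return SpringProfile(
        kind=kind,
        reference_force=reference_force,
        reference_displacement=reference_displacement,
        exponent=float(exponent),
        hysteresis_fraction=hysteresis_fraction,
        rest_length=rest_length,
    )


def tabulated_profile(
    displacement: Sequence[float],
    force: Sequence[float],
    displacement_unload: Optional[Sequence[float]] = None,
    force_unload: Optional[Sequence[float]] = None,
    hysteresis_fraction: float = 0.0,
    rest_length: float = 0.0,
) -> SpringProfile:
    """Build a tabulated profile from measured loading (and optionally
    unloading) force–displacement pairs."""
    if (displacement_unload is None) != (force_unload is None):
        raise SpringValidationError("unloading branch needs both columns")
    table = (np.asarray(displacement, float), np.asarray(force, float))
    if displacement_unload is not None:
        table = table + (
            np.asarray(displacement_unload, float),
            np.asarray(force_unload, float),
        )
    return SpringProfile(
        kind="tabulated",
        hysteresis_fraction=hysteresis_fraction,
        rest_length=rest_length,
        table=table,
    )


def spring_force(profile: SpringProfile, displacement, branch: str = "loading"):
    """Force (N) at ``displacement`` (m) on the given branch.

    Displacement <= 0 returns 0 (the plates cannot pull on the spring).
    Scalar in, scalar out; arrays are handled element-wise.
    """
    if branch not in ("loading", "unloading"):
        raise SpringValidationError(f"branch must be loading|unloading, got {branch!r}")
    d = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(d)):
        raise SpringValidationError("displacement must be finite")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    dpos = np.clip(d, 0.0, None)

    if profile.kind == "tabulated":
        dt, ft = (np.asarray(a, float) for a in profile.table[:2])
        if branch == "unloading" and len(profile.table) == 4:
            dt, ft = (np.asarray(a, float) for a in profile.table[2:])
            f = _interp_strict(dpos, dt, ft)
        else:
            f = _interp_strict(dpos, dt, ft)
            if branch == "unloading":
                f = f * (1.0 - profile.hysteresis_fraction)
    else:
        with np.errstate(invalid="ignore"):
            f = profile.reference_force * np.power(
                dpos / profile.reference_displacement, profile.exponent
            )
        f = np.where(dpos > 0, f, 0.0)
        if branch == "unloading":
            f = f * (1.0 - profile.hysteresis_fraction)
    f = np.where(d > 0, f, 0.0)
    return float(f[0]) if scalar else f


def _interp_strict(d: np.ndarray, dt: np.ndarray, ft: np.ndarray) -> np.ndarray:
    if np.any(d > dt[-1] * (1 + 1e-12)):
        raise ExtrapolationError(
            f"displacement {float(np.max(d)):.4f} m beyond table range {dt[-1]:.4f} m"
        )
    return np.interp(d, dt, ft)


def spring_force_branched(profile: SpringProfile, displacement, loading_mask):
    """Vectorised force with a per-sample branch mask (True = loading)."""
    d = np.asarray(displacement, dtype=float)
    mask = np.asarray(loading_mask, dtype=bool)
    f_load = spring_force(profile, d, "loading")
    f_unload = spring_force(profile, d, "unloading")
    return np.where(mask, f_load, f_unload)


def stored_energy(profile: SpringProfile, displacement: float, n_points: int = 10_001) -> float:
    """Elastic energy (J) stored on the loading branch up to ``displacement``.

    Computed by trapezoidal quadrature of the loading force–displacement
    curve; for parametric profiles this converges to the closed form
    F_ref * d / (q + 1) at the reference displacement.
    """
    if displacement < 0:
        raise SpringValidationError("displacement must be >= 0")
    if displacement == 0:
        return 0.0
    d = np.linspace(0.0, displacement, n_points)
    f = spring_force(profile, d, "loading")
    return float(np.trapezoid(f, d))


def returned_energy(profile: SpringProfile, displacement: float, n_points: int = 10_001) -> float:
    """Energy (J) returned on the unloading branch from ``displacement``."""
    if displacement < 0:
        raise SpringValidationError("displacement must be >= 0")
    if displacement == 0:
        return 0.0
    d = np.linspace(0.0, displacement, n_points)
    f = spring_force(profile, d, "unloading")
    return float(np.trapezoid(f, d))


def calibrate_exponent(target_energy_ratio_vs_linear: float) -> float:
    """Power-law exponent whose equal-secant stored energy is
    ``ratio`` x the linear spring's.

    Stored energy at the secant point is F_ref*d_ref/(q+1), so the ratio
    against linear (q=1) is 2/(q+1) and q = 2/ratio - 1.
    """
    r = float(target_energy_ratio_vs_linear)
    if r <= 0:
        raise SpringValidationError("energy ratio must be > 0")
    if r >= 2:
        raise SpringValidationError("energy ratio >= 2 would require exponent <= 0")
    return 2.0 / r - 1.0


@dataclass(frozen=True)
class PrescriptionModel:
    """Body-mass-proportional stiffness prescription.

    ``constant`` is stiffness per unit mass (kN m^-1 kg^-1, both legs'
    springs summed, characterised at 10 cm of compression); prescribed
    stiffness is reported rounded to ``rounding`` decimals.
    """

    constant: float
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.constant <= 0:
            raise SpringValidationError("prescription constant must be > 0")


def participant_table() -> pd.DataFrame:
    """The 14-participant characteristics table (masses, leg lengths and
    the calculated and as-built spring stiffnesses, kN/m for both legs)."""
    return pd.DataFrame(
        _PARTICIPANTS,
        columns=[
            "sex", "age_yr", "height_m", "leg_length_m", "mass_kg",
            "k_calc_kN_per_m", "k_dg_kN_per_m", "k_ln_kN_per_m", "k_pg_kN_per_m",
        ],
    )


def calibrated_prescription(rounding: int = 2) -> PrescriptionModel:
    """Prescription model with the constant fit from the participant table
    (mean of k_calc / mass over the 14 rows, ~0.1330 kN m^-1 kg^-1)."""
    t = participant_table()
    c = float((t.k_calc_kN_per_m / t.mass_kg).mean())
    return PrescriptionModel(constant=c, rounding=rounding)


def prescribe_stiffness(mass: float, model: Optional[PrescriptionModel] = None) -> float:
    """Prescribed total exoskeleton stiffness (kN/m, both springs summed)
    for a participant of ``mass`` kg."""
    if mass <= 0:
        raise SpringValidationError("mass must be > 0")
    if model is None:
        model = calibrated_prescription()
    return round(model.constant * mass, model.rounding)


def profile_for_condition(
    condition: str,
    mass: float,
    reference_displacement: float = 0.10,
    hysteresis_fraction: float = 0.0,
    model: Optional[PrescriptionModel] = None,
    exponents: Optional[dict] = None,
) -> Optional[SpringProfile]:
    """Per-leg spring profile for a trial condition (NH/DG/LN/PG).

    The prescription gives the summed stiffness of both legs' springs, so
    each leg's spring carries half the reference force.
    """
    condition = condition.upper()
    if condition == "NH":
        return None
    kinds = {v: k for k, v in CONDITION_CODES.items()}
    if condition not in kinds:
        raise SpringValidationError(f"unknown condition {condition!r}")
    kind = kinds[condition]
    k_total = prescribe_stiffness(mass, model) * 1e3  # N/m
    f_ref_leg = 0.5 * k_total * reference_displacement
    exponent = (exponents or CANONICAL_EXPONENTS)[kind]
    return make_profile(
        kind,
        reference_force=f_ref_leg,
        reference_displacement=reference_displacement,
        exponent=exponent,
        hysteresis_fraction=hysteresis_fraction,
    )


def with_rest_length(profile: SpringProfile, rest_length: float) -> SpringProfile:
    if rest_length <= 0:
        raise SpringValidationError("rest_length must be > 0")
    return replace(profile, rest_length=rest_length)
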