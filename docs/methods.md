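# Methods

## Spring model

The three stiffness profiles are represented as a one-parameter power-law
family through the origin,

    F(d) = F_ref · (d / d_ref)^q ,   d ≥ 0 (clamped to 0 otherwise),

constrained at the secant point: every profile exerts `F_ref` at the
reference compression `d_ref` (default 0.10 m, where all springs were
characterised). Stored energy at the secant point is then
`F_ref · d_ref / (q + 1)`, so the energy ratio of any profile against the
linear spring (q = 1) is `2 / (q + 1)`. The default exponents are
calibrated from the published stored-energy ratios rather than from raw
bench curves, which are not available: q = 0.47 makes the degressive
spring store 36% more than linear, and q = 3.21 makes it store 186% more
than progressive (`calibrate_exponent` inverts `2/(q+1)` for any target
ratio). Measured curves can be supplied instead as tabulated profiles
(monotone piecewise-linear, strictly increasing displacements, no
extrapolation beyond the table).

Hysteresis: the unloading branch is the loading branch scaled by
`1 − hysteresis_fraction` in force, which preserves the curve shape and
makes the energy budget exact (energy returned per cycle =
`(1 − h) ×` energy stored). Published loss fractions per spring kind are
not available, so `h` defaults to 0 and is configurable. Branch switching
keys on the sign of the compression rate, holding the previous branch at
zero rate.

Stiffness prescription: total (both-legs) stiffness is proportional to
body mass. The constant defaults to the mean of stiffness/mass over the
14-row participant table (0.13304 kN m⁻¹ kg⁻¹); the published rounded
figure 0.132 can be substituted in config. The published per-participant
stiffnesses are not exactly mass-proportional (ratios span
0.1323–0.1335 kN m⁻¹ kg⁻¹, presumably because the original prescription
used unrounded per-participant measurements), so the proportional model
reproduces 6 of 14 table rows to two decimals and all rows within
0.06 kN/m (~0.6%).

## Synthetic hopper

The generator emulates stationary bilateral hopping at 2.4 Hz with a
0.26 s contact time. Design choices:

- **GRF first, kinematics after.** The summed vertical GRF during contact
  is `F(t) = F_peak sin^γ(π t / t_c)` with `F_peak` fixed by impulse
  balance (mean force over a full cycle = weight), aerial force exactly
  zero. γ (default 2.7, dimensionless) shapes the pulse; at 66 kg the
  defaults give a 2.34 kN peak and an 11 cm contact-phase CoM drop,
  inside the study's observed ranges. The CoM height is the double
  integral of `F/m − g` (trapezoid at 50 µs, ballistic closed form in the
  air), so the emitted GRFs and CoM are consistent by construction.
- **Posture as a one-parameter family.** Joint angles interpolate linearly
  (in a compression coordinate c) from a touchdown posture (ankle 135°,
  knee 165°, hip 177° — on the toes, knee pre-flexed, hip over the toe)
  with per-joint angular amplitudes proportional to
  `joint_amplitude_weights` (default 0.6 / 0.3 / 0.1 ankle / knee / hip,
  scaled by 120°). Per sample, c is solved so that forward kinematics
  about the fixed toe contact point reproduces the required hip height;
  aerial posture is frozen at the extended touchdown configuration. The
  defaults make the positive-power distribution ankle-dominant
  (~66 / 19 / 14%, human hoppers show ~66–69 / 26–31 / 3–5%) and keep the
  knee anterior to the exoskeleton's line of action throughout contact.
- **Bilateral symmetry.** Legs are mirrored onto one sagittal marker set;
  each leg's force plate reads half the summed pulse, with the centre of
  pressure fixed at the toe (forefoot contact, matching the shoe mount
  near the metatarsal heads).
- **Exoskeleton geometry.** The hip attachment rides at the hip joint
  centre on the (upright) pelvis and the foot attachment 2 cm above the
  toe in the foot frame; both are configurable. The spring's rest length
  is the attachment distance of the extended posture, so compression
  starts exactly at ground contact and the spring is slack (clamped at
  zero; it cannot be stretched by the plates) throughout the aerial
  phase. Ground truth (spring displacement, force, line of action,
  per-joint moment arms and signed moments) is evaluated analytically
  from the same geometry and the spring law. With the hip attachment
  exactly at the joint centre the device exerts no hip moment; a
  posterior offset reproduces the hip-flexion-moment observation but then
  the hip's exoskeleton power is positive during loading and negative
  during recoil, and the sum of per-joint positive-part powers exceeds
  the spring's delivery by exactly that rectified hip term (positive
  parts are subadditive) — worth remembering when auditing real data.
- **Exoskeleton mass** defaults to 1 kg per exo leg (unvalidated; the
  device's mass is not published), carried half at the foot attachment
  and half at the hip.
- **Cohorts.** `emit_cohort` draws participant mass ~ N(66, 5.7) kg and
  leg length ~ N(0.90, 0.04) m (segments scaled with leg length),
  prescribes per-condition springs by body mass, and applies optional
  additive per-condition parameter offsets. With zero offsets the cohort
  is a null model for the statistics.

What the generator deliberately does **not** emulate: segment-inertia
feedback into the GRF (the pulse comes from point-mass dynamics, so
inverse-dynamics checks against it carry a documented 5% RMS allowance at
the ankle), human adaptation to the device (the hopper keeps the same GRF
and kinematics under every spring, so the exoskeleton's power share is
larger than adapting humans show, e.g. ~49% of ankle power with DG
springs), exoskeleton force feedback into the GRF waveform, soft-tissue
artefact, frontal-plane motion, and balance. Passing tests therefore
validate the *estimator chain*, not human behaviour.

## Signal processing and events

Markers and GRFs are filtered with a zero-phase (forward–backward)
Butterworth low-pass, effective 4th order at 20 Hz (two passes of order
2; gain at the cut-off is 0.5), odd-reflection padding of at least three
filter lengths. Contact events use a 20 N threshold on the summed
vertical GRF (onset at the first sample ≥ threshold, toe-off at the first
sample below, 10 ms debounce, partial first/last cycles dropped); a hop
cycle runs onset-to-onset. Kinetics are computed on the 200 Hz marker
clock after decimating the filtered 1000 Hz GRFs (anti-aliased,
integer-ratio); time-normalised curves use 101 points.

Two threshold subtleties, both consequences of a 20 N criterion on a
~2.3 kN pulse: (1) the crossing sits ~14 ms inside the true pulse, so
threshold-detected contact times are ~28 ms shorter than the pulse width
(the generator emits its analytic crossing times as ground truth, and
detection matches them within one sample on raw pulses, within ~2 ms
after the prescribed filtering); (2) the spring is already loaded before
the crossing, so the pipeline nulls the spring only in the interior of
aerial phases, beyond a 25 ms guard around each event, and relies on the
rest-length clamp elsewhere.

## Inverse dynamics and decomposition

Bottom-up planar Newton–Euler over foot → shank → thigh per leg, with
Winter-style segment parameters stored in a versioned YAML table
(masses 0.0145/0.0465/0.100 of body mass; CoM at 0.5/0.433/0.433 of
segment length from the proximal end; gyration radii 0.475/0.302/0.323).
Accelerations come from double central differences of filtered marker
positions. The exoskeleton's weight enters as a point mass at the foot
attachment (the hip-side half rides on the pelvis, proximal to every leg
joint, and cannot load them). Net moments are mapped to the
extensor/plantarflexor-positive convention with the per-joint sign table
documented in `hopexo.exo` (ankle −, knee +, hip − applied to
counter-clockwise moments of a leg facing +x); joint power is the net
moment times the inter-segment angular velocity, so `P = M·ω` holds per
sample. In 2D, "resolving in the proximal segment's frame" reduces to
this single scalar moment.

The exoskeleton contribution uses the attachment markers only: axial
force along the attachment line (pin joints at both ends), per-joint
moment = force × perpendicular distance with the sign from which side the
line passes, per-joint power = moment × angular velocity, and each joint
treated independently. MTU series are the per-sample residuals. The
overestimation audit (`exo_power_check`) integrates the positive parts:
summed per-joint exoskeleton average positive power must not exceed the
spring's own delivered average positive power (`F · dL/dt`, positive
part). In the continuum the two sides are identical here (zero hip arm,
sign-synchronised ankle/knee), so the audit carries a 1% allowance for
the finite-difference velocity estimates and is scored per trial
(per-cycle values are reported as diagnostics; with 1 mm marker noise and
few hops, single trials can exceed the allowance by ~1–2% in either
direction). The alternative decomposition route — subtracting the
estimated exoskeleton force from the vGRF before inverse dynamics — is a
possible comparison mode, deliberately not the default.

## Power metrics

Positive-part trapezium integration with the zero crossings of each
sign-changing segment interpolated linearly (no dead band), per leg, then
summed across legs, divided by the onset-to-onset cycle duration, and
averaged over the last 20 complete cycles (configurable; all cycles when
fewer). Percentages are taken against `P̄_tot`, the sum of the three
overall joint means.

## Statistics

One-way repeated-measures ANOVA via the classical balanced within-subject
decomposition (error term = condition × participant interaction,
df = (k−1, (k−1)(n−1))), identical to the mixed-model route for a
complete crossed design; incomplete designs raise rather than impute.
With all condition means equal F is exactly 0. Post hoc paired t-tests
over all k(k−1)/2 pairs use the Sidak adjustment `1 − (1 − p)^m` and by
default run only when the main effect is significant at α = 0.05 (a flag
disables the gate). Sphericity corrections are off by default;
Greenhouse–Geisser is available. Type-I calibration is audited on
outcome-level null cohorts (participant random effect + residual noise,
zero condition effect): 1000 replicates give rejection rates of
0.038–0.045 at α = 0.05.

## Numerical choices and problem sizes

- Quadrature: trapezoid, 10⁴ nodes for spring energies (matches the
  closed form to <0.01%).
- Generator integration: 50 µs grid over one contact phase; posture
  inversion by interpolation on a 3001-point monotone compression grid
  (validated monotone, error otherwise).
- Test and acceptance problem sizes: 6–20-hop trials, 6-participant
  cohorts, 1000-replicate null calibrations — each stage runs in seconds
  on one core; the full suite takes well under a minute.
- Parameter-recovery comparisons exclude ±25 ms around each contact event
  (the step-response window of the zero-phase filter, which rings at the
  touchdown velocity kink) and the first/last cycles (filtfilt edge
  transients). Within that window, noiseless exoskeleton-moment recovery
  is exact to ~0.03% of peak; with 1 mm marker noise it stays within ~1%.

## Known limitations

- Sagittal-plane only; 3D input is projected by dropping the mediolateral
  axis (with a warning when out-of-plane excursion is large).
- Single-segment foot; single-marker joint centres; pelvis represented by
  the global vertical (hip angle assumes an upright trunk).
- The generator's non-adapting hopper overstates device assistance
  relative to humans, and its GRF ignores both segment inertia and the
  exoskeleton's force path (the spring can carry more than 20 N while the
  modelled plate reads less near contact edges).
- The mass-proportional stiffness prescription approximates, but cannot
  exactly reproduce, the published per-participant stiffness table (see
  the spring section).
- C3D binary files are not parsed; convert to TRC upstream.
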