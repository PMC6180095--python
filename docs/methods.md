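# Methods

## Signal metrics

Impact kinematics are uniformly sampled scalar/triaxial series. The
low-pass filter is a 2-pole Butterworth designed by bilinear transform at
the signal's sampling rate and applied once forwards and once backwards
(`scipy.signal.filtfilt`), giving zero phase lag and a combined magnitude of
1/2 at the cutoff (each pass is −3 dB there). The standards' exact
recommended coefficient algorithm ships with verification data we do not
have, so the filter is instead verified by its defining properties: unit DC
gain, zero phase on symmetric pulses, and the two-pass half-amplitude point
at the cutoff. Edges are reflect-padded by three filter orders and cropped,
which suppresses startup transients on short impact records.

HIC is maximized exactly over all ordered sample pairs using a cumulative
trapezoid precomputation (O(n) setup, O(n²) scan, vectorized row-wise so
memory stays O(n)). No resampling happens inside `hic`; the integration
grid is the stored grid, which makes results reproducible across machines.
Two numerical choices matter:

- **Negative means.** A resultant is non-negative, but zero-phase filtering
  can produce small negative excursions; window means ≤ 0 contribute zero
  rather than a complex power.
- **Tie-break.** Among windows tied within 1e-12 relative, the shortest and
  then earliest is returned, so an all-zero trace deterministically yields
  value 0 on the first adjacent sample pair.

Default synthetic pulses are sampled at 20 kHz, comfortably above the
2077.5 Hz HIC cutoff.

## Headform drop model

The drop is reduced to one degree of freedom: indentation x of a rigid
hemispherical headform (mass 4.6 kg, radius 0.08 m by default) into a
surfacing layer of thickness h = 0.10 m. The loading force is
F = scale·σ(x/h)·A(x) with σ the uniaxial loading curve (linear
interpolation; the last segment extrapolates linearly) and
A(x) = min(π(2Rx − x²), πR²) the spherical-cap contact area. This treats
the layer as a nonlinear spring whose stiffness grows with contact area —
a deliberate simplification: no 3-D stress spreading, no rate dependence,
no friction, no neck/torso coupling.

Unloading multiplies the loading force by

    s = 1 − (1 − hu)·(1 − W/W_max)^shape

where W(x) is the strain energy stored on the loading curve at the current
indentation and W_max its running maximum since first contact. Because W is
a state function of x, s is well defined at every integration stage:
s = 1 at the unloading onset (force continuity), s → hu as the layer
relaxes, and reloading before separation retraces the same branch until the
stored energy re-attains W_max. hu is therefore the force fraction retained
at full unload and shape the curvature of the hysteresis loop; the defaults
0.5 and 2.0 are the values used for rubber-composite playground tiles. The
commercial solver's exact unloading law is proprietary — this energy-based
form reproduces its documented semantics, not its implementation.

Integration is classical fixed-step RK4 at dt = 1 µs from first contact
(x = 0, ẋ = √(2gh), g = 9.81 m/s², which keeps the 1.59 m ↔ 5.59 m/s pair
exact to 3 significant figures) until separation (x back to 0 moving
upward). Halving the step changes HIC by well under 0.1 %. The acceleration
trace is the accelerometer reading F/m in g; by default it is emitted at
the integration step, but the HIC pipeline helpers request a 20 kHz output
grid (≈10× the HIC filter cutoff) so the exact O(n²) window scan stays
cheap. A zero impact velocity is degenerate — no impact occurs — and is
returned as the static equilibrium (contact force balancing weight, zero
acceleration trace, zero energy flow) rather than integrating an undamped
settling that never separates.

**Energy audit.** energy_in and energy_returned are force–displacement
integrals over compression and restitution; energy_dissipated is their
difference. The independent check (in tests and the acceptance script)
compares energy_in with ½mv² + mg·x_max from kinematics; it closes to ~1e-6
relative at the default step.

**Baseline material.** The measured rubber-composite loading curve exists
only as a figure, so the package ships a convex parametric family
σ(ε) = E1·ε + E3·ε³ (E1 = 0.24 MPa, E3 = 2.7 MPa, tabulated to ε = 1),
chosen once so that the default geometry's critical height lands at the
1.59 m a standard-passing tile exhibits. Absolute force levels for other
families flow through `calibrate_scale`, which bisects the stress scale on
a log axis until a drop from a target height produces a target HIC
(±0.5 %). Consequences: orderings and magnitudes are meaningful (stiff ×5
→ 1.15 m, soft ×0.2 → 2.24 m critical height, correctly bracketing the
baseline), but the published stiff/soft critical heights (0.79 m / 3.26 m)
are not exactly reproducible without the measured curve ordinates — the
reduced-order model also compresses the spread relative to a full-contact
finite-element drop. The HIC time window at the baseline critical height
comes out at ~8 ms, the right scale for such impacts (reported ~6.3 ms).

**Critical height** is found by geometric bracket expansion from 0.5 m
followed by bisection to 5 mm on the monotone height–HIC response (each
evaluation = drop + 2077.5 Hz filtfilt + unlimited HIC); monotonicity is
verified on the bracket ends and violations raise a diagnostic error with
the probed (height, HIC) pairs. Bisection rather than a secant method:
robust on responses with small integration noise. A peak-g stopping rule
can be substituted by passing a custom `hic_fn`.

## Tissue metrics

MPS is the 95th percentile over brain elements of per-element peak first
principal Green–Lagrange strain — the percentile (not the raw maximum)
avoids single-element numerical artefacts. Percentile convention: linear
interpolation between closest ranks (rank 1 + 0.95(n−1) on the sorted
values), unweighted by element volume; the convention is fixed and
documented because reported MPS values depend on it. Element maxima over
time are taken first, the percentile over elements second, matching the
reporting of one MPS per impact. Skull injury screening uses the plain
field maximum of von-Mises stress. The 0.3 strain threshold (≈50 % mild-TBI
risk) is configurable.

## Age statistics

The direction spread statistic is 100·(max − min)/max. Direction averages
are arithmetic means per age; the error bars are the min/max range across
the three impact directions, the simplest dispersion statistic for n = 3.
Age trends are fitted by ordinary least squares (linear) or by
a·exp(b·age) — the simplest two-parameter exponential, initialized
log-linearly and refined by nonlinear least squares on the original scale;
R² is always computed on the original scale. The HIC–MPS relation is an OLS
line through the direction-averaged per-age points, evaluated at the strain
threshold. Age-dependent threshold scaling uses the tissue ratio rule
threshold(age) = HIC_ref · tissue(ref)/tissue(age), which returns exactly
the reference HIC at the reference age; other scaling arithmetics can be
layered on top.

## Synthetic data

Generators are bit-reproducible per seed (`numpy.random.default_rng`).

- **Pulses**: haversine a(t) = peak·sin²(πt/duration) by default (smooth,
  impact-like, closed-form checkable); triangle and constant shapes for
  closed-form HIC tests. Angular channels are scaled copies governed by a
  rotation factor (low for front impacts, high for back/side, mirroring the
  much larger rotational response off-axis), with the angular velocity as
  the time integral of the angular acceleration.
- **Tables**: metric(age, direction) = (intercept + slope·age)·offset(dir)
  (+ optional Gaussian noise). Direction offsets are normalized to mean 1
  and taken from the published 3-year-old triples where printed (HIC, peak
  linear acceleration) or chosen to reproduce the published direction
  spreads (66.5 % / 58.3 % for rotational kinematics, absolute scales
  invented at realistic head-impact magnitudes). Intercept and slope are
  solved at import time so the zero-noise table reproduces the published
  anchors exactly: HIC 975.3 at (1.5 y, back) and 610.9 at (18 y, side),
  peak accelerations 145.1 g and 118.7 g, brain-strain averages 0.363 at
  1.5 y and 0.29 at 10 y. The skull-stress column decays exponentially with
  age (~50 MPa at birth scale to ~15 MPa at 18 y, invented) so the
  exponential fit recovers it with R² = 1 at zero noise.
- **Strain fields**: lognormal draws rescaled multiplicatively so the 95th
  percentile hits the target exactly (the percentile is homogeneous of
  degree 1).

What the generators do *not* emulate: real pulse waveforms (only their
structure), suture-anatomy effects on skull stress beyond monotonicity,
inter-age correlation of noise, and any nonlinearity of the true age
trends. Passing tests therefore demonstrate that the analysis stack
recovers the structure it assumes — not that real playground falls follow
linear age trends.

## Problem sizes

Default test and acceptance runs use 20 kHz signal grids (hundreds of
samples per pulse), 1–2 µs integration steps (10⁴–10⁵ steps per drop),
~13 drop evaluations per critical-height search, 21-row kinematics tables
(7 ages × 3 directions) and 10³-element strain fields. These sizes make the
full pipeline run in seconds while keeping discretization error far below
every stated tolerance.

## Known limitations

- The drop model is 1-DOF: no body coupling, no rotational kinematics, so
  it cannot reproduce direction-dependent or tissue-level results — those
  enter through tables computed elsewhere or synthesized.
- Critical heights for rescaled families are compressed relative to
  full-scale experiments (see above); orderings are trustworthy, absolute
  values depend on the shipped parametric curve.
- The hysteretic law is quasi-static; strain-rate stiffening of rubber is
  not modelled, which mainly affects very soft, deep-indentation impacts.
- MPS percentiles are unweighted by element volume; on strongly non-uniform
  meshes a volume-weighted percentile would differ.
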