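# Methods

## Signal chain

A wheel-hub gyroscope's Y axis measures wheel angular rate θ̇ in °/s at a
nominal 60 Hz. The kinematics pipeline is fixed in this order:

1. **Onset** — first sample with |θ̇| > 10 °/s. The absolute value is used
   because a sensor mounted on the left hub negates the whole trace; the
   threshold itself (10 °/s ≈ 0.05 m/s at r = 0.3 m) is far above gyro
   noise yet small enough that the onset shift it introduces (< 20 ms at
   sprint accelerations) is absorbed by the fitted time offset t0.
2. **Conversion** — ω = (π/180)·θ̇, v = ω·r. Orientation is fixed by the
   sign of Σω; after fixing, ≥ 99 % of processed samples are non-negative
   on traces of either mount side.
3. **Filtering** — 5th-order Butterworth low-pass at 4.5 Hz, applied
   forward–backward (`scipy.signal.filtfilt`). Zero-phase filtering is
   chosen over causal because phase lag would bias the acceleration time
   constant; the squared magnitude response leaves a 9 Hz component at
   ≤ 1e-3 of its amplitude while passing 0.1 Hz within 1 %. The filter is
   applied to the *translational velocity* of the whole record (maximal
   context keeps edge transients away from the sprint), before cropping.
4. **Crop** — onset through the global velocity maximum, inclusive; ties
   break at the first maximum (earliest plateau attainment). The sprint
   model describes only the acceleration phase.
5. **Time normalization** — linear interpolation onto 1000 uniform points
   over [0, t_peak]. Only the sample count is normalized; time stays in
   seconds so τ keeps physical units. At 60 Hz the interpolation error for
   a mono-exponential is bounded by h²·max|v″|/8 ≈ 1.1e-4 m/s.

## Sprint model and fit

V(t) = Vmax·(1 − e^(−(t−t0)/τ)), a(t) = (Vmax/τ)·e^(−(t−t0)/τ), so
a·τ + V ≡ Vmax. Fitting is bounded nonlinear least squares
(`scipy.optimize.least_squares`, ftol 1e-10) on the 1000-point resampled
trace, uniform weights. Initialization: Vmax₀ = max observed velocity,
τ₀ = time to reach 63.2 % of Vmax₀, t0₀ = 0; bounds Vmax ∈ (0.5, 15],
τ ∈ (0.05, 10], t0 ∈ [−0.5, 0.5]. Up to 5 deterministic-by-seed jittered
restarts on solver failure. t0 is a free onset-offset parameter: a pure
sign flip of t0 in the exponent is observationally equivalent, so the
convention V(t0) = 0 (velocity zero at the effective start) is adopted.
Goodness of fit is rmse and r² of modelled vs measured velocity.

## Resistive-force models

**AF**: SA = 0.2025·H^0.725·m^0.425·0.266 (Du Bois-type scaling with a
frontal-area fraction), ρ = 1.293·(P/760)·(273/(273+T)),
k = ½·ρ·SA·0.9, F_R = k·(V−V_wind)². Indoors V_wind = 0.

**CRF**: C_D(V) = 0.2955/(V+0.0762) + 0.1608,
C_L(V) = 0.2099/(V+0.1218) + 0.1666,
μ = (m·a + C_D·V²)/(m·g + C_L·V²), F_R = μ·m·g, g = 9.81 m/s².
The drag/lift constants are read as rational functions of velocity — the
only reading with finite positive asymptotes (0.1608, 0.1666), which is
what a velocity-dependent drag/lift characterization of a rugby chair
produces; a linear reading would grow without bound.

Both resistive forces are positive magnitudes added in
F_net = m·a + F_R: resistance is load the athlete must overcome, so it
adds to the propulsive force estimate. Under this convention the CRF
model's F_net is ≥ the AF model's at every point of a fitted sprint, and
at V → 0 the ratio is exactly 2, because μ reduces to a/g and F_R to m·a.
This doubling is a deliberate property of the published CRF formulation:
μ's numerator embeds the inertial term, so adding μ·m·g to m·a counts
inertia twice relative to a strict free-body reading. The package
reproduces that computation as its default — its force/power outputs are
the ones that align with direct ergometer dynamometry of comparable
athletes — and exposes `strict_freebody=True` (μ without the m·a term)
for sensitivity analyses only.

**Pressure units.** The density formula divides pressure by 760, a mmHg
convention. The package treats "pressure" as formula units with reference
value 760 throughout and provides `pressure_from_hpa` (reference 1013.25)
for barometers reporting hectopascal.

## FV outcomes

OLS of F_net on V over all 1000 modelled points, unweighted, no trimming:
intercept F0, slope < 0. V0 = −F0/slope, Pmax = F0·V0/4, per-kg slope =
slope/m (only the per-kg normalization is comparable across athletes).
DRF is the OLS slope of RF = 100·F_net/√(F_net² + (m·g)²) against V, with
m the *system* mass (athlete + chair — the same m as the net-force
equation). This ratio-of-force definition is the standard sprint-mechanics
one; evaluating it on linear profiles built from published wheelchair-rugby
cohort means (F0 282.1 N, V0 4.63 m/s, m 87.66 kg; F0 139.1 N, V0 4.80 m/s)
returns −6.76 and −3.33 %·s/m, matching the published DRF values (−6.794,
−3.309) and confirming the reconstruction. The instantaneous-power maximum
is kept as a secondary diagnostic (within ~15 % of F0·V0/4 on realistic
sprints; the FV curve is not exactly linear under either model).

## Cohort statistics

Mean ± SEM per metric and model, SEM = sample sd (n−1)/√n. Two-sided
paired t-tests on per-sprint CRF−AF differences, α = 0.05, no
multiple-testing correction across the five metrics. Published reference
values can be "velocity-corrected" to a target V0 along their own FV line
(F0′ = −slope·m·V0′, Pmax′ = F0′·V0′/4); this is a best-effort
reconstruction, flagged as such, that only round-trips exactly for a
self-consistent reference (F0 = −slope·m·V0 — published rows normalized
to their own cohort mass are generally not, with m = 87.66).

## Synthetic data

The generator inverts the measurement chain: mono-exponential velocity →
wheel angular rate → 60 Hz samples → additive white Gaussian noise on the
gyroscope signal (where sensor noise physically enters), optional
quantization. Cohort defaults emulate a national rugby squad: body mass
69.51 ± 12.08 kg, chair mass 18.15 ± 1.15 kg (system 87.66 ± 12.59 kg),
seated stature 1.1905 ± 0.0576 m, wheel radius U(0.25, 0.32) m, Vmax
truncated-normal 4.6 ± 0.5 on [3.5, 5.5] m/s, τ 1.4 ± 0.35 on
[0.8, 2.5] s, two 8 s trials per athlete (≥ 5τ guarantees the plateau a
45 m sprint is chosen to provide). All randomness flows from one explicit
seed.

The default noise, 100 °/s, is an *effective* level: MEMS gyro noise
alone is < 1 °/s, but real sprint traces carry per-push velocity ripple
of a few tenths of m/s about the mean path. Lumping both into white
gyro noise yields a post-filter velocity residual of ≈ 0.2 m/s
(pre-filter σ_v = (π/180)·100·r ≈ 0.44–0.56 m/s, reduced ×0.37 by the
4.5 Hz filter), placing per-sprint fit quality in the rmse 0.1–0.35 m/s,
r² 0.90–0.99 band typical of mono-exponential fits to real wheel-hub IMU
sprints. What the synthetic data does *not* emulate: push-cycle
periodicity (noise is white, not ~1–2 Hz structured), fatigue within a
trial, curvilinear deviations, or clock jitter. Passing tests therefore
demonstrate correct recovery of the *mean-path model* under realistic
residual magnitudes, not robustness to every artifact of field data.

## Numerical choices and edge cases

- Crop ties → first maximum; velocity maximum at the first sample →
  degenerate-sprint error; all-below-threshold trace → no-sprint error.
- Fit preconditions: ≥ 10 samples, velocity range > 0.5 m/s; zero-variance
  measured series makes r² undefined (error, not NaN).
- Paired tests need ≥ 3 complete pairs and nonzero difference variance;
  identical columns are flagged degenerate rather than tested.
- Generic-dialect CSV round-trips bit-for-bit (shortest-repr floats,
  `float_precision="round_trip"` on read). NaN rows are dropped and
  counted, never imputed. Stature > 3 m is treated as a cm-unit slip and
  divided by 100 with a warning.
- fs is inferred from the median Δt; >1 % deviation from 60 Hz warns but
  does not fail (consumer IMU clocks jitter).

## Problem sizes

Validation uses a 3×3 noise-free parameter grid (Vmax ∈ {3.5, 4.5, 5.5},
τ ∈ {0.9, 1.4, 2.2}), 20-seed Monte Carlo at 5 °/s noise, and 18-athlete
× 2-trial cohorts — sizes at which every stochastic check is stable
across seeds while the full suite runs in seconds.

## Known limitations

- The CRF drag/lift constants characterize one class of rugby chair on
  specific surfaces; no tire-pressure or surface variants are provided.
- Table-level cohort means from real athletes are not reproducible here
  (the underlying data are not shareable); synthetic-cohort FV-slope
  magnitudes depend directly on the chosen τ distribution and with
  τ ∈ [0.8, 2.5] s exceed those of the slower real cohort (a real squad's
  effective τ ≈ 3 s would bring them down proportionally).
- The velocity-corrected reference adjustment is a labelled
  reconstruction, not a reproduction of any published figure.
- No curvilinear kinematics, distance gating, multi-IMU fusion, or
  roll-down-based resistance estimation.
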