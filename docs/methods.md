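# Methods

This note documents the models, numerical choices and validation logic of
the package: what is simulated, what is fitted, which knobs matter, and
what passing tests do and do not demonstrate about real tracked data.

## Units

Internally everything is in mm, mg, ms: inertia in mg·mm², density in
mg/mm³ (numerically equal to g/cm³), speed in mm/ms (numerically equal to
m/s), gravity g = 9.81×10⁻³ mm/ms². Angular velocity is rad/ms inside the
integrator and reported in rev/s everywhere public, under the convention
1 Hz = 2π rad/s. Take-off performance constants: air density
ρ = 1.2 kg m⁻³, dynamic viscosity μ = 18.3×10⁻⁶ Pa s.

## Mesh mass properties

Volume, centre of mass and the inertia tensor of a closed triangular mesh
are computed exactly for the polyhedron by divergence-theorem accumulation
over signed origin tetrahedra; the second-moment matrix of each
tetrahedron uses the closed form C = (V/20)(Σ pᵢpᵢᵀ + ssᵀ). Uniform
density is assumed throughout (per-segment densities are out of scope).
Non-watertight meshes are rejected with the offending open edges listed;
inverted winding (negative signed volume) is auto-corrected with a
warning. Validation: cuboid, sphere and capped cylinder agree with their
closed-form inertias within 1% at the tested refinements, and the tensor
about the COM is invariant under rigid translation to ~1e-9 relative.

**Axis naming.** Principal axes are matched to anatomical roles by
proximity: pitch is the eigenvector closest to the transverse direction
(moment I₂); of the remaining two, roll is the one closest to the
cranial–caudal axis (I₁) and yaw the other (I₃). Signs are chosen along
the anatomical directions and right-handedness is enforced via
u₃ = u₁ × u₂. A fully degenerate (spherical) tensor returns the anatomical
triad itself; the proximity-then-smallest-index rule makes near-degenerate
cases deterministic.

## Parametric nymph models

The synthetic nymph is an ellipsoidal body (semi-axes a = L_b/2, b, c)
plus two capsule segments (femur, tibia+tarsus) per leg, posed by joint
angles (azimuth, elevation, knee). Defaults describe a third instar:
L_b = 8.9 mm, mass 28.4 mg, calibrated so the uniform-density model lands
at ≈1.02 g/cm³ (published insect values are ≈1.0). The legs-extended pose
extends fore/mid legs laterally and the hindlegs rearward and crossed; the
legs-tucked pose folds all legs alongside the body. Because no boolean
mesh engine is assumed, the mesh is a concatenation of individually closed
parts with leg roots inset 0.1 mm into the body; the double-counted
overlap is <0.5% of total volume and is absorbed by the density
calibration. With the default geometry the legs account for ~23–55% of
the principal moments (geometry-dependent; real rigged models place this
higher), and leg extension raises the roll moment by ~16%.

**Cross-sections.** Silhouette areas are exact unions of projected
triangles (shapely polygon union) rather than rasterized shadows — exact
union is at least as accurate as any raster resolution and robust to
degenerate triangles after `buffer(0)` cleanup. The minimum enclosing
convex polygon is the union's convex hull.

## Rotational dynamics

The integrator advances the body-frame angular momentum L and the attitude
quaternion with fixed-step RK4:

    dL/dt = L × ω − (ln2/t_char)·L,   ω = I(t)⁻¹·L,
    dq/dt = ½·q ⊗ (ω, 0),  q renormalized each step.

For constant inertia this is algebraically the Euler equations (a test
verifies the equivalence against the direct dω/dt form); the momentum
formulation makes L exactly continuous through inertia changes, so an
instantaneous posture switch reproduces per-axis angular-momentum
conservation ω'ᵢ = (Iᵢ/I'ᵢ)ωᵢ without special-casing.

- **Drag law**: τᵢ = −(ln2/t_char)·Iᵢ·ωᵢ, i.e. exponential decay with
  half-life t_char, applied per body axis with a single shared t_char per
  posture (the two coincide for principal-axis spin). The characteristic
  time blends linearly across the leg-extension window, mirroring the
  inertia schedule. Defaults: 155 ms (tucked), 76 ms (extended).
- **Inertia schedule**: principal moments interpolate linearly per matched
  axis over [t_ext_start, t_ext] (default 0–40 ms); when the two postures'
  principal frames differ, the axis triads blend along the geodesic
  (a₀·exp(f·log(a₀ᵀa₁))), which reduces exactly to per-axis linear
  interpolation for coincident frames.
- **Step size**: default dt = 2.6×10⁻³ ms. RK4 is 4th order (halving dt
  shrinks the attitude error ~16×, verified), so validation ensembles use
  dt = 0.05–0.1 ms where the integration error is still orders of
  magnitude below the fitted quantities' tolerances; conservation checks
  run at the default step. With zero drag and constant inertia, |L| and
  rotational kinetic energy are conserved to better than 1e-6 relative
  over 500 ms.
- Attitudes are unit quaternions throughout, converted to ZYX (yaw-pitch-
  roll) Tait–Bryan angles only at boundaries; gimbal lock (|pitch| = 90°)
  is resolved by roll = 0 plus a flag.

Classical benchmarks: symmetric-top body-frame precession matches
Ω_b = ω₃(I₃−I₁)/I₁ to 0.1%; intermediate-axis spin is unstable while
extreme-axis spins stay bounded (tennis-racket behaviour); principal-axis
spin halves after exactly one t_char (0.5%).

## Trajectory fitting

The ballistic model is parameterized in 3D with an explicit azimuth so
that planarity is testable rather than assumed; all parameters except g
vary freely (Levenberg–Marquardt, initialized from finite differences).
A vertical launch makes the azimuth unidentifiable; it is reported as 0
with a degeneracy flag. RMSE follows the scalar-residual convention
(per-coordinate), directly comparable to the 0.54 mm reconstruction-error
scale; event-window RMSEs (take-off +25 ms, leg extension ±25 ms, impact
−5 ms) are compared with a seeded permutation test (10,000 label
permutations by default) because no specific test is prescribed for
residual differences. The plane fit is total least squares (smallest
principal component); heading comes from per-coordinate quadratic
regression in centred 25 ms windows, with the derivative evaluated at the
window centre.

The maximum-range and flight-time metrics are evaluated at the optimal
angle θ = 45° with the standard projectile forms R = v²·sin(2θ)/g and
t_TOF = 2v·sinθ/g; the sin2θ form is the one consistent with the computed
ranges (≈89 cm at v ≈ 2.95 m/s), whereas a sin²θ variant sometimes quoted
in this context is not.

## Orientation kinematics

Only the cranial–caudal axis u_cc is observable from two tracked points
(roll about u_cc is invisible; full per-frame 3D attitude reconstruction
is out of scope). Its angular speed uses atan2(|uᵢ×uᵢ₊₁|, uᵢ·uᵢ₊₁)/Δt on
consecutive frames — stable near 0 and π — with forward differences at the
native 1 kHz frame rate and no smoothing by default. The take-off angular
velocity vector comes from the relative rotation of two full attitudes
5 ms apart (axis–angle over the interval); a ~180° relative angle is
direction-ambiguous and rejected. Oscillation periods are mean inter-peak
intervals on the series detrended by its fitted decay envelope, with
peaks requiring ≥5% prominence and ≥10 ms separation (both configurable —
these stand in for what was originally a manual measurement). For a
symmetric top the closed-form check is T_osc = π/Ω_b, since
|ω × u_cc| = √(ω⊥²sin²(Ω_b t) + ω₃²) has half the body-precession period.

The Wilcoxon signed-rank and rank-sum tests are implemented in-repo with
exact small-sample null distributions (dynamic-programming enumeration for
n ≤ 25; mid-ranks for ties, zero differences dropped; normal approximation
with tie correction beyond). They are cross-checked against brute-force
sign/subset enumeration and against scipy on tie-free data. Tracked and
simulated ω_cc series are compared after 25 ms boxcar averaging, paired by
window.

## Synthetic data

The generator's defaults are the study conditions: take-off speed 3.0 m/s
(published range 2.7–3.4), launch angle 45°, isotropic Gaussian tracking
noise σ = 0.54 mm (the published reconstruction-error bound; the true DLT
error is anisotropic — a documented simplification), 1000 frames/s,
initial spin (2, 18, 5) rev/s (within the published 5–45 Hz range and
pitch-dominated, as observed), t_ext = 40 ms, t_char = 155/76 ms. Head and
caudal points sit at ±L_b/2 along the simulated attitude's cranial–caudal
axis plus the same noise. Landing outcomes are drawn from a 6×2
orientation × success table whose default marginal makes ventral impacts
most frequent and most successful with overall success ≈122/207. Cohorts
draw specimen-level parameters once per specimen (Gaussian, truncated to
positive support, defaults spanning the published ranges) and trial noise
independently; every trial is bit-reproducible from its seed.

Steering (azimuth drift) and a pre-impact angular-speed kick exist only as
positive controls for the detection code and default off (no steering was
observed; the pre-impact rise seen in a minority of trials has no proposed
mechanism and is modelled phenomenologically).

**What passing recovery tests show — and don't.** At σ = 0.54 mm the
ballistic fit recovers v and θ to ≪1% and R² ≥ 0.96 on every trial, so the
fit-quality floor mirrors real tracked data. The ω_cc noise story is
different: σ = 0.54 mm endpoint noise on a 8.9 mm baseline injects
~0.12 rad of frame-to-frame direction noise, and because ω_cc is a speed
(non-negative), forward differences of noisy directions are biased upward.
Drag-time and oscillation-period recovery are therefore validated on
simulated (noise-free) orientation series, matching how the original
analysis compared simulations with tracked data rather than inverting
noisy tracks; tracked-series extraction at full noise is exercised but
not held to recovery tolerances.

## Landing statistics

Clopper–Pearson bounds come from beta quantiles (lower
Q_Beta(α/2; k, n−k+1), upper Q_Beta(1−α/2; k+1, n−k)), exact by
construction and verified against binomial tail-equation bisection.
Simultaneous multinomial CIs default to Sison–Glaz (matching the R
MultinomCI default) with Goodman as the alternative; for extreme tables
where the Sison–Glaz construction is undefined (all mass in one cell) the
Goodman interval is substituted with a warning. A category is "more
frequent than expected" when its CI excludes 1/6 from above. The
chi-squared two-sample test is the standard 2×K homogeneity statistic
(zero-margin categories dropped, small-expected-cell warning at <5).
Grand means weight each specimen equally (mean of specimen means); their
95% CI uses the t distribution on specimen means — the CI construction for
published grand means is not stated, so this is a documented assumption
(width 0 for identical means, undefined for a single specimen).

## Problem sizes

Validation ensembles: 200 noisy ballistic trials (60–160 ms flights),
25 + 25 simulated rotation trials (300/500 ms at dt = 0.05/0.1 ms) for
drag-time and precession-period recovery, 48-specimen cohorts for the
fit-quality floor, 250–400 multinomial draws (n = 200) for simultaneous
coverage, and 500 ms conservation runs at the default step. These sizes
put Monte-Carlo error well inside each asserted tolerance.

## Known limitations

- The synthetic nymph is a stylized ellipsoid-plus-capsules model: useful
  for exercising the pipeline and for order-of-magnitude inertia ratios,
  not a replica of any real specimen (leg inertia fractions are lower than
  rigged photogrammetric models give).
- Translational aerodynamics (drag forces on the trajectory), lift/Magnus
  coupling, and multi-link articulated dynamics beyond the two-segment
  throw model are out of scope; the trajectory model is zero-drag by
  design.
- ω_cc extraction from noisy endpoints carries the positive noise bias
  discussed above; quantitative drag fits on real tracks need either
  smoothing or longer baselines.
- The quadratic-drag torque alternative (`DragModel(law="quadratic")`,
  ω(t) = ω₀/(1 + t/t_char) for principal-axis spin) is verified against
  its closed form but not against data; the exponential law is the
  default because it matches the fitted half-life definition exactly.
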