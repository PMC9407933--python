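# Methods

## Coordinate frame and what is modeled

All spatial-strength data live in a body-centered cylindrical frame:
α (degrees) about the vertical body axis with α = 0 in the sagittal
plane and positive toward the measured limb's side; z (cm) height above
the floor; r (cm) radial distance from the body axis. Only the maximum
*upward* lifting force is modeled — the zone is a scalar field
F(α, z, r), not a multi-directional force map. Left/right limb and the
reach-measurement convention (handgrip axis vs fingertip) are stored as
metadata flags on the subject profile; mirroring is never applied as a
geometric transform.

The model is purely phenomenological: it interpolates measured forces
and imposes one physical constraint — force is monotone non-increasing
in r along every (α, z) ray, because lifting capacity drops as the hand
moves away from the body. No muscle physiology, joint torques or
posture simulation is attempted.

## Field construction

`build_strength_field` turns a measured point cloud into a lattice
field in three steps per measured ray (a distinct (α, z) pair):

1. duplicate radii are averaged;
2. the force sequence is projected onto the monotone non-increasing
   cone by least-squares isotonic regression (pool-adjacent-violators);
3. the monotone sequence is piecewise-linearly interpolated in r,
   linearly extrapolated toward the body axis below the innermost
   sample (the innermost segment's slope, clipped at 0 N), and set to
   0 beyond the ray's reach.

Across rays the field is bilinearly interpolated in (α, z). This
requires the measured rays to form a complete α × z grid; a missing
ray, or a ray with fewer than 3 distinct radii, raises a coverage error
naming the deficient ray. A convex combination of non-increasing radial
profiles is non-increasing, so monotonicity survives the blend; a final
running-minimum pass guards the invariant against floating-point drift.

The reach boundary of a measured ray is the supplied per-ray value or,
absent that, the largest measured radius — the measurement protocol
already probes the reach limit, so no separate reach model is imposed.

**Lattice resolution.** Default 5° × 5 cm × 1 cm. This is finer than a
realistic laboratory sampling (~100 force points per subject) while
keeping a desk-scale field a few thousand nodes; the radial step is the
finest because layer geometry and feature extraction read radii off the
lattice. All resolutions are user-settable (`GridSpec`).

## Constant-strength layers and allowable forces

The layer at level L is, per lattice ray, the largest radius at which
the (piecewise-linear) field still reaches L, clamped to the reach
boundary; 0 where L is never reached, and an `empty` flag when L
exceeds the global maximum. Because every radial profile is monotone,
the crossing is unique and found by linear inversion between the two
bracketing lattice nodes. Layers nest by construction: a higher level
can never bound a larger radius.

Laboratory limit forces F are reduced to allowable working forces
F_d = k·F by a single proportional scalar k ∈ (0, 1] (default 1.0 — no
correction). Work-condition corrections (load duration, convenience,
holding time) are deliberately not modeled beyond this scalar; the
choice of k is the ergonomist's. Proportionality means rescaling
commutes with layer extraction: the layer of the rescaled field at k·L
has the geometry of the original layer at L. In floating point this
identity is bit-for-bit when k is a power of two (scaling by 2⁻ᵐ
commutes with IEEE rounding) and agrees to ~10⁻⁹ cm for general k;
tests assert exactly that split.

Layer surfaces are exported as ASCII OBJ or ASCII STL triangle meshes
(units cm, right-handed, z up) for placement in CAD; the surface is the
open sheet swept by the boundary radii over the (α, z) grid.

## Simplified features and matching

The five-feature quick characterization reads the field at defined
points: D1 = reach at (α = 0, shoulder height); F1 and F3 = force at
full and half reach on that ray; F2 = force at full reach at α = 60°,
shoulder height; F4 = force at full reach at α = 0, elbow height.
Boundary forces are evaluated at the last lattice radius inside the
reach (at most one radial step, default 1 cm, short of it). Missing
coverage raises an error naming the feature.

Normalization is min–max against the repository's per-feature extremes,
computed over repository rows only — the query user is excluded, so the
bounds describe the stored population and a user query never shifts
them. User values outside the repository range are clamped to [0, 1]
with a warning; a degenerate interval (max = min) maps every input to 0
with a warning. Both policies are explicit choices for out-of-range
queries, which the matching statistic itself does not define.

The dissimilarity between normalized vectors is the weighted mean
absolute difference, equal weights by default (all five quick
measurements are treated as equally informative; the weight vector is
exposed for sensitivity studies). It is a pseudometric on [0, 1]⁵ with
range [0, 1]. The matcher ranks all entries ascending and returns the
first; ties are broken by table order (stable sort). An optional
acceptance threshold flags — but still reports — a best match whose
total exceeds it; no default threshold is imposed.

**Dual input convention.** The matcher accepts either raw newton/cm
features (normalized internally) or a pre-normalized vector. The
bundled worksheet needs both: its printed user vector contains
f₄ = 0.739, which under the printed bounds corresponds to F₄ = 118 N,
while the listed raw measurement is 110 N (giving f₄ = 0.672 and an
entry-7 total of 0.095 instead of 0.085). The package reproduces both
paths and pins regression tests to the printed vector; it does not
guess which raw value was intended.

All arithmetic is full precision; 3-decimal rounding is display-only.

## Synthetic generator

`generate_icz` emulates a laboratory session with the separable form

    F(α, z, r) = peak · ang(α) · hgt(z) · (1 − ρ·r/reach)^p + ε,
    ε ~ N(0, noise_sd²),  clipped at 0 N,

where ang is a linear angular falloff (fraction of sagittal force
remaining at 60°), hgt a linear height factor equal to 1 at shoulder
height and `elbow_ratio` at elbow height, p ≥ 1 the radial decay
exponent and ρ ∈ (0, 1] the decay fraction: ρ = 1 drives the force to
zero exactly at the reach boundary, ρ < 1 leaves a positive boundary
force, which real subjects exhibit (the tuned worksheet subject has
88 N at full reach). `spec_for_features` inverts the p = 1 form so a
generated subject reproduces a target five-feature vector exactly in
the noiseless limit.

Default sampling is 5 angles × 4 heights × 5 radii = 100 points, the
scale of a realistic measurement session. A single seeded generator
drives all noise; generation is bit-reproducible per seed.

What the generator does *not* emulate: postural coupling, asymmetric
reach envelopes, fatigue across the session, heteroscedastic
measurement error, or population structure. Passing round-trip tests
therefore demonstrates that the pipeline is self-consistent — that
fields, layers and features faithfully process clouds with the assumed
monotone separable structure — not that the form fits any real person.

## Numerical notes and limitations

* Isotonic regression is inconsistent at the outermost sample (the
  classic boundary-spiking of monotone estimators), so under noise the
  full-reach features F1/F2/F4 converge visibly more slowly than the
  interior feature F3; the convergence test measures total RMSE at
  widely separated sampling densities (5 vs 80 radii per ray) for that
  reason.
* Feature recovery tolerance: 2 N on forces, 1 cm on D1 for noiseless
  round-trips. The slack absorbs lattice discretization (boundary
  forces are read one radial step inside the reach), not model error.
* Layer boundaries between lattice rays are bilinear in (α, z); the
  dense-scan oracle tests validate per-ray radii to the scan step
  (0.01 cm).
* Task points outside the modeled angular/height region are reported
  as out of reach with an explanatory note rather than raising, so one
  bad point cannot abort a layout report.
* Room-frame layouts are supported through a single rigid body
  placement (position + facing angle), reflecting the standing-user
  scenario; moving users are out of scope.
* The repository imposes no minimum size; matching quality necessarily
  degrades with small repositories, and the reported total is the only
  quality signal.
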