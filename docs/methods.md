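# Methods

This note documents the models, numerical choices, and limitations of
`liverreg`.  Units are millimetres for geometry, Pascals for elastic
moduli, and radians for angles; all meshes and clouds share one
right-handed world frame with 0-based indices.

## Registration task and data model

A preoperative organ is represented by a triangulated surface
(`TriSurfaceMesh`, with named face regions for the anterior/posterior
split and the salient feature patches) and a tetrahedral volume
(`TetVolumeMesh`, with a boundary map onto the surface).  Intraoperative
data is a `FeaturePointCloud`: points labeled `anterior`, `falciform`,
`left_ridge`, or `right_ridge`.  Registration outputs are either a
`RigidTransform` (orthonormal rotation with det +1, validated to 1e-9,
plus translation) or a dense per-node `DisplacementField` that composes a
rigid pose with a nonrigid elastic field.

## Rigid methods

**Point-based registration** solves the weighted Procrustes problem by SVD
of the weighted cross-covariance; the reflection branch is corrected by
flipping the smallest singular direction.  Collinear sources (second
singular value ≤ 1e-9 of the first) are rejected, since roll about the
line is unobservable.

**ICP** alternates closest-point correspondence against the mesh with a
full point-based re-solve, which makes the RMS correspondence distance
non-increasing.  The clinical practice of manual initialization and
re-initialization is replaced by a deterministic bank of 8 starting poses
(identity and 180° world-axis flips, plus principal-axis alignment and its
flips, all centroid-aligned).  Each start runs a 30-iteration coarse
screen; the two best basins are refined fully and the lower final RMS
wins.  Default convergence tolerances are 1e-4 mm translation and 1e-6 rad
rotation change per iteration, max 100 iterations.

**wICP** matches feature-labeled points only to the same-label surface
patch with weight `w(k) = 1 + (w0 − 1)·γᵏ` at iteration `k`
(defaults `w0 = 10`, `γ = 0.9`; the source literature states only that the
schedule decays exponentially, so these are package choices exposed in
`IcpConfig`).  Anterior points match the whole surface with unit weight.
Initialization is automatic: when at least three feature labels are
present, a coarse pose is solved from feature-centroid/patch-centroid
pairs; otherwise the same 8-pose bank is screened with feature weighting.
Convergence additionally requires the weight schedule to have decayed to
within 5 % of unity, so features cannot freeze an early pose.

## Kelvinlet deformable registration

The deformation basis is the regularized Kelvinlet: the closed-form
displacement of an infinite homogeneous linear-elastic medium under a
smoothed point load of radial scale ε,

    u_ε(r) = [ (a−b)/r_ε I + (b/r_ε³) r rᵀ + (a ε²/(2 r_ε³)) I ] f₀ ,

with `r_ε = √(|r|²+ε²)`, `a = 1/(4πμ)`, `b = a/(4(1−ν))`,
`μ = E/(2(1+ν))` (the standard Kelvin-state convention).  The response is
smooth and bounded everywhere (value `(3a−2b)/(2ε)·f₀` at the center) and
decays as 1/r.  Defaults: `E = 2.1 kPa`, `ν = 0.45` — soft-tissue scale;
note that TRE is insensitive to `E` alone because the reconstructed forces
rescale with it, so the effective knobs are ν, the energy weight, and ε.

**Control sets.**  160 control points (the full-surface default) are
placed by farthest-point sampling over the surface vertices, seeded at the
vertex nearest the region centroid — deterministic for a given mesh.  Each
control's ε is 2.0× its mean distance to its 3 nearest fellow controls,
which keeps responses local at any control count; the factor 2.0 was
calibrated on synthetic parameter-recovery runs (1.0 leaves the basis too
spiky to reach interior targets smoothly).  A posterior-only region option
exists for contact-load scenarios.

**Objective.**  With data features F (sizes N_F) and per-point
model-to-data errors d_i,

    C(f, t, θ) = Σ_F (w_F/N_F) Σ_i d_i² + w_E f_E² .

Anterior points use signed distance along the surface normal at their
closest point on the deformed surface; feature points use closest-point
distance restricted to the same-label patch.  f_E is the linear-elastic
strain energy of the nonrigid field — one-point quadrature per tet of
`λ/2 tr(ε̃)² + μ‖ε̃‖²_F` on the analytic Kelvinlet gradient, with
linearized strain ε̃ — normalized by `μ × mesh volume` so it is
dimensionless (a mean-squared-strain scale).  With that normalization the
default `w_E = 1000` (all `w_F = 1`) was calibrated on synthetic recovery:
values 30–300 maximize clean-data accuracy by a small margin, but
`w_E = 1000` keeps 2-mm-noise cases below the rigid baseline across
generator seeds at a cost of ~0.1 mm in the clean case.

**Optimization.**  Forces (3 per control) and a concurrent rigid pose
(axis-angle + translation, composed left of the nonrigid field:
`x → R(x + u_nl(x)) + t`) are fit by Levenberg–Marquardt.  Each iteration
freezes correspondences, assembles the analytic Jacobian (the energy term
enters through a precomputed quadratic form `E = ½ fᵀQf`), solves
column-scaled damped normal equations, and accepts a step only if the
exactly re-evaluated objective decreases — so the reported objective trace
is non-increasing by construction.  Damping starts at 1e-3 and adapts
×10/÷10; max 100 iterations; relative objective tolerance 1e-6.  A
rejected step after 8 damping escalations terminates with the best
iterate.

## Synthetic challenge generator

The generator defines the study conditions and is first-class tested code.

* **Organ.**  A star-convex lobed ellipsoid (semi-axes 95×65×45 mm, lobe
  amplitude 0.22 biasing the right lobe), triangulated from a subdivided
  icosphere (642 vertices / 1280 faces by default; total area ≈ 5.4e4 mm²,
  volume ≈ 1.1e6 mm³ — liver scale).  Anterior/posterior regions split at
  z = 0; the falciform patch is an anterior mid-sagittal band and the
  left/right inferior ridges are bands along the antero-inferior rim.  The
  tet mesh Delaunay-triangulates the surface vertices plus two jittered
  interior shells and the center, keeps tets with interior centroids, and
  drops slivers with quality `volume/longest_edge³ ≤ 4e-3` (their P1
  gradients are meaningless); interpolation falls back to the nearest
  element for points in the resulting hairline notches.  159 validation
  targets are rejection-sampled uniformly inside 0.9 of the radial bound
  and validated against the tet mesh.  Seven farthest-point volume
  partitions stand in for Couinaud segments S2–S8 (the synthetic organ has
  no true anatomy; the labels exercise stratified evaluation).
* **Deformation states.**  Each state applies 2–4 posterior Kelvinlet
  loads (random posterior centers, ε ∈ [45, 65] mm, directions near the
  posterior normal), scaled so the peak target displacement equals the
  requested 12 mm — matching the small-to-moderate deformation regime.
  The broad ε keeps the generating field near-incompressible
  (per-element |J| within [0.85, 1.15] at default conditions).  The
  generating load configuration is drawn independently of the
  registration's 160-control farthest-point set, so recovery is not a
  strict inverse crime; a Gaussian-RBF posterior generator
  (`model="rbf"`) is available for full basis separation.  Requested
  peaks above 25 mm trigger a linear-regime warning.
* **Patterns.**  A geodesic anterior patch is grown from a random
  anterior seed face and its radius bisected until the measured coverage
  extent matches the target within ±1.5 percentage points.  Feature-curve
  points are added when the patch comes within 35 mm of the feature faces,
  emulating the separate stylus swipes used clinically to digitize
  accessible feature curves (`feature_reach=0` restores strict overlap).
  Default 450 anterior points plus up to 40 per feature.
* **Extent.**  Coverage is measured with a surface-projected alpha
  criterion: the area fraction of faces whose centroid lies within α of a
  data point, with default α = 2.5× the cloud's median nearest-neighbour
  spacing.  This is monotone in the point set, bounded by [0, 100] %, and
  reproduces analytic areas (a densely sampled hemisphere measures
  50 ± 2 %).  Whether the original extent computation used a 3-D or
  surface-projected alpha shape is not documented; the projected variant
  was chosen for determinism and monotonicity.
* **Noise.**  2-mm-amplitude sinusoidal noise along the local surface
  normal, `amplitude·sin(2π s/λ + φ)` with s the coordinate along a random
  travel direction, λ = 20 mm, and random phase — only the amplitude is
  reported by the source study; direction, wavelength, and phase model are
  declared package choices.
* **Assembly.**  28 patterns × 4 states = 112 instances; a random 21 of
  the 28 patterns carry noise (84 noisy / 28 clean instances); each
  instance is posed by an independent uniform random rigid transform
  (axis components uniform in [−1, 1] normalized, angle uniform in
  [0, 2π), translations uniform in [−100, 100] mm).  All randomness fans
  out deterministically from one master seed.  Ground truth (deformed
  target positions and poses) lives in a sealed structure/file that
  registration code paths never read.

## Evaluation suite

Per-target TRE is the Euclidean error at the 159 targets after applying
the dense field (barycentric interpolation in the containing tet; points
marginally outside are extrapolated from the nearest element with a
warning).  Noise efficiency/degradation follow the ratio formulas at
A_N = 2 mm.  Extent bins default to [20, 28), [28, 36), [36, 44] (upper
edge closed); segment summaries exclude labels below a configurable
minimum count.  Field consistency averages per-element ‖ε‖ and |J| across
fields (mean of measures, not the measure of the mean field).  The matrix
L2 norm in ‖ε‖ is interpreted as the spectral norm (largest absolute
eigenvalue of the symmetric strain); Frobenius is available via
`norm="frobenius"`.  Method comparisons use Friedman (Wilcoxon signed-rank
when only two methods are supplied) with Bonferroni-adjusted pairwise
Wilcoxon tests; noisy/clean group contrasts use Wilcoxon rank-sum,
Brown–Forsythe (median-centered Levene), and two-sample
Kolmogorov–Smirnov tests at α = 0.05.

## Problem sizes and determinism

Default test and acceptance runs use the 642-vertex surface / ~3.7k-tet
volume, 450–550-point patterns, and 160 controls; a single deformable
registration takes well under a minute on one CPU at these sizes, and the
full 112-instance challenge assembles in a few seconds.  Closest-point
queries use a KD-tree over face centroids with an exhaustive-certificate
fallback near the surface; queries farther than five face radii accept the
candidate answer (distance error O(R²/d), irrelevant for correspondence
selection).  Equidistant-face ties resolve to the lowest face index.

## What the synthetic study does and does not show

Passing the synthetic suite demonstrates that the estimator recovers
posterior-load deformations from sparse anterior data, beats its own
rigid baselines under the stated conditions, and produces biomechanically
consistent fields.  It does not certify performance on real organs: the
surrogate lacks true anatomy (ligament attachments, vessel stiffening,
heterogeneity), the generating deformations live near the span of the
reconstruction basis even with separated configurations, and real
digitization error is not a single coherent sinusoid.  Known limitations:
spatially coherent structured noise over a small patch can mimic genuine
deformation signal and degrade the reconstruction markedly on occasional
instances (regularization does not rescue such cases); the
infinite-medium Kelvinlet assumption misplaces effective forces near
stress-free boundaries; and ICP from arbitrary SE(3) poses can settle in
wrong basins when run without feature information, which is precisely the
failure mode wICP addresses.
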