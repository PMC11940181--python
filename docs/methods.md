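# Methods

This note documents the models and numerical choices behind `rebiom`:
what each stage computes, the defaults and why, what the synthetic
fixtures do and do not emulate, and the known limitations.

## Curvature estimation and classification

Per-vertex principal curvatures come from a least-squares quadric
(osculating paraboloid) fit: the ring-neighbourhood of each vertex is
expressed in a tangent frame whose third axis is the outward vertex
normal, a graph h(u,v) = ½au² + buv + ½cv² + du + ev is fitted, and the
Weingarten map assembled from the first and second fundamental forms of
that graph is eigen-decomposed into k₁ ≥ k₂. Including the linear terms
makes the fit robust to the vertex not being exactly on the smooth
surface. The default neighbourhood is ring 2 (typically 15–25 points,
enough to determine 5 coefficients stably); ring 3 is used for noisy
scanned surfaces, where the wider stencil acts as an additional
low-pass. Vertices on an open boundary get one-sided stencils with
systematically biased curvature, so they are flagged undefined and
inherit the nearest interior vertex's values; vertices with fewer than 5
usable neighbours are treated the same way, with a warning.

Sign convention: the fit height is measured along the *outward* normal,
so a convex region (bulging outward) has negative principal curvatures
and H < 0. This is the one convention under which the HK table's
"convex ⇔ H < 0" rows and the shape index's "+1 ⇔ convex cap" agree,
and it is applied consistently everywhere.

The shape index S = −(2/π)·arctan((k₁+k₂)/(k₁−k₂)) is 0/0 at umbilics;
the limit along any path with k₁ → k₂ is sign(−(k₁+k₂)), and that value
is returned by continuity. At k₁ = k₂ = 0 no limit exists and S is NaN
("unspecified"); such points are flat by the curvedness criterion
anyway. SC classification bins S at its critical points 0, ±0.5, ±1:
open intervals give the elliptical and saddle families, and a band of
half-width `eps_s` (default 0.05) around ±0.5 captures the developable
(cylinder) classes, which are a measure-zero set under any noise.

Zero-thresholds: the classifiers treat |H| ≤ eps_h, |K| ≤ eps_k and
C ≤ eps_c as zero. The defaults derive all three from one robust scale —
the median absolute curvedness c̄ of the field — as eps_h = eps_c =
0.05·c̄ and eps_k = 0.05·c̄² (K lives in 1/mm², hence the square).
Deriving eps_k from the spread of K itself fails on developable
surfaces, where |K| is pure estimation noise and any fraction of its
median classifies the whole surface as curved; the curvedness scale does
not have this degeneracy. On a perfectly flat analytic plane c̄ = 0 and
the automatic scale collapses to its floor; classify such fixtures with
explicit absolute thresholds.

## Segmentation

Region growing flood-fills same-class connected components in vertex
index order (deterministic for a fixed ordering). Components smaller
than `min_vertices` (default 20) are absorbed into their largest-area
neighbouring region, smallest first, ties to the lowest id. Cusp
extraction then reports one record per convex region whose apex — the
region vertex extreme along the region's mean outward normal — is
strictly interior to the region; sliver regions produced by noise peak
on their own border and are rejected by this test.

Noisy scanned crowns are cleaned before curvature estimation with
Taubin (volume-preserving) smoothing; the pipeline default for scanned
input is 80 iterations with ring-3 curvature. With those settings the
cusp count on the molar (8) and premolar (6) presets is stable across
10 noise seeds at σ = 1% of the crown diameter, which is the regime the
scanner emulator targets.

Long-bone partitioning samples cross-section areas along the primary
axis (60 stations by default) and takes the prominent local minima of
the area profile — the anatomical necks — nearest each extremity as the
head|shaft and shaft|base boundaries. A minimum counts as prominent
when the area rises at least 5% on both sides, which rejects both
discretisation wiggles and the flat profile of a plain cylinder (an
error, since such a bone has no necks to find). The extremity with the
larger maximal cross-section is taken as the head, matching metacarpal
and phalangeal anatomy where the distal articular head out-sizes the
base; the choice is configurable. Compact (carpal-like) bones fail the
long-bone precondition (axial extent ≥ 1.5× maximal transverse extent)
and should be treated as single regions.

## Referential geometric entities

The principal frame uses the *solid* inertia tensor (divergence-theorem
mass properties) because the centre of gravity is a solid property; for
open meshes the vertex mean and covariance stand in, with a warning.
Axes are ordered by descending spatial extent of the shape along each
eigenvector — not by eigenvalue — so flat-and-wide bones keep a stable
primary axis. The sign of each of the first two axes points towards the
vertex farthest from the centroid along it (rigid-motion-equivariant and
deterministic); the third completes the right-handed triple. Shapes
whose three extents agree within 1% are flagged degenerate
(arbitrary-but-orthonormal axes).

COR fitting is algebraic least squares (a linear system in the sphere
centre and radius) refined by geometric Levenberg–Marquardt on the
radial residuals; on exact data the result is exact to solver precision.
Circle-in-plane mode projects the points onto their SVD best-fit plane
first and is intended for the condylar profile of a single principal-
plane cross-section (hinge joints); sphere mode suits the ball-like
metacarpal heads. The head sub-region passed to the fit is the `head`
feature label intersected with the convex-elliptical class, which
excludes the neck blend that would otherwise bias the fit. Coplanar
input in sphere mode is rejected with advice to use circle mode.

## B-spline fitting

Curves are clamped cubic B-splines, chord-length parameterised, with
the end control points pinned to the polyline endpoints and the interior
solved by least squares. Surfaces are tensor-product cubic B-splines
over a principal-plane parameterisation (SVD of the region's points,
with the same equivariant sign rule as the RGE axes); the fit minimises
‖BP − X‖² + λ‖D₂P‖² where D₂ takes second differences of the control
net along both directions — a discrete thin-plate fairing term.
Coordinates are normalised by the bounding-box diagonal inside the
solve so λ is dimensionless; the default λ = 1e-3 leaves analytic test
shapes essentially unbiased while regularising rank-deficient nets. At
λ = 0 an under-determined net raises rather than returning an unstable
solution. Stitch validation samples the four boundary curves of every
patch; two boundaries from different patches count as shared when their
symmetric mean distance is below a fraction (default 25%) of the shorter
curve, and the report passes when every shared pair's worst gap is
under tolerance.

## Hand model

The skeleton fixes the 8 carpals as one block (they move little during
grasping and are welded to the root), welds the 4 finger metacarpals to
it, and articulates 15 joints: universal (2 DoF) at the finger MCPs and
the thumb MCP and CMC, revolute (1 DoF) at the PIPs, DIPs and thumb IP.
That yields 21 rotational DoF; the anatomical count (4 per finger,
5 thumb, 6 wrist) is 27, the difference being the wrist block and the
finger CMC/palm-arch mobility deliberately frozen out of the model.

Dynamics are decoupled per joint axis: a torque generator plus linear
torsional spring-damper, I·θ̈ = τ(t) − k(θ−θ₀) − c·θ̇, integrated by
fixed-step RK4, with joint limits enforced by a one-sided penalty spring
(400× the joint stiffness, critically damped inside the penalty layer)
that keeps excursions under ~0.5°. This lumped model trades fully
coupled rigid-body dynamics for per-axis closed-form testability: the
step response is checked against the analytic damped-oscillator solution
to better than 1e-4 rad, and the spring-plus-kinetic energy is verified
non-increasing under zero torque. The per-axis inertia is the inertia of
the distal sub-chain about the joint axis at the rest pose (parallel-
axis theorem over the distal bones), frozen during simulation — pose-
dependent inertia variation is ignored. Default spring constants are
k = 50 N·mm/rad and c = 5 N·mm·s/rad per axis (heavily overdamped, so
poses settle monotonically in ~0.1 s); no published values exist for
these, and they are configurable per joint. Torques are N·mm, inertias
g·mm²; the 10⁶ unit bridge between them is a named constant.

Kapandji targets follow the clinical ladder — radial side of the index
proximal and middle phalanges, the four fingertips, small-finger DIP /
PIP / proximal creases, distal palmar crease — derived procedurally from
the rest geometry (crease points are volar surface points at fixed
axial fractions of their bone) and attached to their bones, so they ride
through the forward kinematics as the fingers move. The score is the
highest n with positions 1..n all touched within tolerance (default
5 mm). The reference trajectory is built by bounded least-squares IK
over the thumb chain plus the target finger; an unreachable target
raises rather than silently under-scoring. FMA templates are per-joint
flexion-angle bands expressing each position qualitatively; every
non-extension template excludes the zero pose at one or more joints, so
the battery is discriminative by construction. The bands are config
defaults with internal-consistency tests only — no clinical calibration
is claimed.

Grasp forces: fingertips within tolerance of the grasped sphere become
contacts with inward normals; magnitudes minimise the squared net
force-plus-torque residual (torque arms about the contact centroid,
normalised by the mean lever so the two residuals are commensurate)
subject to f ≥ 0 and Σf = total, solved by SLSQP and renormalised to
satisfy the total exactly. Symmetric contact arrangements provably
equalise, which the tests exercise; a brute-force simplex grid search
provides the independent optimality oracle.

## Synthetic fixtures

The generators produce parametric idealisations, not anatomical
replicas; realism targets the geometric features the pipeline measures.

- **Long bones**: surface of revolution with superellipse cross-sections
  (exponent 2.4 along the shaft, blending to circular at the ends), a
  monotone-cubic radius profile with prescribed neck stations, and an
  *exact* sphere at the distal head whose centre is the ground-truth
  COR. Mesh rows are placed at equal arc length along the profile so the
  caps are resolved where they bend; at the default resolution the mesh
  centroid agrees with the quadrature centroid of the continuum solid to
  0.001% of length. The analytic CoG uses the superellipse area factor
  4Γ(1+1/p)²/Γ(1+2/p) in the quadrature.
- **Occlusal crowns**: a height field over a disk — shallow central
  basin, rim roll-off, and n radially placed Gaussian cusps with seeded
  ±8% height and ±12% angular jitter. Presets: molar 8 cusps, premolar
  6, incisor 3. The apex list is the ground truth for recovery tests.
- **Hand skeleton**: 27 bones placed with ≥1.6 mm joint gaps
  (interference-checked), digit lengths scaled per finger, the thumb
  column abducted radially and rotated volar so its flexion sweep
  opposes the finger pads. Thumb ranges (CMC flexion −0.4..2.1 rad,
  abduction ±1.3 rad) are generous because the model channels the
  CMC's anatomical pronation through its two axes.
- **Scanner emulator**: area-uniform surface sampling per view,
  visibility culling by normal direction, Gaussian noise along the
  normal (default σ = 0.05 mm, structured-light class), dropout, and
  per-view rigid jitter with ground-truth transforms returned. Jitter
  variates are drawn even when disabled so the sample stream is
  identical across settings at a fixed seed. Not emulated: outlier
  clusters from specular highlights, spatially correlated noise,
  occlusion shadows, registration drift — so passing recovery tests
  show correctness of the pipeline's geometry, not robustness to every
  real scanner artefact.

Every generator is a pure function of spec + seed (bitwise
reproducible).

## Problem sizes and determinism

Default problem sizes are desk-scale by design: bones ~4300 vertices,
crowns ~3100, skeleton assembly ~0.5 s, the full pipeline ~20 s, the
whole test suite ~2 min on one CPU. All stochastic stages take explicit
seeds, threaded from the pipeline seed; two runs with the same config
and seed produce identical reports.

## Known limitations

- Curvature estimation assumes locally graph-like neighbourhoods; it
  will blur features sharper than the ring radius.
- The HK/SC schemes agree on family membership only where curvedness is
  significant; near developable and flat transitions the schemes
  legitimately resolve borderline vertices differently.
- Per-axis decoupled dynamics ignore inertial coupling between joints
  and pose-dependent inertia; they are adequate for settling-type pose
  simulations, not for impact or high-speed dynamics.
- The FMA bands and Kapandji target derivations are geometric proxies
  for clinical procedures; scores on synthetic hands validate the
  scoring machinery, not clinical equivalence.
- Surface reconstruction from raw clouds (Poisson-style meshing) is out
  of scope; meshes come from fixtures or upstream tools, and the toolkit
  validates/repairs rather than reconstructs.
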