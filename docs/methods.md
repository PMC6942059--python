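# Methods

## The measurement model

The quantity of interest is how far the medial meniscus extrudes medially
past the tibial plateau. Both the 3D volume and the width metric are
defined relative to a *thickened cross-sectional model*: the tibia,
expressed in an anatomical frame, is cut 10.0 mm inferior to the plateau
(parallel to the frame's ZX plane) and at the frame's XY plane; the
cross-section of the retained medial block at that −10 mm level is extruded
30.0 mm superiorly into a prism. Extrusion volume is the meniscus volume
outside the prism; extrusion width is the mediolateral gap between the
prism's outer edge and the meniscal outer edge on the Z axis. The point of
the −10 mm reference is robustness: marginal osteophytes sit at the joint
line, so an outline taken 10 mm below it does not move as osteophytes grow,
which is what makes longitudinal comparisons meaningful. Both cut depths
are parameters (`MeasurementParams`, mm) with those defaults.

### The anatomical frame

The frame construction mirrors the manual procedure it automates. A planar
section is taken at the *top of the fibular notch* — a user-supplied
landmark, since in practice it is identified visually — and a rectangle is
fitted tangent to the section contours: the posterior side on the common
posterior tangent of the two condylar arcs, medial/lateral sides tangent to
the respective condyles, and the anterior side tangent to the medial
condyle only. The posterior bitangent is found as the convex-hull edge
whose endpoints straddle the mediolateral midline while facing posterior;
when no such edge exists (a merged, convex posterior contour) the
orientation falls back to the caller's medial hint with a warning. This
bitangent rule is a deterministic reconstruction of a manual fitting step
whose exact objective is not published; it reproduces the four named
tangencies exactly on analytic two-circle sections.

The rectangle center is transferred superiorly to the *bottom of the
medial tibial plateau*. Implemented reading: the translation distance is
the plane-normal distance to the lowest upward-facing articular vertex
(face-normal within 30° of superior) inside a medial band of the rectangle
footprint (|X| ≤ 0.6·half-extent, Z between 10% and 85% of the medial
half-extent). The band deliberately avoids the plateau rim, where an
osteophyte's upper shoulder could masquerade as articular surface. An
explicit offset can always be supplied.

Axes: Z along the rectangle's mediolateral side (medial positive), X along
the anteroposterior side (anterior positive), Y = Z × X (superior
positive). Left knees are mirrored (x → −x) before fitting so that medial
is +Z for both sides.

### Frame transfer between modalities

The frame is fitted once (on the CT-derived model in the validation
workflow) and transferred to the second model by rigid ICP. Correspondences
are closest points *on the target surface* for an area-weighted sample of
the source surface (default 10 000 points, seeded); each iteration first
tries a linearized point-to-plane update and falls back to the closed-form
rigid least-squares (Kabsch) update whenever point-to-plane fails to lower
the RMS — the fallback makes the closest-point RMS provably non-increasing,
which is asserted on every run, while point-to-plane gives fast terminal
convergence. Convergence: RMS change below `tol` (default 1e-4 mm).

### Volumes without mesh booleans

The prism is a vertical extrusion, so for any watertight mesh M,

vol(M ∩ prism) = Σ over triangles T of M of ∫over T∩(P×ℝ) clamp(y, y₀, y₁)·n_y dA,

where P is the base polygon: the divergence theorem applied to the field
(0, clamp(y), 0), whose flux through the prism's vertical walls is zero.
Each triangle is clipped against P in its (x, z) projection (shapely,
exact), the clamp split uses the identity clamp = y₀ + relu(y−y₀) −
relu(y−y₁) so slab-boundary ties are never double-counted, and the
remaining integrals are closed-form (signed area × affine centroid value).
The extrusion volume is the mesh volume minus this quantity. This is an
exact evaluation of the boolean-difference volume, not an approximation; it
is independently cross-checked against a ray-parity voxel oracle at 0.1 mm
(agreement ≲0.5% on phantoms, dominated by the oracle's own
discretization). If polygon clipping ever fails, the voxel estimate at
0.1 mm is returned with a provenance flag. The exported extruded sub-mesh
is assembled from the clipped triangle pieces plus wall cuts; adjacent
pieces share geometry but not vertices (T-junctions), so its volume is
evaluated with the same y-flux formula, which vertical-wall stitching
cannot perturb.

Planar cuts are capped by ear-clipping the open boundary loops (holes
bridged to their outer ring), with a union-find vertex merge beforehand and
an angular tie-break for boundary "pinch" vertices where two cut planes
meet on a mesh vertex — both needed to keep the capped plateau watertight
in exactly-axis-aligned configurations.

### Width

`axis_line` mode (default) reads the width where the Z axis crosses: the
meniscal cross-section at X = 0 versus the prism outline at X = 0.
`max_over_x` scans anteroposterior positions at 0.5 mm and reports the
largest protrusion — the stricter metric that a single fixed line can
undershoot. The 2D single-slice width is provided for comparison: the slice
with the greatest medial-spine area is selected (coarse-to-fine scan at
0.5 mm resolution, ties anterior), and the width is the mediolateral
distance from a caller-supplied plateau-edge reference point to the
outermost meniscal contour point, clamped at zero.

## The phantom

The synthetic knee is built so that the measurement's target quantities are
exact by construction:

* Every horizontal tibia cross-section is the union of two circles
  (condyles), star-shaped about the origin, sampled at 512 angles with
  vertices exactly on the circles. Radii and center offsets are constant
  from the plateau down past the −10 mm cut (vertical walls in the
  measurement zone — this is what makes the true width equal the
  construction offset), then taper smoothly into a single shaft.
  Default dimensions (condyle radii 23 mm, centers ±17 mm, ~80 mm overall
  mediolateral width) are in the range of an adult proximal tibia.
* The meniscus is a trapezoidal wedge (10 mm wide, 4 mm tall at the rim
  tapering to 0.8 mm) swept 150° around the *medial condyle center* with a
  vertical outer wall at radius r_medial + e. Hence the maximal width is
  exactly e, the axis-line width has a closed form (equal to e for
  symmetric condyles), and the extrusion volume is an annular-sector
  integral with a linear height profile, also closed form.
* Optional features: articular dishes (medial depth 2 mm — defines the
  "bottom of the medial plateau" the frame origin lands on), a medial
  tibial spine ridge (for slice selection), a marginal osteophyte bump
  confined to the rim zone above the −10 mm level, and a cosmetic fibular
  notch dent below the landmark level. A specification whose osteophyte
  would intersect the meniscus is rejected.
* The true frame (origin, axes) is computed from circle tangent geometry in
  closed form, independently of any mesh operation.

Acquisition emulation voxelizes the clean mesh at CT-like (0.5 mm
isotropic) or MRI-like (2.0 mm coronal slices stacked along the
anteroposterior axis, 0.47 mm in-plane) resolution, low-pass filters the
occupancy (σ = 0.9 voxels, the partial-volume analogue), adds correlated
noise scaled — via the local field gradient — to a boundary jitter of
0.1 mm (CT) or 0.25 mm (MRI), re-extracts the 0.5 isosurface and lightly
smooths. The noise is zeroed on the outer two-voxel shell so the isosurface
is always closed; disconnected specks are dropped by keeping the largest
component. All randomness sits behind one integer seed; repeat calls are
bit-identical.

What the phantom does *not* emulate: real segmentation bias (reader
tracing, cartilage/osteophyte ambiguity on MRI), trabecular texture,
cartilage layers, a femur, non-rigid joint pose differences between scans.
Passing the phantom suites therefore demonstrates that the geometry
pipeline is correct and stable under acquisition-style degradation — not
that clinical segmentations of real knees would show the same absolute
accuracy.

## The simulated agreement study

`run_cohort_study` draws n subjects (default 10) with anatomy jittered
around the canonical phantom, extrusion offsets spread over 1.5–6.5 mm and
osteophytes attached to higher synthetic disease grades; each subject gets
a CT-like and an MRI-like tibia and an MRI-like meniscus (the meniscus is
only segmentable from MRI in practice). The frame is fitted on CT,
transferred to MRI by ICP, and the full measurement plus the 2D width runs
against both tibial references. Cohort phantoms use a 55 mm shaft — the
measurement only probes the proximal 20 mm, and the shorter shaft keeps
the emulation grids small. The report mirrors how such validation studies
tabulate results: per-variable modality comparison (normality, means with
95% CI, median/IQR, pooled t, Cohen's d, post-hoc power), per-subject
signed surface differences of the plateau models, and consistency
regressions (CT on MRI, and 2D on 3D width) with adjusted R².

Surface differences are sampled on the test (MRI) model, signed positive
outside the reference (CT), with faces created by the cutting planes
excluded on both sides; the per-subject 95% interval is descriptive
(mean ± 1.96·SD over points) — the convention such tables use, since the
points on one surface are not independent draws.

## Statistics

* Shapiro–Wilk, pooled two-sample t (the convention in this workflow, with
  a paired variant available), OLS consistency regression with
  adjusted R² = 1 − (1−R²)(n−1)/(n−2).
* ICC: two-way absolute-agreement single measures ICC(2,1) by default —
  the apt model for one rater re-measuring after an interval — with
  one-way and two-way consistency variants exposed; F-based confidence
  intervals (via pingouin). Exactly agreeing repeats short-circuit to
  ICC = 1 (the variance-ratio limit).
* Power/sample size from the noncentral t distribution, one-sample/paired
  family by default with noncentrality d·√n: this family reproduces the
  published-style calculation n = 10 at d = 1.32, α = 0.05, power = 0.95
  (a two-sample family would give 16 per group). `required_sample_size`
  is a deterministic scan from n = 2 upward; the definitional pair
  (power(n) ≥ target > power(n−1)) is asserted across an effect-size grid.

## Numerical choices and limitations

* Global vertex-merge tolerance 1e-6 mm; degenerate (zero-area) faces are
  dropped on load but tolerated inside caps where collinear boundary
  vertices require them for watertightness.
* Smoothing is Taubin shrink/inflate with the pass-band relation
  1/λ − 1/ν = 0.1 (volume drift <2% at defaults), never plain Laplacian,
  so modality comparison is not biased by shrinkage.
* Closest-point queries refine long triangles until each piece fits a ball
  of radius 0.75 × median edge, then use a centroid KD-tree with a
  completeness bound (a candidate shell narrower than best + reach
  triggers escalation), making results exact rather than heuristic.
* The voxel oracle counts grid columns by winding parity with an
  irrational grid offset, so mesh edges and grid lines essentially never
  coincide; error is O(surface area × pitch).
* Suite problem sizes: phantom sweeps use the default 512-angle tibia
  (~94k faces), oracle checks 0.1 mm voxels, the cohort study 10 subjects —
  sizes chosen so each scenario completes in seconds-to-minutes on one
  CPU while keeping discretization error far below the asserted
  tolerances.
* Known limitations: frame fitting assumes the notch-level section
  approximates the manual landmark (±0.5 mm landmark jitter moves the
  width by ≲0.15 mm on phantoms); the auto plateau-bottom heuristic can be
  misled by extreme rim deformity (manual override provided); the exported
  extruded sub-mesh is not edge-manifold at cut seams (its volume is
  flux-exact regardless); patients whose osteophytes extend below the
  −10 mm level are outside the method's assumptions.
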