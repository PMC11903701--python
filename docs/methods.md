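# Methods

## Measurement model

The sensor model is a pinhole camera with per-pixel *z-depth* (distance
along the optical axis, not Euclidean ray range): this makes the intrinsic
equation exactly solvable for the remaining coordinates,
`x = (u − ox) z / fx`, `y = (v − oy) z / fy`. Pixel indices are 0-based,
`(u, v) = (column, row)`, and refer to pixel centers. Extrinsics `[R|t]`
map world → camera; world recovery uses the closed-form inverse
`Rᵀ(p − t)`. Invalid depth returns are a non-positive sentinel in files and
a validity flag in memory; they are never interpolated — missing-data
policy is the measurement layer's, which simply excludes affected triangles
and reports the loss through `coverage`.

Two areas are computed per wound component (components are 4-connected):

* **2D projection area.** The component's outer contour is the ordered
  Moore-neighbor boundary trace of its masked cells, oriented
  counter-clockwise in image coordinates. Its world-frame polygon defines a
  best-fit plane via Newell's method (normal from the cyclic summation,
  reference point at the vertex centroid). The polygon is projected onto
  the plane and its area taken as the absolute *signed* (shoelace) area in
  an in-plane orthonormal basis. A Heron fan over the contour — the
  obvious alternative — is unsigned and over-counts concave fans; the
  signed form is exact for all simple polygons and agrees with Heron on
  convex ones, so it is used throughout. Self-intersecting contours
  produce a warning and the signed value. The in-plane basis is the
  normalized projection of the world x-axis (y-axis fallback when nearly
  parallel to the normal); any orthonormal basis gives the same area, but
  fixing one makes outputs bit-reproducible.
* **3D surface area.** Every 2 × 2 quad of adjacent pixels is split along
  the top-left → bottom-right diagonal (the direction of the row-major scan
  order); triangle areas come from Heron's formula in the numerically
  stabilized sorted-side (Kahan) form, so near-degenerate slivers cannot
  yield negative radicands. A triangle contributes iff all three vertices
  are masked and depth-valid — the estimate never extrapolates outside the
  segmentation. A test verifies that choosing the other diagonal changes
  phantom areas by far less than the discretization error.

Units are meters internally; all reported areas are cm², rounded to two
decimals in output files only.

## Curvature convention

Cross-sections are ellipses with *full* caliper axes `a ≥ b` in cm. The
flat vertex has curvature `b/a²`, the sharp vertex `a/b²`, and the circular
limit `a ≈ b = d` gives `1/d`. This reproduces the worked example
(7.4 × 7.0 cm → 0.127 / 0.151 after truncation); note it is a *diameter*
convention — half the differential-geometry curvature — so the osculating
circle at curvature κ has radius `1/(2κ)`. Semi-axis formulas would instead
give (0.256, 0.302) for the same forearm, so the full-axis reading is
forced. Reported curvatures are truncated toward zero at three decimals
(0.12783 prints as 0.127; rounding would print 0.128).

`predicted_ratio(κ, A)` models the template as a geodesic disc of area `A`
on a circular cylinder of radius `R = 1/(2κ)` even when the site is
elliptical (each site is summarized by one curvature number; the
approximation error is surfaced by comparison tests, not hidden). In
developed coordinates the projection of the disc onto the tangent plane at
its center has area `∫ 2√(r² − s²) cos(s/R) ds`, evaluated by adaptive
quadrature; the ratio depends on `κ√A` only, is strictly increasing in κ,
equals exactly 1 at κ = 0, and matches the small-curvature closed form
`1/(1 − r²/(8R²))` to the quartic remainder (≈1.0 × 10⁻⁴ at κ = 0.05 for
A = 43 cm²). The domain ends where the disc wraps a quarter turn
(`r ≥ πR/2`), beyond which the projection folds.

## Phantom generator

The generator stands in for human participants carrying physical round
templates. Surfaces are a plane, circular and elliptical cylinders, and a
sphere, positioned with the template center at the world origin and the
outward normal toward the camera. Templates are geodesic discs: on
developable surfaces the disc is drawn in the unrolled plane and re-rolled,
so its surface area equals the requested area exactly (the elliptical
cylinder uses a tabulated arc-length parametrization, inverted by
interpolation); on the sphere the polar angle inverts the cap-area formula
`A = 2πR²(1 − cos θ)`. The default area is 1/400 of a 17,000 cm² adult
body surface, rounded half-up to 43 cm².

Scenes are rendered by closed-form ray/quadric intersection — no meshes, so
ground truth stays analytic. The depth value is the camera-frame
z-component of each pixel-center ray hit; the mask bit is set iff that hit
lies inside the template region. Defaults follow the capture protocol the
generator emulates: 192 × 256 resolution (sensor-native), 0.27 m standoff
(midpoint of the 25–30 cm protocol), and — since mobile LiDAR intrinsics
are not published — *auto-framing* intrinsics: a single focal length chosen
so the template spans 85% of the tighter image dimension (the photographer
fills the frame with the wound), principal point centered. Explicit
intrinsics can be passed instead. Renders refuse scenes whose template
touches the image border, leaves the field of view, or is partially
occluded by the surface itself (boundary-visibility ray check).

Depth noise is i.i.d. Gaussian on z (default σ = 0; no public noise
specification exists for the sensor, so σ is a config knob), applied after
the mask is formed and seeded for reproducibility. Because noise on
adjacent pixels tilts the small triangles, σ > 0 *biases the 3D area
upward* — at the native pixel pitch (~1.5 mm on the surface at 0.27 m) a
σ of 2 mm roughly triples the apparent area. Real sensors smooth
spatially, so the generator's noise is a stress knob, not a calibrated
sensor model; robustness tests use σ ≤ 0.4 mm, where the response is
near-linear.

`ground_truth` returns the constructed 3D area (exact) and the region's
orthogonal projection onto the tangent plane at its center, computed by
dense parametric integration (midpoint rule, ≥1.4 million samples at the
default 1201 × 1201) — the brute-force oracle the measurement pipeline is
tested against. By each phantom's symmetry the tangent plane at the disc
center coincides with the best-fit plane of the boundary.

## Cohort simulation

`simulate_cohort` renders one template per subject per anatomical site and
measures it. The published summary gives per-site curvature means and SDs
but not the underlying ellipse axes (only one forearm example, 7.4 × 7.0
cm). The default site list therefore uses the forearm axes verbatim and,
for the other sites, full axes fixed a priori at anatomically plausible
aspect ratios that reproduce the male-cohort curvature means; subject
variability rescales each site's ellipse so the contact curvature is drawn
from a normal with the site SD, truncated at ±2.5σ so every draw stays
inside the wrap/visibility domain. The dorsal hand is included as an
elliptical cylinder for completeness, but a single-curvature convex model
cannot reproduce that site's observed high ratio (compound anatomy); it is
simulated, not claimed predictable. Summaries report sample means and SDs
with the n − 1 denominator; regressions are unweighted OLS with intercept
(`scipy.stats.linregress`), matching the printed `y = ax + b` form.

## Numerical behavior and known limitations

* **Mask-boundary bias.** Because a pixel is wound iff its center-ray hit
  falls inside the region, and a triangle needs all three vertices masked,
  the triangulated region stops about half a pixel inside the true
  boundary. For a disc of radius `r` pixels the deficit is ≈1.1/r of the
  area: ~1.4% at the native resolution with the template filling the
  frame, growing to ~2.3% at curvature 0.183 where the flanks are viewed
  at grazing angles. The contour polygon for the 2D area passes through
  the same boundary-cell centers, so the *ratio* 3D/2D is nearly
  bias-free (flat-surface ratio 0.998 at 192 × 256). Consequences: the
  measured 3D area is a slight, quantified *under*-estimate of ground
  truth (never an overestimate on noiseless renders), and tests of
  absolute-area recovery use the bias envelope while ratio tests use
  sub-percent tolerances. On fine parametric grids (801 × 801) the same
  conventions recover areas to 0.5%.
* **What passing phantom tests do not show.** Phantoms have exact masks,
  no segmentation error, no motion blur, no depth/RGB registration error,
  and smooth convex geometry; real wounds have none of these guarantees.
  Phantom results validate the geometry pipeline, not end-to-end clinical
  accuracy.
* **Degenerate inputs.** Components with <3 cells are skipped with a
  warning; collinear contours raise a degenerate-contour error; wounds
  with no valid triangle raise an unmeasurable-wound error; depth coverage
  below 0.95 of the masked quads flags a low-coverage warning.
* **Rigid-motion behavior.** Rigidly transforming the world-frame point
  cloud leaves both areas unchanged to ≤1 × 10⁻¹² relative (floating-point
  rotation perturbs pairwise distances in the last ulp, so bit-identity is
  not attainable); re-rendering the same surface from a tilted camera
  changes areas by <0.5%.
* **Multi-wound planes.** Each wound component gets its own best-fit
  plane (consistent with summing 2D results separately); a single global
  plane for multi-wound images would be an alternative reading and is not
  implemented.
* **Out of scope.** Segmentation itself (masks/polygons are inputs), lens
  distortion, depth-to-RGB registration of real devices, mesh smoothing,
  hole filling, wound volume, and TBSA% conversion.
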