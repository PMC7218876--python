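# Methods

This note records the models implemented in `cloudspectra`, the defaults
that matter, and the reasoning behind the design choices that were genuinely
open.  It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Radiometric model

Reflectance is a calibrated flux ratio

    R = K · Φer / (Φei · cos θ),
    Φei = ν / (g · τ),
    Φer = f² (ρ − B) / (A · γ · ε) + C,

where ν are sunshine-sensor counts, g its gain, τ its exposure (s); ρ is the
raw pixel, f the f-number, γ the ISO, ε the imager exposure (s), and A, B, C
factory per-camera coefficients.  θ is the angle between the sun direction
and the sunshine-sensor axis.  The per-band coefficient K comes from panel
shots of known reflectance Ri as the arithmetic mean of Ki = Ri·Φei/Φer over
valid shots; shots with Φer ≤ 0 or a mean pixel above 98% of the dynamic
range are excluded.  Because the panel ratio carries no cos θ factor, it is
exact only when the sunshine sensor faces the sun; the synthetic panel
sessions are therefore generated at θ = 0, which is also how a field
operator levels the rig for panel captures.

Reflectance is clipped to [0, 2] (configurable) rather than rejected:
specular highlights in field data produce R > 1 without being invalid
pixels.  NDVI is defined as 0 when NIR + Red = 0 so that no non-finite
value reaches the clustering.  A misprint hazard in the flux formula's
symbol list (the f-number is sometimes called g in prose) is resolved by
the equation itself: f is the f-number, γ the ISO, ε the exposure.

## Fisheye projection

The multispectral imager is a wide-angle camera modeled as

    θ = (2/π)·arctan(√(X²+Y²)/Z) ∈ [0, 1],
    ρ = θ + p₂θ² + p₃θ³ + p₄θ⁴,
    (x_d, y_d) = Affine₂ₓ₂ · ρ·(X, Y)/√(X²+Y²) + (c_x, c_y),

in a camera frame with +Z along the optical axis, +X right, +Y down.  θ is
*normalized*: θ = 1 is a ray 90° off axis, so the model covers the full
hemisphere (a printed form of this model reads "2π arctan", which is
inconsistent with θ ∈ [0, 1]; the 2/π reading is implemented).  The affine
matrix is treated as the complete normalized-to-pixel map (it carries the
focal scale); pixels are 0-based with centers on integer coordinates.
Unprojection inverts the quartic by bracketed root finding on [0, 1]
(`brentq`, xtol 1e-14); projection∘unprojection closes to well below
1e-6 px over the usable θ range.

## Visibility

A point cloud has no surfaces, so occlusion is decided with oriented surfel
disks.  Per camera:

1. frustum filter, then back-face cull (a point whose normal points away
   from the camera is self-hidden by definition);
2. sort candidates by distance to the camera, nearest first;
3. each accepted point registers a disk centered on it, oriented by the
   mean normal of its radius-neighbors (neighbors whose normals deviate
   more than `normal_angle_max` = 60° are excluded from the average);
4. a candidate is occluded iff the ray to it intersects an already
   registered disk nearer by more than a depth bias; a screen-space hash
   grid keeps the test local.

Defaults: neighbor radius = 3× the mean nearest-neighbor spacing (estimated
from 1,000 sampled points), disk radius = 0.5× the neighbor radius, depth
bias = 1.0× the disk radius.  The narrower disk and the full-radius bias
were set by measuring agreement against an exact ray-casting oracle on
plane-behind-plane and sphere-on-plane scenes: full-radius disks overhang
object silhouettes and shadow visible background in a band one disk radius
wide, and a small bias lets the tangent-plane disks of a curved surface
falsely occlude its own grazing region (the sagitta of a neighboring disk
approaches a quarter-radius bias).  Both test scenes sit at ≥ 99% agreement
with the oracle under the shipped defaults; the acceptance suite re-measures
this.

## Multi-view fusion

Reflectance reliability degrades with the angle between the surface normal
and the point→camera direction, so samples are class-weighted:
perpendicular [0°, 25°) → 1.0, oblique [25°, 60°] → 0.5, indirect
(> 60°) → 0.  The class boundaries follow the three stated ranges (both
boundary angles are assigned to the oblique class for determinism); the
weight *values* are a package choice — any monotone triple with zero weight
for indirect views expresses the same ordering — and are config-exposed.
Samples are bilinear in the reflectance raster; a sample is missing when
any of its 4 support pixels is missing.

Three reliability gates, all config-exposed and default-on, protect the
fused values from boundary artifacts that a pixel grid inevitably creates:

- **mixed-pixel gate** — a sample is rejected when its 4 support pixels
  spread by more than 15% of their mean (the bilinear cell straddles a
  material or occlusion edge);
- **depth-edge erosion** — a view is rejected when a strictly nearer point
  projects within 2 px and is closer by more than the neighbor radius (the
  pixel neighborhood straddles a silhouette);
- **cross-view consistency** — with ≥ 4 surviving views, a view deviating
  from the per-point median by more than 3 scaled MADs *and* 5% of the
  median is rejected;
- **neighborhood consistency (admission)** — after fusion, a point whose
  band value deviates more than 15% from the median of its spatial
  neighbors (within 2× the neighbor radius, ≥ 5 neighbors) is excluded
  from the enriched set.

The motivation is quantitative: the divisive splitter's stop rule compares
a cluster's *maximum pairwise distance* with a centroid separation, so a
handful of blended points — pixels mixing two materials at an edge, or a
point whose only surviving views looked across an occlusion boundary — can
inflate a diameter past its stop margin and cascade a clean material cluster
into fragments.  Disabling the gates restores the plain weighted mean.
A point is admitted to clustering only when all four bands were recovered
(NDVI needs NIR and red; the 11-vector must be complete); excluded points
are labeled −1.

## Divisive clustering

All points start in one cluster.  Each processed node is bisected by
2-means (k-means++, `n_init` = 10 restarts, best inertia, deterministic
under the run seed); for each child, with D the Euclidean distance between
the two sibling centroids, the child is recursed into iff

    diameter(child) ≥ D   and   |child| ≥ min_size (default 10),

otherwise it is a final material cluster.  The diameter is the exact
maximum pairwise distance up to 2,000 members and the diameter of a
farthest-point subsample of 2,000 beyond that (never above the exact value,
at least half of it).  A `max_depth` of 32 guards pathological inputs.  The
alternative reading of the stop rule — comparing the *parent's* diameter
with its children's centroid distance — can never terminate, because two
child centroids always lie inside their parent, so the child-diameter
reading is used.  No merge post-processing is applied: leaves are the
materials.

Features are z-scored per dimension before the Euclidean metric is applied
(meters, [0,1] color and reflectance otherwise share one metric by
accident of units); constant dimensions pass through as zeros with a
warning.  The default spatial weight is 0.35 on X, Y, Z: position supports
spatial coherence but is not a material property, and at full weight the
ground plane's 10 m extent dominates the metric and forces spatial
subdivision of a single material.  Weights are per-dimension configurable.

### Operating envelope of the stop rule

Two properties of the rule shape everything downstream:

- **Outlier fragility.**  The diameter is a maximum, so one aberrant point
  inflates it.  Worse, when a node's diameter is inflated by a single far
  point, the inertia-optimal 2-means split usually halves the bulk rather
  than isolating the stray (isolating one point at distance ~12σ saves
  ~144σ² of inertia; halving 600 points saves more), after which the
  halves' own splits have tiny centroid distances and the cascade runs down
  to `min_size`.  This is why the fusion gates above exist.
- **Contrast homogeneity.**  A child is only re-examined against the D of
  the split that created it.  If one material pair is far weaker in
  contrast than the others, the weak pair tends to be isolated as one node
  by a *strong* split (large D) and then freezes: its internal diameter
  cannot reach that D.  Conversely the rule cannot resolve clusters whose
  separation is below their own diameter (a few thousand isotropic Gaussian
  samples already span ~8–9.5 sd in 2–5 dimensions).  The rule therefore
  operates well when inter-material contrasts are of comparable magnitude
  and each exceeds the within-material spread by a wide margin.

Both the Gaussian-mixture study and the reference scene are designed inside
this envelope, which is documented precisely so that users know what the
green acceptance numbers do and do not promise (see Limitations).

## Synthetic scenes and the forward renderer

The generator emulates the acquisition the pipeline targets: a ~10×10 m
natural plot — tree canopy (sphere, r 1.2 m at 2.8 m), trunk (cylinder,
r 0.25 m, 2 m tall), one flower bush (sphere cap), one shrub bed (raised
plane patch), a three-rock pile (sphere caps), rocky ground (plane) —
ringed by 8 fisheye cameras (radius 8 m, height 5 m, 480×360 px,
focal-scale 330 px, mild polynomial distortion).  Each material has one
spatial instance: with X, Y, Z in the feature vector, spatially disjoint
pieces of one material are separate Euclidean clusters, and no unsupervised
method scored against per-material labels could merge them.

Spectral signatures are invented (no reflectance tables exist for the
target setting) under ordinal constraints — vegetation high in NIR/REG and
low in red with green-dominant color, leaf NDVI > 0.6, rock and soil
spectra flat with NDVI < 0.2, flowers a saturated color with high REG/NIR —
and, within those constraints, numerically balanced so the pairwise
material-centroid distances in the standardized feature metric are
homogeneous (max/min ≈ 1.3).  The balancing is a direct consequence of the
stop-rule envelope above: with hand-picked "natural-looking" values the
rock/soil contrast was several times weaker than the rest and froze
unresolved at a substantial fraction of seeds.  Within-material variation
defaults to 1% relative per band and 0.01 absolute per color channel.

The renderer is the exact inverse of the measurement chain: per camera,
point visibility is decided by *analytic ray casting against the primitive
surfaces* (independent of the pipeline's disk test — the two must agree,
and the acceptance suite measures how well); visible points splat small
disks (1.6× point spacing, perspective-scaled) into the raster with
nearest-depth-wins; the per-point true reflectance is converted to raw
counts by inverting the flux equations with a configured K_true per band;
multiplicative Gaussian pixel noise (default 1% in the reference
configuration) is added; empty pixels are NaN.  Splatting renders surfaces
as continuous regions, as a real megapixel imager sees them — single-pixel
point splats at a resolution matched to a 10⁴-point cloud would leave most
bilinear supports incomplete.

What the generator does **not** emulate: shadows and indirect illumination,
BRDF/specular effects, vignetting and dark current, atmospheric variation
between captures, reconstruction noise in positions and normals (positions
are exact; normals are analytic), rolling shutter, and sub-pixel PSF
effects.  Passing tests therefore demonstrate the correctness of the
geometric/radiometric inversions and the clustering logic under the model's
own assumptions, not robustness to those field effects.

The Gaussian-mixture generator used by the cluster-recovery study draws
k ∈ {2..8} cluster centers in a 5-D ball of radius 14.5 sd under a 16 sd
minimum-separation rejection rule (component sizes equal up to remainder,
n = 5,000).  The numbers come from the envelope: separations must exceed
the ~9.5 sd diameter of the components with margin against stray tail
points near group bisectors, stay mutually homogeneous so no nested split
freezes, and avoid the near-symmetric crowded packings that make the
inertia-optimal top-level bisection cut a component in half.

## Registration

Correspondences are nearest-neighbor with weight
`exp(−d²/d_max²)·max(0, cos φ)` (φ the normal angle); pairs beyond `d_max`,
beyond the normal-angle gate, or with opposing normals are dropped.  Each
iteration solves the weighted orthogonal-Procrustes problem in closed form
with reflection correction; iterations that would increase the mean squared
residual are rejected and the best transform is returned, so the objective
sequence is non-increasing.  Convergence: relative objective decrease below
`tol` = 1e-12.  Point-to-point residuals (not point-to-plane) keep the
implementation aligned with the error being minimized and reported.  No
global initialization is provided: field setups coarse-align via GPS; the
API accepts an initial transform instead.  Alignment quality is the RMSE of
nearest-neighbor distances from the aligned cloud into the reference cloud
(the reference is the denser, more accurate model, so pairing is directed
into it).

## Problem sizes in the shipped studies

The evaluation studies run at: 1,000 draws (radiometric round trip), 1,000
rays + 21 closed-form cases (projection), 2,000 points per occlusion scene,
200 ICP trials on a 5,000-point scene, 50 mixtures of 5,000 points, and one
10,000-point / 8-camera / 1%-noise end-to-end run.  These sizes make the
full suite and the acceptance script each complete in a few minutes on one
CPU while keeping every statistical criterion meaningfully powered.

## Known limitations

- The stop rule's operating envelope (outlier fragility, contrast
  homogeneity) is a property of the method, not of this implementation;
  on field data with strongly unequal material contrasts the hierarchy
  will either over- or under-segment the weak contrasts, and the reliability
  gates can only remove artifacts, not equalize real contrasts.
- The surfel visibility test is approximate near silhouettes (a band of
  roughly one disk radius); the acceptance studies quantify the residual
  disagreement with exact ray casting at ~1%.
- LAS I/O is not provided (PLY and XYZ are); binary PLY is little-endian
  only.
- The panel-calibration model assumes the panel is Lambertian and the
  sunshine sensor sun-aligned during panel shots; violations bias K by the
  cosine of the misalignment.
- `estimate_normals` orients normals toward a single viewpoint; clouds
  requiring per-region orientation (e.g. full 360° closed surfaces without
  a meaningful viewpoint) need externally supplied normals.
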