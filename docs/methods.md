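# Methods

This note documents the models, numerical choices and limitations of
`plaquefuse`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Contour extraction in polar OCT frames

Both cap interfaces are extracted as minimal-cost paths through a cost
image derived from the radial intensity gradient of the polar frame.
The image is pre-smoothed with an isotropic Gaussian (σ = 1 pixel,
wrap-around across A-lines), the gradient is signed per interface
polarity (dark→bright for the lumen, bright→dark for the abluminal cap
border), clamped at zero and normalized by a robust edge-strength
estimate — the median over A-lines of the per-A-line gradient maximum.
This normalizer is deliberate: interface edges occupy only one or two
radial pixels per A-line, so a global high percentile of the gradient
image underestimates the edge scale, while each A-line's maximum is an
edge sample wherever the interface is present.

The path objective is

    min over r   Σ_θ c(θ, r_θ) + λ Σ_θ |r_θ − r_{θ−1}|,   |r_θ − r_{θ−1}| ≤ max_step

with defaults λ = 0.5 (per unit cost, cost scaled to [0, 1]) and
max_step = 2 pixels — values chosen to admit the steepest physiological
radius changes at the raster in use while suppressing speckle-induced
jumps.  The optimum is found by a first-order dynamic program over
A-line columns (accumulate, then back-track); for this cost class the
result is identical to fast-marching-style front propagation with
back-tracking, and the implementation is verified against exhaustive
enumeration of all admissible paths on small grids.

**Closed contours.**  The luminal contour is cyclic; its objective
includes the wrap smoothness term λ|r_first − r_last| and the wrap step
bound.  The exact cyclic optimum is found by anchoring at the column
containing the global cost minimum: a free-end solve gives a lower
bound (and is itself the exact answer when its endpoints coincide);
otherwise candidate anchor radii are pruned with an admissible
per-radius lower bound (first-column cost plus a backward free-end
table, ignoring only the wrap closure) against an upper bound from a
handful of fixed-start solves, and each surviving radius is solved
exactly.  In practice one to a few fixed-start solves suffice, making
the exact cyclic solve about as cheap as the open one.

**Ties.**  Cost ties resolve toward the smaller radius.  Rotating a
frame rotates the extracted contour, but a degenerate optimum may
resolve differently after rotation; equivariance therefore holds up to
optimal-path degeneracy (identical path cost), which is what the tests
assert.

**Thickness.**  Contours are converted to Cartesian millimetres
(A-line i at angle i·360/n_alines, counterclockwise).  The luminal
tangent comes from centred differences after an 11-A-line circular
moving average (pixel-level jitter otherwise dominates the normal
direction); the inward (into-the-wall) normal ray is intersected with
the abluminal polyline, and the Euclidean distance is the thickness at
that A-line.  Rays that miss are flagged and excluded from summaries.
The abluminal search window starts 40 µm beyond the lumen — below the
axial resolvability of two OCT interfaces — preventing contour
collision.  The representative thickness is the grand mean over five
randomly selected valid sites per frame (seeded, without replacement),
on frames every 0.5 mm along the plaque.

## Biplane reconstruction

The two views are modelled as orthographic projections at known
in-plane angles ≥ 30° apart.  The support half-width of an ellipse with
semi-axes (a, b) and orientation ψ seen from beam angle α is
H(α)² = a² sin²(α−ψ) + b² cos²(α−ψ).  Two widths cannot determine
(a, b, ψ); ψ is fixed to (α_A+α_B)/2 − 45°, which aligns the recovered
axes with the view frame when the views are orthogonal, and (a², b²)
follow from a 2×2 linear solve.  The remaining major/minor mirror
ambiguity is resolved toward orientation continuity with the previous
slice.  This convention recovers the true ellipse exactly when the
views are orthogonal and axis-aligned with it; for rotated view pairs
the inherent biplane ambiguity causes a small area bias (≈0.4 % at 15°
obliquity for the default ellipticity), which is why the
view-rotation-invariance test uses a 3 % band.

**Quantization-aware edge smoothing.**  Silhouette edge polylines are
quantized to the 76 µm angiographic pixel grid.  A quantized edge is a
staircase whose every sample constrains the true edge to ±q/2; the
sub-pixel information lives in the positions of the staircase
transitions.  Each edge is therefore smoothed by alternating a cubic
smoothing-spline fit (λ = 0.01) with projection back into the ±q/2
band (30 iterations): the result approximates the minimal-roughness
curve consistent with the quantization and removes the half-pixel bias
that any fixed-window filter keeps on quantization plateaus.  The
centerline is the back-projection of the two smoothed silhouette
midlines; arc-length is accumulated along it.  Slices are sampled at
0.1 mm.

Extensions of 5× the local mean radius are appended at the inlet and
outlets with the end cross-section unchanged; they are flagged and
never enter surface maps.

## Hemodynamic surrogate

Instead of volume-mesh CFD, the surface WSS is the exact fully
developed laminar solution of a straight elliptical duct applied
section by section: with flow Q and semi-axes a ≥ b,

    G = 4µQ(a²+b²)/(π a³ b³),
    τ(φ) = (G a²b²/(a²+b²)) · √(cos²φ/a² + sin²φ/b²),

which reduces to 4µQ/(πr³) for a circle.  The implementation is
cross-checked in the tests against an independent finite-difference
Poisson solve (Shortley–Weller boundary stencils, 201×201 nodes,
boundary shear evaluated at the semi-axis endpoints where the normal
aligns with the grid).  The surrogate neglects axial development,
curvature-induced secondary flow and pulsatility; it preserves the
section-to-section WSS contrast that drives the risk map, and an
importer accepts externally computed CFD samples in the same format
when higher fidelity is available.

Parameters: blood viscosity µ = 3.5 mPa·s (typical literature value);
flow scaling Q = k·D^e with e = 2.27 and k = 10⁻⁶/3^2.27 m³ s⁻¹ mm⁻ᵉ
(≈1 mL/s at D = 3 mm), both configurable.  These scaling constants are
assumptions from the empirical coronary flow–diameter literature, not
values validated here.  At bifurcations the flow splits proportional to
D^e of the branch and the distal main vessel; conservation is exact by
construction.  Normalizing the binned map by its 50th percentile (over
covered bins) makes it invariant to any global rescaling of the inflow,
which is the property that motivates reporting normalized WSS at all.

## Shared grid, registration, fusion

Both maps live on one half-open grid: rows [iΔs, (i+1)Δs) with
Δs = 0.2 mm from the proximal end of the un-extended segment, columns
[jΔθ, (j+1)Δθ) with Δθ = 10°, angle 0 at the first section's major
axis, counterclockwise from proximal to distal.  Axial registration is
piecewise-linear through landmark pairs (linear extrapolation at the
ends, monotonicity enforced).  Rotational offsets are map-minus-OCT
branch orientations wrapped to (−180°, 180°], interpolated linearly in
frame index along the shortest arc between the two anchors and held
constant outside them.  Cap samples land at (s = axial(frame),
θ = A-line angle + offset(frame)) and are averaged per bin; bins
without cap samples are flagged and, at fusion, classified as if the
cap were above threshold (they can only be LOW or MED_WSS).  Region
fractions are reported both over all classified bins and over
cap-covered bins, since the cap map covers the plaque ROI while WSS
covers the whole segment.

Risk thresholds are inclusive: thin means cap ≤ 151 µm, high means
WSS ≥ 1.7 Pa.  The sensitivity analysis uses the explicit lists
141/151/161 µm and 1.6/1.7/1.8 Pa (the conventional rounded ±7 %
values) and reports, per region, the min/max relative area change
against the central map; a region empty in the central map reports 0
when it stays empty and infinity otherwise.

## The phantom: what it emulates and what it does not

The phantom is a straight tube with elliptical sections (default base
major semi-axis 1.85 mm, proximal-vessel calibre; ellipticity 0.85), a
compact cosine-bump stenosis (35 % depth over ±6 mm), two side branches
(arc-lengths 3 and 21 mm, orientations 60° and 200°, daughter diameters
2.2 and 1.8 mm), and a fibrous cap over s ∈ [9, 15] mm, θ ∈ [120°,
260°] whose thickness field is constant, a linear ramp, or a Gaussian
dip (default: 300 µm base dipping to 100 µm).  Two realism terms are
load-bearing for the angiographic path: a smooth lumen-radius
undulation (40 µm amplitude, 4 mm period) and a generic off-axis
vessel position on the detector (0.337, −0.211 mm).  Real lumens are
neither perfectly cylindrical nor centred, and without these terms the
76 µm silhouette quantization would become a *systematic* error that no
estimator could average away; with them it behaves as dither that the
band-constrained spline can exploit.

OCT frames are rendered as a piecewise radial template per A-line —
dark lumen (0.04), bright band (1.0) from the luminal border to the
abluminal cap border (or a default 0.8 mm wall band outside the cap),
then a darker exponentially attenuated region (0.45·exp(−Δr/0.5 mm)) —
with multiplicative Gaussian speckle (amplitude 0.2 by default, clipped
at ±3σ) and a linear per-frame rotation drift of 0.5°/frame emulating
catheter twist.  This exercises gradient-based segmentation and the
rotational registration; it does **not** claim physical OCT realism: no
speckle statistics of coherent imaging, no guide-wire shadow, no
eccentric catheter, no lipid/calcium contrast.  Passing the phantom
tests therefore demonstrates the correctness of the algorithms under
their stated models, not clinical-grade robustness.

Cross-sections are drawn in planes perpendicular to the tube axis; the
pullback coordinate and the angiographic arc-length are the same
coordinate by construction.  Clinical data would add frame-to-frame
motion and foreshortening that the phantom does not model.

**Problem sizes.**  The default study raster is 360 A-lines × 504
radial samples over a 4.3 mm scan depth (radial pixel ≈ 8.5 µm, the
resolution the thickness claims rely on), 24 mm pullback at 200 µm
inter-frame distance; the full clinical 968-A-line raster is available
via `PhantomConfig(n_alines=968)`.  The angular reduction leaves the
radial quantization — the accuracy-limiting factor for thickness —
unchanged.

## Degenerate inputs and tie-breaks

* Constant OCT frame → uniform cost 1 (no edge; the DP returns the
  smallest-radius path rather than erroring).
* No admissible path under the step bound / search window → a
  segmentation error naming the frame.
* Identical luminal and abluminal contours → thickness 0 (the normal
  ray is allowed to hit at distance 0).
* Fewer valid sites than requested in a frame → all available sites
  are used with a warning.
* Empty or zero-median WSS map → normalization error.
* All-missing risk map → fusion error.

## Known limitations

* The elliptical-section assumption cannot represent crescent or
  bifurcation lumens; the reported lumen-area correlation on the
  phantom quantifies only quantization and smoothing losses, not this
  model error.
* The ellipse-orientation convention leaves biplane reconstructions of
  obliquely oriented ellipses biased (see above); three or more views
  would be needed to resolve it.
* The rotational registration is linear between two anchors; real
  catheter twist between landmarks is unobserved, and the phantom's
  linear drift is exactly the case the interpolation can represent —
  the drift-recovery test validates the mechanism, not the clinical
  interpolation error.
* The hemodynamic surrogate is steady and unidirectional; oscillatory
  metrics (OSI, RRT) are out of scope.
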