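# Methods

This note documents the models, numerical choices and synthetic-data
design behind `edgesense`, and what the test suite does and does not
demonstrate about real micrographs.

## Cell spreading model

The spreading population is modelled by the axisymmetric linear diffusion
equation for the non-dimensional cell density u(r, t) = c(r, t)/K,

    ∂u/∂t = D (1/r) ∂/∂r (r ∂u/∂r),   0 ≤ r ≤ R,

with a symmetry condition at r = 0, zero flux at the physical well wall
r = R, and u(r, 0) = C0 for r ≤ a, 0 otherwise. Proliferation is omitted
deliberately: the assay design this package addresses suppresses
proliferation (Mitomycin-C pretreatment), so spreading is migration-driven.

Parameters and defaults:

| parameter | meaning | default | rationale |
|---|---|---|---|
| a | barrier radius | 3 mm | assay geometry |
| R | well radius | 7.8 mm | 15.6 mm well diameter |
| cell diameter | packed cell footprint | 25 µm | typical 3T3 fibroblast |
| K | carrying capacity | 1/diam² = 1600 /mm² | square packing |
| C0 | initial density | n/(K·π·a²): 0.221 (10k), 0.663 (30k) | uniform seeding |
| D | cell diffusivity | **required**; study configs use 1000 (10k) and 2000 (30k) µm²/h | see below |
| dr, dt | grid/time steps | 0.01 mm, 0.01 h | front resolved by ~50 nodes |

D is assay-specific and must come from configuration; it is not a value
this package can derive. The study configurations ship
literature-scale fibroblast diffusivities chosen so that the low-density
front advances ~1 mm over 72 h, the distance scale reported for such
assays; the slightly larger value for the denser seeding reflects the
commonly reported density dependence of effective motility. These are
plausible defaults, not measured values.

### Numerics

The solver is a conservative finite-volume discretisation (faces at
r_{i±1/2}, cell volumes r_i·dr, half cells at both boundaries) with
implicit Euler stepping — one tridiagonal solve per step
(`scipy.linalg.solve_banded`). The r = 0 coordinate singularity uses the
standard symmetry limit 2·∂²u/∂r² , which is identical to the flux
balance over the axis half-cell of volume dr²/8; consequently the scheme
conserves the discrete mass to round-off (observed relative drift
~3·10⁻¹³ over a 72 h run) and, being an M-matrix scheme, satisfies the
discrete maximum principle 0 ≤ u ≤ C0.

Accuracy is validated against an independent oracle: the closed-form
infinite-domain solution for an initially uniform disk, evaluated by
Gauss–Legendre quadrature of the radial heat kernel with the
exponentially scaled Bessel function `ive` (valid while the front is far
from the wall). Observed convergence is first order in dt (consecutive-
difference ratio 2.0) and second order in dr. One subtlety: the step
initial condition assigns C0 to the grid point exactly at r = a, so the
discrete initial state represents a disk of effective radius a + dr/2;
spatial-order measurements compare against the oracle at that effective
radius, and absolute-accuracy checks use dr = 0.0025 mm, where the
solver matches the oracle to < 10⁻³.

Saved times must be integer multiples of dt (the solver steps exactly
onto them; no interpolation). Grids with fewer than 10 nodes across the
barrier trigger a warning.

## Synthetic micrographs

`sample_cell_positions` draws cell positions from a density profile by
inverse-CDF sampling of r·u(r) (trapezoid CDF, linear interpolation
within grid cells — radii can therefore smear one grid cell past the
support edge) with uniform angles. `render_assay_image` rasterises each
cell as a filled disk (pixel-centre rounding), composes overlaps by stain
saturation (minimum intensity), applies Gaussian blur, adds Gaussian
noise and clips to [0, 1].

Defaults: 0.01 mm/px (a 25 µm cell is 2.5 px, matching low-magnification
stereo-microscope imagery), background 0.95, stain depth 0.9 (crystal
violet is high-contrast), blur σ = 1 px (10 µm, sub-cellular optics
blur), noise SD 0.001 (stained brightfield images are smooth; noise well
below the smallest meaningful gradient threshold). Stain polarity is
dark-on-light, invertible via `invert`.

What the generator does *not* emulate: cell shape/size variability,
staining heterogeneity, illumination gradients, optical vignetting, and
any agent-level motility (positions are independent draws from the mean
field). Passing tests therefore demonstrate correctness of the analysis
chain under a faithful mean-field image model, not robustness to every
real-image artifact.

A consequence of the point-cell texture model worth knowing: very high
gradient thresholds (S ≳ 0.4) respond to dense cell clumps rather than
the spreading front, so their detected region can *shrink* with time.
Real preliminary threshold screening exists precisely to discard such
settings; the pipeline reproduces it programmatically (below).

## Edge detection

Sobel kernels are normalised by 1/4 so that a unit intensity step has
gradient magnitude 1 (a ramp of slope s/px gives magnitude 2s); on
[0, 1]-scaled images, thresholds S ∈ [0.01, 0.5] are then meaningful
fractions of the intensity range. A constant offset is subtracted before
convolution so flat images give exactly zero magnitude.

Manual pipeline: magnitude > S → dilation with a disk of radius 7 px
(isotropic; configurable) → hole filling → removal of border-touching
objects → selection of the population component (the component containing
the image centre, falling back to the largest — the fallback keeps the
detector translation-invariant on off-centre fixtures) → erosion with the
same disk → 5×5 median smoothing → single-component mask; area =
pixel count × scale². On sharp disk fixtures the area is accurate to
< 1 % across the whole threshold range.

Automatic variant: S = 4 × mean gradient magnitude (the conventional
Sobel auto-cutoff), clamped to (0, 1); constant images are rejected. No
attempt is made to replicate any proprietary toolbox bit-exactly — only
envelope consistency with the manual sweep is claimed.

Interactive-tool-style variant: unnormalised 8-bit Sobel behaviour is
emulated by scaling the magnitude by 4 and clipping to the intensity
range (moderate edges saturate, as in 8-bit edge enhancement), then 3×3
sharpen, IsoData (iterative intermeans) binarisation, disk(7) closing and
hole filling (the interactive wand traces the *enclosing* contour), a
second edge pass to outline the region, and flood fill from the image
centre; a flood that reaches the border signals an open contour and is an
error. Fixture error is ~0.02 %.

## Threshold band and summary statistics

The manual sweep uses the grid S ∈ {0.01, 0.02, …, 0.50}. The usable
band [S_min, S_max] is then selected by the preliminary-screening rule: a
threshold is usable if detection succeeds on every study image and the
replicate-mean area is non-decreasing in time (within a 2 % slack for
replicate noise) in every condition — a leading edge must track the
spreading front outward. On the default synthetic study this yields
approximately [0.01, 0.35].

A(0) conventions: the manual method uses the average of the minimum and
maximum mean initial areas over the band, applied to all manual M(t) of
the condition; automatic methods use their own t = 0 mean area. These
conventions reproduce the published worked-example tables for the
automatic pipelines to ±0.1 (the published interactive-tool rows for the
sparser assay are not consistent with any single-A(0) convention and are
excluded from checks). Standard deviations use the n−1 estimator;
percentages are reported to one decimal.

## Density calibration

A detected area A is interpreted as the model contour c = u(√(A/π), t),
read off the monotone decreasing front by piecewise-linear interpolation
(consistent with the solver's second-order spatial accuracy); the
inverse map is the same interpolation, so the round trip is exact to
< 10⁻⁶. S_min (largest area) pairs with c_min (lowest contour), S_max
with c_max, and intermediate thresholds are assigned linearly — the
linear form is an assumption, consistent with the observation that
varying the threshold shifts the detected edge smoothly through the
front. Endpoints of the map are snapped exactly.

On fully self-consistent synthetic studies (images sampled from the
solved profile), the recovered bands lie at roughly 2–6 % of the maximum
packing density at every time — the detected "leading edge" is a
low-density contour, not the population bulk — and the per-time bands of
a condition overlap each other: varying the threshold corresponds to a
*consistent* density variation over time, even though the area spread
(and hence the M(t) spread) between S_min and S_max grows steadily as
the front becomes more diffuse. The band is approximately time-invariant
rather than widening because the texture-driven detection responds to
local density, whose contour structure the spreading front transports
outward.

## Problem sizes

Synthetic-study runs use an 11 mm field at 0.01 mm/px (1100² px; the
well rim, which the spreading front never approaches, is cropped as in
real micrographs — the rare far-tail cell falling outside the field is
not rendered), three replicates per condition/time, and a 25-point
threshold grid in the acceptance script (11-point in the session test
fixture); solver checks use dr down to 0.0025 mm. These sizes keep a
full study in the minutes range on one CPU while leaving every claimed
property comfortably resolved.

## Known limitations

* The linear S→c map is assumed, not derived; only its endpoints are
  anchored by area inversion.
* Calibration requires a monotone decreasing front; profiles near the
  well-mixed limit (or contour levels below the boundary value) are
  rejected rather than handled.
* The automatic-threshold and interactive-tool variants emulate behaviour
  classes, not specific software versions.
* D is a configuration input; fitting D from edge data is out of scope.
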