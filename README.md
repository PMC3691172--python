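# edgesense

Threshold-sensitivity analysis of leading-edge detection in circular
barrier (cell spreading) assays.

## The problem

In a circular barrier assay a population of cells is seeded inside a
removable barrier (radius 3 mm) at the centre of a tissue-culture well
(diameter 15.6 mm); the barrier is lifted and the population spreads
outward. The standard migration measure is the percentage change in the
area enclosed by the population's leading edge,

    M(t) = 100 · (A(t) − A(0)) / A(0),

where A(t) is estimated by segmenting micrographs of the fixed, stained
population. The leading edge, however, is an *operational* quantity: it is
whatever the segmentation pipeline finds, and as the spreading front
becomes diffuse, different — individually reasonable — detection settings
disagree substantially. For the same images, M(t) can differ by more than
25 percentage points depending only on the Sobel sensitivity threshold.
`edgesense` quantifies this sensitivity end to end and gives the
threshold a physical meaning as a cell-density contour.

The package provides:

* **synthetic data** — barrier-assay micrographs rendered from a known
  radial cell-density field (stained cells dark on a light background,
  Gaussian optics blur, sensor noise), so every downstream stage can be
  validated against ground truth without any experimental data;
* **edge detection** — three Sobel-based pipelines: a manual method with a
  user-set threshold S (all edges weaker than S are excluded, then
  dilation, hole filling, border clearing, erosion, median smoothing), an
  automatic variant (S = 4 × mean gradient magnitude), and an
  interactive-tool-style variant (edge enhance, sharpen, IsoData
  binarisation, wand-style region tracing);
* **migration metrics** — replicate means/SDs, equivalent circular radii
  √(A/π), M(t), and threshold-sweep envelopes;
* **diffusion model** — the axisymmetric linear diffusion equation
  ∂u/∂t = D (1/r) ∂/∂r (r ∂u/∂r) for the non-dimensional density
  u = c/K (carrying capacity K = 1/diameter² under square packing,
  1600 cells/mm² for 25 µm cells), with a step initial condition u = C0
  for r ≤ a, symmetry at r = 0 and zero flux at the well wall — solved by
  a conservative finite-volume scheme with implicit Euler stepping;
* **density calibration** — inversion of detected areas to contour levels
  of u(r, t) and the linear map c(S) from the usable threshold band
  [S_min, S_max] to the bracketing contour band [c_min, c_max].

## Worked example

```python
import edgesense as es

# M(t) arithmetic on published mean areas (10,000-cell assay, automatic
# gradient-threshold method): A(0) = 29.0 mm², A(72 h) = 44.6 mm²
es.migration_rate(29.0, 44.6)      # -> 53.8   (percent)
es.equivalent_radius(44.6)         # -> 3.768  (mm)

# ground-truth fixture: a sharp 3 mm disk, true area π·9 ≈ 28.274 mm²
params = es.RenderParams(image_size=700)
disk = es.make_disk_fixture(3.0, params)
es.detect_edge_manual(disk, 0.05).area   # -> 28.520 mm²  (+0.9 %)
es.detect_edge_manual(disk, 0.5).area    # -> 28.449 mm²  (+0.6 %)

# density model: 10,000 cells inside the 3 mm barrier
K = es.carrying_capacity(25.0)            # -> 1600 cells/mm²
C0 = es.initial_density(10000, 3.0, K)    # -> 0.221
profile = es.solve(es.ModelParams(D=1000.0, C0=C0), [0.0, 24.0, 48.0, 72.0])

# which density contour encloses a detected area of 40 mm² at 72 h?
from edgesense.calibration import area_to_contour
100 * area_to_contour(profile, 72.0, 40.0)   # -> 1.36  (% of K)
```

On sharp fixtures all thresholds agree to within a percent; on diffuse
spreading fronts they do not, and the calibration expresses each
threshold as the cell-density contour (a few percent of the maximum
packing density) that its detected edge follows.

A full synthetic study — two seeding conditions (10,000 and 30,000
cells), four times (0–72 h), three replicates, a threshold sweep per
image, and the density calibration — runs from the command line:

```
edgesense run-all --seed 1 --out study_out
```

writing the rendered images, per-image detections, summary statistics
(`summary.csv`), threshold-sweep envelopes, calibration maps
(`calibration.json`) and a reproducibility manifest. Repeated runs with
the same seed produce byte-identical tables.

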