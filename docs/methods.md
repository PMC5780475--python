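# Methods

## The measurement model

A PTA-stained kidney in a micro-CT volume is treated as a mixture of
grey-value (GV) populations, one per anatomical compartment, ordered by
contrast uptake: cortex > medulla > pelvis/cavities ≈ air. Classification
is purely intensity-based — no spatial regularization or region growing —
so the whole quantification reduces to (i) isolating the organ, (ii)
decomposing the organ's GV histogram into overlapping Gaussian classes, and
(iii) reading class borders off the histogram envelope. All geometry is
voxel-based with isotropic spacing; the physical center of voxel *i* is
`origin + (i + 0.5) · spacing`, volumes are `count · spacing³` (mm³),
areas mm², lengths mm.

### Organ segmentation

Voxels at or above a threshold (user-set, or Otsu's two-class threshold for
`auto`), reduced to the largest 26-connected component, interior holes
filled in 3D. Hole filling is essential, not cosmetic: unstained cavities
(pelvis, vessel lumina) lie inside the organ and must count toward
V_kidney, because the histogram method expects them inside the organ VOI as
the lowest GV class. Component-size ties break deterministically toward
the smallest first linear index.

### Histogram classes and boundaries

The organ histogram (default 256 equal-width bins over the masked range;
unit-width "native" bins by flag) is fitted with a k-component Gaussian
mixture by EM on the binned counts (k = 3 inside an organ mask; a
full-field histogram needs k = 4, with the lowest class being air, and the
air class is discarded before compartment mapping). EM details:

- **Initialization** is deterministic: the bins are partitioned at the
  multi-Otsu thresholds for k classes and each component starts at its
  class's weighted mean/SD/weight. A fixed-percentile start
  (20/50/80) was tried and rejected: with a ~72% cortex class two
  components initialize inside the dominant mode and EM converges to a
  degenerate local optimum (two nearly identical means, no usable
  boundary).
- Convergence at 1e-8 relative log-likelihood change, max 500 iterations;
  SDs floored at half a bin width; a non-converged fit is returned with
  `converged=False` and a warning, never silently.
- The fitted envelope is the mixture density itself, so curvature is
  analytic — no smoothing noise enters the boundary search. A
  `smoothed_numeric` fallback applies the same rules to a Savitzky–Golay
  smoothed histogram (window ≈ bins/10, polyorder 3) for envelopes the
  parametric fit cannot represent; the boundary object records which method
  produced it.

**Boundary rule.** Between adjacent component means the envelope is either
bimodal (a resolved valley) or a merged shoulder. When bimodal, the
interior inflection-point pair brackets the valley and the border is the
valley bottom — for an equal symmetric mixture this is exactly the
inter-mean midpoint, and for well-separated classes it approaches the
misclassification-minimizing crossing of the component densities. When the
classes have merged (no interior minimum), the border is the curvature
zero-crossing nearest the inter-mean midpoint. Picking an inner inflection
point even when a valley exists was rejected: those points sit near
mean ± SD of the flanking components and systematically transfer one
class's tail to its neighbour (errors of several percentage points on
phantoms with known fractions).

Classes map in ascending GV to pelvis (+ cavities and vessel lumina),
medulla, cortex; the cortex is the brightest class, from the upper
threshold to the maximum GV. Bins belong wholly to the class containing
their center, so class volumes partition the masked volume exactly.

### Cortical thickness and the √A/Cth index

Cth is deliberately the 2D quantity measured on the central frontal slice
(middle of the organ's bounding box along the slice axis, default axis 1).
Sites are capsule points at `n_sites ≥ 5` evenly spaced polar angles
starting at 12 o'clock around the in-slice centroid — a deterministic
realization of "at least five positions". Each site's thickness is the
in-plane shortest distance from the capsule point to the nearest interior
voxel below the cortex threshold (medulla or cavity). The shortest
(perpendicular) distance, not the oblique ray length toward the centroid,
is used: on elongated organs the radial ray crosses the cortex shell at an
angle and overestimates by ~10%, while the perpendicular distance matches a
3D distance-transform oracle on ground-truth labels to within 5%
(`label_thickness_3d`, reported for QC but never as Cth). Sites whose
profile never leaves the cortex class are skipped with a warning; fewer
than five valid sites is an error.

The index √A_kidney/Cth is dimensionless and scale-invariant (both √A and
Cth scale linearly with the organ), so healthy kidneys of different sizes
share a common value. Note on conventions: the bundled reference
measurements report surface areas of ~33–49 mm² for 190–340 mm³ organs,
which is smaller than the minimal closed surface of such volumes — those
values evidently follow a planar/projected-area convention. This package
reports the true 3D isosurface area; the index formula is the same either
way, but index values computed from 3D areas are on a different scale than
the bundled reference indices and must not be mixed with them.

### Surface area

Marching cubes on the binary mask followed by Taubin mesh smoothing
(λ–µ smoothing preserves volume and flat faces). Plain binary marching
cubes carries a ~9% staircase overestimate on curved surfaces; Gaussian
pre-smoothing of the mask fixes spheres but rounds sharp edges (a 1 mm
cube loses ~10% of its area). Taubin smoothing with the iteration count
scaled to voxel size (≈1.6 mm / spacing, clamped to [10, 200]) keeps a
fixed physical smoothing length: sphere-area errors fall 1.1% → 0.3% →
0.2% across 80/40/20 µm voxels and a 1 mm cube stays within 5%.

### Cube-based cortical radio-opacity

Sampling cubes (default edge 0.5 mm = 0.125 mm³, six per kidney) must lie
wholly inside the cortex class. Feasible centers are voxels whose
distance to the class boundary is at least half the cube's space diagonal
(edge·√3/2); the first center is the deepest such point and the rest follow
farthest-point sampling — deterministic, reproducible, and "evenly
distributed" by construction (manual placement is not reproducible). If the
cortex is too thin the error reports the largest feasible edge. Per-cube
min/mean/max GV are computed over voxel centers inside the cube; the
kidney-level aggregate is the mean of cube means (and max of cube maxima).

### Group comparison

Two-sided unpaired t-test, pooled-variance Student by default (Welch by
flag), accepting raw values or (mean, SD, n) summaries; SDs use n−1. The
statistical unit is the kidney (n = 4 per group in the reference design,
pooled df = 6): with the bundled reference summaries
(3575 ± 94.5 vs 3039 ± 105.5 GV) this yields p = 2.8 × 10⁻⁴, printed as
0.0003, which is what fixes the kidney-level aggregation — pooling the 24
cubes would give df = 46 and a very different p. Degenerate input (zero
variance, equal means) returns t = 0, p = 1. Cortical volume loss is
100·(1 − V_uuo/V_sham), assuming both kidneys of an animal started equal.

## The phantom

Compartments are nested *similar* ellipsoids: for target volume fractions
(pelvis, medulla, cortex) the inner shells' linear scales are cube roots of
cumulative fractions (s³ = cumulative fraction — exact for proportionally
scaled ellipsoids, so the geometry stays analytic and voxel-count oracles
are exact up to discretization). Grey values are drawn i.i.d. per voxel
from the compartment's Gaussian, optional global detector noise is added,
and everything clips to the 16-bit detector range [0, 65535].

Defaults model a healthy adult mouse kidney: semi-axes 5.2/3.4/2.9 mm
(V ≈ 215 mm³, inside the 188–341 mm³ reference range), fractions
0.12/0.16/0.72 (the reference cohort means), classes
pelvis 500 ± 80, medulla 2500 ± 150, cortex 3575 ± 94.5 GV, background
(air/medium) 100 ± 30 GV, spacing 0.04 mm. Class means for pelvis and
medulla are not printed anywhere in the reference material; they were fixed
once at round values consistent with the observed ordering and the
detector scale, with gaps wide enough that the three classes are resolved —
the regime the original analysis itself operates in. The cortex mean/SD are
the measured healthy cube statistics. Optional extras: unstained vessel
lumina (random cylinders labelled as cavities), dark glomerular dots
(50–100 µm, off by default — only meaningful at 12.5 µm spacing).

Pathology operates on the label/intensity pair, not the generating
geometry, so it applies to any phantom: **UUO** converts the innermost
medulla voxels to cavity until the pelvis has grown by the dilation factor
and only `medulla_retention` of the medulla survives (converted voxels are
resampled from the phantom's own pelvis GV distribution), then shifts all
cortex GVs by `cortex_gv_shift` (−536 GV reproduces the measured sham/UUO
gap 3575 → 3039). **Cysts** are spheres relabelled to cavity with
pelvis-like GVs; a sphere reaching outside the organ is rejected.

What the phantom does *not* emulate: PTA diffusion kinetics, beam
hardening/scanner artefacts, partial-volume blur at compartment borders,
anatomical texture (tubule bundles, medullary rays), organ asymmetry
(real kidneys are bean-shaped, not ellipsoidal), or between-animal
biological variance of class means. Consequently passing tests demonstrate
the *statistical* correctness of the pipeline under the assumed mixture
model — class recovery, boundary placement, morphometry and test operating
characteristics — not robustness to scanner physics. In particular the
sham-cohort spread of cube means on phantoms (~8 GV) is far tighter than
the measured between-kidney SD (~95 GV), because phantom kidneys differ
only by sampling noise; power estimates on phantoms are therefore
upper bounds.

## Validation studies and problem sizes

The simulation studies (`renalvh.studies`, driven by `analysis/`) use a
scaled-down geometry chosen once: semi-axes 2.4/1.8/1.5 mm at 80 µm
voxels with 0.25 mm cubes — the same compartment fractions, GV classes and
4-kidneys × 6-cubes design, at roughly 1/9 the voxel count, so one full
cohort replicate (8 phantoms through the entire pipeline) runs in under
half a second and the 100-replicate power and 200-replicate null studies
complete in minutes on one CPU. Grey-value parameters are never scaled.
Observed under these conditions (analysis drivers, seeds as committed):
fraction recovery mean |error| ≈ 0.00 pp over 20 phantoms spanning 60–80%
cortex; detection power 1.00 at α = 0.01; sham-vs-sham false-positive rate
0.070 against nominal 0.05.

## Degenerate inputs and tie-breaking (summary)

- Missing/zero voxel spacing, anisotropic NIfTI headers: hard errors —
  never a silent default.
- Empty segmentation, empty masks, thresholds outside the histogram range,
  cysts outside the organ, shells thinner than a voxel: errors with
  diagnostics.
- Empty GV class in volumetry: fraction 0 with a warning (not an error).
- All ties (component size, farthest-point candidates, argmin over flat
  valleys) resolve to the smallest index — every run is bit-reproducible
  under a fixed seed, and the full pipeline report is byte-identical JSON.

## Known limitations

- Intensity-only classification cannot separate compartments whose GV
  distributions genuinely overlap beyond bimodality; the shoulder rule then
  places a border but the class volumes inherit the ambiguity.
- Cth is a single-slice measurement by design; organs whose central frontal
  slice is atypical need the `slice_index`/`slice_axis` overrides.
- The 3D isosurface area convention differs from the projected-area
  convention of the bundled reference measurements (see above); comparing
  index values across conventions is invalid.
- One organ per volume; no multi-organ scenes, DICOM, reconstruction, or
  3D rendering.
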