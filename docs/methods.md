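# Methods

## Scar segmentation (FWHM)

Scar is segmented inside the myocardial mask (the region between the endo-
and epicardial contours, rasterized by pixel centre with the even-odd rule)
by thresholding at half of the enhancement range,
`T = I_min + 0.5 (I_max − I_min)` over myocardial intensities.  The
half-maximum is referenced to the myocardial minimum because that variant is
invariant to global intensity scaling *and* offsets; the plain `0.5·I_max`
reference is available via `reference="max"`.  The reference statistics are
computed per slice by default — slice-to-slice coil shading then cannot bias
the threshold — with a per-volume option (`per_volume=True`) for uniformly
scaled acquisitions.  Connected components smaller than `min_component_px`
(default 5) are removed as noise; this cleanup is a noise-suppression step,
so exact-recovery checks on noiseless data disable it.  A slice with uniform
myocardial intensity has no half-maximum; it yields an empty scar mask and a
logged warning rather than an error.

## Surface maps

Endocardial contours are resampled to `points_per_slice` (default 120, i.e.
3° angular resolution) equal-arc-length vertices starting where the +x ray
from the contour centroid crosses the contour, so rings of adjacent slices
correspond by index and stitch into a tube mesh.  Both scalar fields are
measured along the same in-slice chord per vertex:

* **Wall thickness** — distance along the outward endocardial normal
  (central difference of the neighbouring ring vertices, oriented away from
  the centroid) to the first crossing of the epicardial polyline.  If the
  normal ray misses the epicardial contour (possible at sharp concavities),
  the ray from the contour centroid through the vertex is used; if both
  miss, an error names the slice and angle.
* **Transmurality** — 100 × (chord length through scar pixels) / (chord
  length), sampled at a quarter of the pixel spacing.

Chords are 2-D in-slice because both quantities are defined by the
short-axis measurement convention; a 3-D formulation would require a
long-axis definition that the planning workflow neither has nor needs.
Scalars live on vertices (targets and distances are point-based).  With a
pixel spacing `s` and wall thickness `WT`, voxelization limits per-vertex
transmurality accuracy to roughly `100·s/WT` percentage points — about 8 pp
at the default 0.8 mm / 10 mm, and 2 pp on the 0.2 mm grid the fine-grid
tests use.

## Planner

IBZ: `low ≤ T ≤ high` (defaults 1–20%, both bounds inclusive) and
`WT > wt_min` (default 5 mm, strict).  Danger: `T > high` or `WT < wt_min`.
A vertex at exactly WT = 5 mm is neutral (neither "> 5" nor "< 5").
Sectors split the circumference at ±90° around a user-supplied septal
direction (the phantom emits it; real data needs the operator to supply it,
since image axes alone do not identify the septum).  Within each sector,
targets are chosen by greedy farthest-point sampling over IBZ vertices in
3-D, seeded at the IBZ vertex radially closest to the sector centre.  Greedy
dispersion is deterministic, satisfies the classic factor-2 bound on the
optimal k-dispersion, and realises "equally distributed" without any
randomness; ties break to the lowest vertex index.  Needle depth is
`needle_depth_fraction × local WT` (default one half).  A sector with fewer
IBZ vertices than requested raises an error listing the deficit rather than
silently under-delivering targets.

## Registration

Stage 1 emulates the interactive "align the volumes first" step of a fusion
workstation as centroid matching plus principal-axes alignment; the four
proper axis-sign combinations are disambiguated by symmetric nearest-
neighbour RMS, and a rank-deficient cloud degrades to centroid-only
alignment with a warning.  Stage 2 is trimmed point-to-point ICP: per
iteration, nearest-neighbour correspondences, keep the best
`1 − trim_fraction` (default 80%) by distance, closed-form SVD rigid fit,
stop when the trimmed RMS improves by less than `tol` (default 1e-4 mm) or
after `max_iter` (default 100) iterations.  The trimmed RMS is non-
increasing across iterations by construction.  Trimming absorbs partial
coverage of the interventional surface; registration is rigid only, since
both modalities are metric.

## DICOM export

Each target becomes its own secondary-capture DICOM series in the geometry
of the base volume: endocardial sample points at intensity 1 and the target
as a filled sphere (default radius 2 mm) at intensity 1000 — a viewer-
agnostic encoding that any workstation can overlay.  The JSON sidecar per
target carries the exact millimetre coordinates, sector and needle depth and
is the authoritative record; the voxelization is for display.  Coordinates
are DICOM patient (LPS) mm throughout; NIfTI I/O converts from RAS at the
boundary.  Integer-valued volumes round-trip bitwise through the writer;
arbitrary floats are linearly quantized to 16 bits with slope/intercept
recorded.

## Evaluation endpoints

An injection is projected onto the endocardial ring of its slice (nearest
slice with a non-empty IBZ arc if its own has none; the out-of-plane offset
is reported separately).  The distance to the IBZ band is the minimal arc
length along the ring, zero inside the band.  **Sign convention:** negative
when the shorter path borders the region with transmurality above the upper
bound (infarct side), positive when it borders the sub-threshold (remote)
side.  Depth is the perpendicular point-to-contour distance, positive into
the wall; blood-pool-side injections come back negative with a warning.
Distances are per-slice 2-D measurements, matching scoring on transversal
tissue slices; no 3-D geodesic across slices is attempted.  Repeated
measurements are averaged per animal before any group comparison, so each
animal contributes one observation.

## Statistics

`ttest_from_summary` implements the two-tailed unpaired t test from
per-group (mean, sd, n): pooled variance with `df = n_a + n_b − 2` by
default, Welch–Satterthwaite as an option.  Published tables carry only
those summaries, which is exactly what this entry point recomputes; the
pooled default reproduces the printed p-values of the study tables this
package's evaluation mirrors (e.g. 0.355 for injection-procedure time), but
because table inputs are rounded to one decimal, exact reproduction of every
cell is not expected and the sample-based path retains full precision.
`ttest_from_samples` is *defined* as the summary test applied to the
samples' own statistics, so the two paths cannot disagree.  Degenerate
zero-variance input: equal means give p = 1 by convention, unequal means
p = 0 with a warning.  Shapiro–Wilk uses the standard approximation (3 ≤ n ≤
5000; constant samples are an error); chi-square is Pearson's without
continuity correction.

## The phantom: what it emulates, what it does not

The phantom is a stack of circular annuli: per slice an endocardial radius,
wall thickness, and an angular scar wedge whose transmurality profile sets
the infarcted innermost fraction of each radial chord.  Defaults (the
conditions all pipeline-level tests run under):

| parameter | default | why |
|---|---|---|
| slices × spacing | 8 × 5 mm | short-axis coverage of a porcine LV |
| endo radius | 20 mm at base, apex taper 0.5 | LV cavity scale; strong apical taper as in a real ventricle |
| wall thickness | 10 mm | healthy porcine LV wall |
| scar wedge | [60°, 120°) | 60° antero-septal wedge straddling the septal/anterior boundary, so the IBZ spans both planner sectors |
| transmurality profile | two-slope ramp, 30% at 60% of half-width from edge, 100% at core | graded border zone with a shallow peripheral tail flanking a dense core; a knife-edge ramp would make the 1–20% band thinner than the 3° vertex spacing |
| intensities | remote 100, scar 300, background 30 | 3:1 hyperenhancement contrast; background below myocardium |
| noise | Gaussian, sd 10 (10% of remote) | threshold/geometry pipeline needs no Rician magnitude bias |
| pixel spacing | 0.8 mm | high-resolution LGE in-plane scale |
| centre drift | (3.5, 1.75) mm/slice | oblique long axis in patient coordinates |

Centre drift and apex taper are not cosmetic: a straight stack of equal
circles is a surface of revolution, so rotation about the long axis would be
unobservable from the epicardial surface and rigid registration would be
ill-posed — unlike a real heart.  The drift-plus-taper geometry constrains
all six rigid degrees of freedom, which is what makes the apply-and-recover
registration tests meaningful.

The interventional surface is emulated by sampling the epicardial contours
(300 points/slice), applying the "unknown" rigid transform, adding isotropic
Gaussian jitter and randomly subsampling; the ground-truth transform is
returned for testing.

Not emulated: MRI physics (partial volume, Rician noise, surface-coil
shading), papillary muscles and trabeculation, breathing/cardiac motion,
non-circular cross-sections, and a 3D-RA surface that includes more of the
thorax than the LV epicardium.  Passing tests therefore demonstrate the
correctness of the geometry, segmentation, planning, registration and
scoring machinery under known ground truth — not robustness to real image
artefacts or anatomical variability.

## Numerical conventions

Right-handed patient space in mm, slices apex→base with strictly increasing
z, angles CCW from +x in-slice; indices 0-based, intervals half-open.
Contours are implicitly closed, at least 8 points, non-self-intersecting; a
polyline whose implicit closing segment exceeds 25% of its perimeter is
rejected as an open arc.  Phantom generation, planning and ICP are
deterministic given their seeds/configs (farthest-point ties break to the
lowest index).  Noiseless voxel classification and the truth masks use the
same pixel-centre rule, so they agree exactly by construction.

## Problem sizes used in the tests

The default suite runs the full pipeline on the 8-slice phantom
(157×157×8 voxels, 960 mesh vertices), 20-seed registration recovery,
100 random-toy comparisons of the signed IBZ distance against a dense
exhaustive search, and 1000-replicate null calibration of the t test —
sizes chosen so the whole suite gives tight checks in well under a minute.
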