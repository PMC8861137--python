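# Methods

## The measurement model

CT-osteoabsorptiometry treats the subchondral bone plate (SBP) of a
vertebral endplate as a thin shell whose local mineral density is
proportional to the long-term mechanical load it has carried. The
package measures that density field in three steps: isolate the shell,
project its peak attenuation onto the endplate plane, and reduce the
resulting 2D map to comparable statistics.

**Axis conventions.** Volumes are indexed `(x, y, z)` = (mediolateral,
anteroposterior, craniocaudal) with z = 0 at the cranial end.
Densitograms are `(row, col)` with row 0 at the anterior edge and
col 0 at subject-left; the fixed raster is 50 columns × 40 rows, the
wide axis mediolateral (lumbar endplates are wider than deep).

**Shell definition.** Historical CT-OAM isolated the SBP by hand. Here
it is algorithmic and reproducible: for each in-plane column the first
mask voxel from the chosen end is the surface, and the shell extends
`depth_mm` into the bone (`depth_vox = max(1, round(depth_mm / dz))`),
clipped to the mask so it can never exit the bone. The rendered plate
thickness is not a published quantity; the 2 mm default is this
package's choice and is the main exposed tunable. Columns whose surface
voxel is an outlier are *not* silently corrected.

**Orientation.** The en-face view is obtained from user-supplied Euler
angles (the historical workflow rotated interactively; automatic pose
estimation is out of scope). The volume is resampled trilinearly onto
an isotropic grid at the finest input spacing — the clinical inputs mix
1 mm coronal and 1.5 mm sagittal acquisitions, and resampling to
isotropy before projection is where that anisotropy is resolved — and
the mask nearest-neighbor, on a grid tightly cropping the rotated mask
with a 2-voxel margin. The rotation center defaults to the mask
centroid and is overridable.

**MIP densitogram.** Each valid pixel holds the maximum HU over its
column's *shell* voxels only; projecting whole columns would leak
trabecular or cortical-wall signal. Background pixels carry NaN and
valid = 0, never HU 0 (0 HU is water/tissue, a legitimate value).

**Calcium quantification.** Relative calcium concentration is the
absolute calcium content (per-pixel calcium × pixel area, summed)
divided by plate area (valid pixels × pixel area); the two integrals
reduce exactly to the area-weighted mean per-pixel calcium, reported in
mg/ml. The default calibration line through (0 HU, 0 mg/ml) and
(1000 HU, 600 mg/ml) is a **configurable placeholder**: no public
HU→calcium lookup exists for this workflow, so every cohort statistic
the package reports is a ratio, which is slope-invariant whenever the
intercept is 0. Predictions are clamped at 0 and extrapolation beyond
the fitted HU range is flagged.

## Rasterization and maxima

Each densitogram is resampled onto the 50×40 grid spanning the tight
bounding box of its footprint, so plates of different sizes become
comparable. Cell values are exact area-weighted means: pixels are split
fractionally at cell borders (separable 1D interval overlaps), which
gives the conservation law Σ cell·occupancy·cell_area =
Σ pixel·pixel_area to machine precision. Cells with occupancy ≤
`occupancy_min` (default 0.5) are background.

Local maxima are detected on the raster: a foreground cell is a maximum
iff strictly greater than every *foreground* cell among its neighbors
(8-connectivity default, 4 available). Strictness means plateaus yield
no maxima and isolated cells count — the simplest contract with an
unambiguous brute-force oracle; the original isMaxima routine's
tie/connectivity behavior is undocumented, so both are exposed as
configuration. When a plate has more than 20 maxima only the 20 highest
are kept, ties broken by row-major order.

## Mean maps

Matched rasters (same level, side, condition) are averaged per cell
over the images in which the cell is foreground, with a coverage count;
intersection-only averaging would discard the peripheral rim, which is
the region of interest. Cells seen in fewer than `min_coverage` images
(default: half, rounded up) are masked — whether the historical
workflow did this is unknown, so it is configuration, not contract.

Rendering maps 800–2200 HU linearly onto the jet scale with clamping at
both ends and a reserved background color. Bicubic smoothing uses the
cubic-convolution kernel (a = −0.5) with background-excluded,
renormalized support (normalized convolution); kernel exactness on
constants and, in the interior, on linear ramps is tested. Smoothing is
display-only: the >1000 HU high-mineralization maps (strict inequality;
1000 HU itself is *not* high) and their areas are computed on the raw
mean raster so the statistic is resolution-independent.

## Group statistics

Two-way fixed-effects ANOVA of relative calcium on condition × level
uses Type III sums of squares with sum-to-zero contrasts (statsmodels
OLS), appropriate for the unbalanced cohorts this design produces
(17 vs 18 subjects, 5–15 affected discs per level) and matching the
behavior of the mainstream commercial packages used for such analyses.
Superior and inferior plates are analysed separately. Level-wise
condition contrasts are Welch t-tests with Šidák adjustment
(p′ = 1 − (1 − p)^m, m = comparisons per side), significance at
p′ < 0.05.

Percent-of-healthy is `round(100·mean_DDD/mean_healthy)`, half away
from zero — the convention that reproduces the published integer
percentages from the published cohort means at five of six inferior
levels (the remaining level differs by 1 because the source's own means
are printed rounded). Per-subject motion-segment ratios divide the
inferior plate of the upper vertebra by the superior plate of the lower
one; subjects missing either plate are excluded and reported.

## The phantom generator

The phantom emulates what the analysis assumes about real endplates: an
elliptical-cylinder body (default semi-axes 22.5 × 17.5 mm, height
27 mm — a typical lumbar vertebra), a thin high-density shell on each
endplate, trabecular interior (150 ± 50 HU), air background, voxel
spacing 0.5 × 0.5 × 1 mm (clinical in-plane resolution and slice
thickness). The shell's in-plane field is

    pattern(x, y) = baseline
                  + A_ring·(1+s)·max(0, 1 − d(x,y) / (w·(1+s)))
                  + Σ A_hot·(1+s)·exp(−|r − r_hot|²/2σ²)
                  (+ dorsal-median term, sacral-like plates)

with `d` the Euclidean distance to the ellipse boundary and `s` the DDD
severity in [0, 1]: degeneration both raises (amplitudes × (1+s)) and
broadens (ring width × (1+s)) the peripheral ring, pointwise monotone
in severity. Defaults — baseline 400 HU, ring amplitude 700 HU (1100 HU
at the boundary, so the healthy ring crosses the 1000 HU threshold),
ring width 6 mm, two dorsolateral hotspots (350 HU, σ = 4 mm, at
(±0.62·ax, 0.62·ay)) — place the healthy plate mean near 380 mg/ml
under the default calibration, in the range reported for healthy lumbar
plates, and reproduce the peripheral-ring-with-dorsolateral-accents
geometry. Gaussian HU noise (default sd 25 HU, a typical clinical bone
noise level) is added per shell voxel; volumes are integer HU.

Cohorts add a log-normal per-subject scale on baseline and amplitudes
(default σ = 0.08, matching the ~9 % coefficients of variation of the
published healthy cohort); healthy subjects get severity 0. Because the
field is linear in its amplitudes, a subject's analytic truth is just
scale × footprint mean, and `severity_for_mean_ratio` can solve (by
monotone bisection) for the severity whose analytic DDD/healthy ratio
equals a target such as 1.34.

**Ground truth.** The footprint mean of the pattern is integrated
numerically on a grid 10× finer than the voxel resolution, restricted
to the analytic ellipse. The boundary distance is solved from the
ellipse stationarity condition by safeguarded bisection on a bracketed
monotone root (well below 1e-9 mm at 100 iterations; a pure Newton
iteration can escape its basin for points near the evolute, so the
bracketed form is used).

**What the phantom does not model** — and hence what passing tests do
not establish about clinical data: kidney-shaped endplate outlines,
curved (non-planar) plates, trabecular microarchitecture, scanner noise
spectra and beam hardening, segmentation error in the masks, and any
coupling between degeneration and plate geometry. Recovery results on
phantoms validate the pipeline's arithmetic, not the biological claim.

## Numerical choices and sizes

* Noiseless end-to-end recovery agrees with analytic truth to ~0.03 %
  at 0.5 mm voxels; the 1 % test tolerance absorbs footprint
  discretization at the rim.
* With shell noise, the per-column MIP over a 2-voxel shell is the
  maximum of 2 noisy draws and is biased upward by ≈ 0.56 σ ≈ 14 HU
  (~2 %); this cancels in DDD/healthy ratios, which is another reason
  the package reports ratios.
* Cohort recovery tests use n = 15 per arm at one level — the size of
  the largest published DDD level group — and run in seconds at the
  default phantom resolution.
* ANOVA null calibration uses 1000 replicates of a balanced 2×3 design
  with n = 5 per cell; the empirical type-I error at α = 0.05 is
  checked against [0.035, 0.065].
* Densitograms are stored as 2-page 16-bit TIFF (values + 1024 offset
  so negative HU survive; mask page) with a JSON sidecar for spacing
  and identity; integer HU round-trip bit-exactly.
* Maxima tie-breaks, grid origin (row 0 anterior, col 0 subject-left)
  and 0-based indices are fixed conventions so maxima tables from
  different runs are comparable.

## Known limitations

* The HU→calcium calibration is a placeholder interface; absolute
  mg/ml values are only meaningful relative to a user-supplied
  calibration.
* Vertebra segmentation and pose are inputs, not outputs: the package
  does not segment raw CT or estimate endplate orientation.
* The shell model (first bone voxel + fixed depth) is a reproducible
  surrogate for manual rendering, not a reconstruction of it.
* Superior and inferior plates enter separate ANOVAs; whether the
  original analysis pooled them in one model is not stated in the
  source material, so the package makes its own (documented) choice.
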