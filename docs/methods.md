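# Methods

## Measurement pipeline

The unit of raw input is a *mask stack*: an ordered set of per-B-scan binary
segmentations of the Schlemm's canal (SC) lumen with physical calibration
(lateral μm/px, axial μm/px, B-scan spacing). Processing per B-scan:

1. **Component extraction** (`segment.extract_components`). Foreground is
   labeled with 8-connectivity (diagonal contact joins thin lumen fragments,
   matching the default of the MATLAB-style region analysis this convention
   descends from). For each component the pixel count, area, centroid and
   central second moments are computed over *pixel centers in μm
   coordinates*. Working in physical units before any eigen-decomposition
   matters because anterior-segment OCT grids are ~5× anisotropic
   (defaults 7 μm lateral, 1.3 μm axial); a pixel-space ellipse would have
   distorted axes.

2. **SC part selection** (`segment.select_sc_components`). The anchor is the
   largest-area component whose centroid lies in the region of interest
   (whole frame if none); all in-roi components with area ≥ 20% of the
   anchor's are kept. The threshold is inclusive ("at least 20%"). The roi
   is a declarative rectangle standing in for the anatomical criterion
   "immediately lateral to the iridocorneal angle", which is otherwise a
   manual judgement; with synthetic data it defaults to the full frame. The
   position filter defines the anchor set *before* the 20% rule is applied.

3. **Ellipse morphometrics** (`morpho.fit_ellipse`). Each selected part gets
   the equal-second-moment ellipse, normalized moments plus the per-axis
   +(pixel size)²/12 finite-pixel correction. The correction keeps a single
   pixel from degenerating to zero axes (it returns 2s/√3 per axis) and is
   applied per axis in μm. Cross-section width = Σ major axes, height =
   area-weighted mean of minor axes, area = Σ component areas. The
   area-weighted height always lies between the extreme minors (asserted in
   tests).

4. **Series aggregation** (`morpho.series_morphometry`). The analysis window
   is the first ⌊1500 μm / spacing⌋ B-scans (anchored at the first analyzed
   section; no recentering rule is defined, so none is applied). Volume is
   the rectangle-rule integral Σ area × spacing with empty sections counted
   as zero area — volume is an integral, absence contributes nothing —
   while mean width/height/area average over non-empty sections only,
   because they are properties of existing lumen. This exclusion choice is
   a documented sensitivity knob: callers who want empty sections in the
   means can filter the per-section table themselves.

Auxiliary quantifications follow the same conventions: peripheral cornea
thickness is the mean axial separation of paired anterior/posterior
boundaries averaged over three cross-sections per eye, and flat-mount SC
area per high-power field is the mean calibrated foreground area over 4–8
fields.

## IOP-response analysis

One measurement row per (eye, group, ΔIOP, repeat); width/height/volume are
computed per repeat, not pooled, so a 5-level × 3-repeat protocol contributes
15 points per eye to each fit. Two normalization schemes:

* **relative volume** — divide by the mean *control-group* volume at
  baseline (Δ0), a joint control-anchored scale for both groups;
* **per-eye normalization** — divide each eye's values by that eye's mean
  at the Δ−10 mmHg reference, so each eye's series averages exactly 1 there
  and absolute canal size cancels.

Slopes come from OLS of value on ΔIOP pooling all eyes and repeats of a
group (fixed-effects pooling; per-eye random effects are deliberately out of
scope). The 95% CI uses the t distribution with n−2 df; when the residual
sum of squares is numerically zero (≤ 1e−12 relative) the data are exactly
collinear and the CI width is set to 0. The slope difference between groups
is the two-sided t-test on the interaction coefficient of the pooled
`value ~ ΔIOP × group` model (ANCOVA) — the standard construction for a
single slope-difference p-value; the interaction estimate equals the
difference of the per-group OLS slopes identically. On noiseless pooled data
the t statistic is undefined and the case is resolved as "no difference"
(p = 1) when the interaction estimate is also zero. Per-level group
contrasts use the two-factor (group × level) cell-means model: the pooled
within-cell variance is the error term (replicate values are the error
unit), each level's group difference is t-tested against it, and p-values
are Šídák-adjusted, p_adj = 1 − (1 − p)^m over the m tested levels. Levels
missing one group are skipped with a warning. OLS fitting is delegated to
statsmodels.

## The phantom generator

`phantom` emulates the study conditions this pipeline is built for: a
1.5 mm segmented canal length imaged at 5 IOP offsets (−10, −5, 0, +5,
+10 mmHg) with 3 repeats per level and 6 eyes per group, on a 7 × 1.3 μm
grid. The lumen is an ellipse with full axes *w* (lateral) × *h* (axial);
deformation is linear: h(Δ) = h0 + s_h·Δ, and area A(Δ) = π/4·w0·h(Δ)·
(1 + f·Δ) with f = `slope_area_frac_per_mmHg` (width stays fixed when
f = 0). Linear deformation is the simplest model whose recovery validates a
linear-fit analysis; because the offsets are symmetric about 0, the
quadratic cross-term s_h·f·Δ² is orthogonal to the linear trend and the
population OLS slope equals V0·(s_h/h0 + f) exactly, which is the truth the
recovery benchmark uses.

Rasterization is pixel-center-inside, which is unbiased to first order and
matches the moment conventions downstream. Noise has two components chosen
to mimic manual segmentation of in-vivo data: (i) smooth radial boundary
jitter — a 6-harmonic random Fourier series of unit SD scaled to
`noise_px` (default 0.5) geometric-mean pixels, applied independently per
B-scan; mean-zero radial jitter preserves expected area to first order;
(ii) a per-acquisition scale factor of SD `repeat_noise_frac` (default
0.05, i.e. 5% of baseline) on the lumen height, which propagates
multiplicatively to height, area and volume — this is the repeat-to-repeat
variability that drives the statistical benchmarks. Between-eye size
variation is a per-eye factor on the baseline width (SD 0.08). Septation
replaces the ellipse by two side-by-side sub-ellipses with widths r·w and
(1−r)·w, the same height, and a 3-pixel gap: analytic area, summed width
and area-weighted height are conserved *exactly*, so ground truth needs no
septation corrections (the rasterized pixel counts agree within
discretization, ~1–2% at the default grid).

Group presets: the *control* phantom (h0 = 27 μm, s_h = −0.85 μm/mmHg,
w0 = 200 μm, f chosen so the relative-volume slope is −0.044/mmHg) is a
compliant canal; the *mutant* phantom (h0 = 19 μm, s_h = −0.34 μm/mmHg,
w0 = 170 μm, relative-volume slope −0.022/mmHg on the control baseline,
baseline volume ≈ 0.6× control) is a smaller, hypo-responsive canal. These
magnitudes are the physiological scale reported for control and
stiff-outflow mutant mouse eyes. Ground truth is always computed
analytically from the `PhantomSpec`, never from the raster, and all randomness
derives from one seed sequence, so a seed reproduces an experiment
byte-identically.

### What the phantom does and does not emulate

It emulates lumen geometry, its linear IOP response, septation, boundary
digitization, acquisition-scale noise and between-eye size spread. It does
*not* render OCT speckle or angiographic contrast, does not simulate
segmentation bias (systematic over/under-tracing), curvature of the canal,
within-stack drift, or non-linear collapse at extreme pressures. Passing
recovery tests therefore demonstrates that the measurement and inference
chain is unbiased and correctly calibrated for data matching its stated
conventions — not that manual segmentations of real B-scans are accurate.

## Numerical choices and benchmark sizes

* Default n_bscans is 50 (30 μm spacing over 1.5 mm); the 200-experiment
  recovery benchmark uses 25 B-scans per stack (60 μm spacing), a size at
  which raster bias is already far below the 5% acquisition noise.
* The recovery benchmark fits raw volume against ΔIOP (one eye per
  experiment) and checks 95% CI coverage of the analytic slope and the mean
  absolute slope error; the power benchmark simulates relative-volume
  measurements directly (1 + slope·Δ + Gaussian noise, SD 0.05) for
  6 eyes × 5 levels × 3 repeats per group.
* Zero-variance tolerances are relative (1e−12 of Σy²+1); selection ties at
  exactly the 20% threshold are included; single-pixel components are never
  degenerate.
* Masks are written as 8-bit 0/255 multi-page TIFF with a JSON calibration
  sidecar; any nonzero pixel reads back as foreground.

## Known limitations

No mixed-effects modeling of the eye/animal hierarchy (slopes pool repeats
and eyes within group); the per-eye-normalized schemes divide by a noisy
reference mean, which slightly correlates points within an eye and is the
reason the recovery benchmark uses raw volume for its coverage claim; the
roi is rectangular and static per stack; and the phantom's fixed-width
default reflects that only height/volume responses are characterized in
vivo — whether SC width itself responds to IOP is left as a configurable
assumption (`slope_area_frac_per_mmHg`), not a claim.
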