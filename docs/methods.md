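# Methods

## Scope and model

`cortifilo` quantifies the spatial distribution of a fluorescently
tagged protein in single vegetative amoebae: cortical enrichment,
cortical asymmetry, filopodium counts, pixel-wise colocalization of two
channels, and intensity profiles along lines. All measurements run on
2-D maximum-intensity projections of short confocal z-stacks; no 3-D
optics (point-spread function, optical sectioning) is modelled, because
the measurements themselves are defined on projections.

The geometric model of a cell is:

* a **body** bounded by a smooth closed outline — analytically, a circle
  of radius `cell_radius_um` perturbed by a low-order (orders 2–5)
  cosine series with relative amplitude `boundary_roughness`, which
  captures the smooth-but-non-circular outline of an amoeba while
  keeping area and annulus analytically computable at roughness 0;
* a **nucleus**, a darker disk strictly inside the body (the tagged
  proteins are cytosolic/cortical and excluded from the nucleus), which
  must be excluded from the cytoplasm reference region;
* a **cortical band**, the layer of the body within `band_width_um`
  (default 0.8 µm) of the boundary, where cortex-associated protein
  accumulates;
* optional **filopodia**, thin (~0.25 µm) protrusions extending a few µm
  beyond the boundary, with a brighter punctum at the tip where the
  motor accumulates.

## The two headline statistics

**Cortex:cytoplasm ratio.** Mean intensity over the band divided by
mean intensity over the cytoplasm (body minus band minus nucleus).
Ratios ≈ 1 mean no cortical pool; a 20 % enriched band gives 1.2. The
ratio is invariant to a global intensity gain, so it can be compared
across cells expressing at different levels.

**Cortical SD (asymmetry).** Band pixels are binned by angular position
about the body centroid (default 360 bins of 1°); the statistic is the
standard deviation across bin means. Binning decouples the statistic
from band thickness and pixel count; the raw-pixel SD is available as a
config mode (`over="pixels"`) since either reduction is defensible. For
a band modulated as `M·(1 + A·cos(φ − θ₀))` the statistic converges to
`M·A/√2` (SD of a cosine), which the tests verify at 3 %. By default
the SD is reported in raw intensity units — it then scales with gain —
with a normalized mode (÷ cytoplasm mean) for cross-cell comparisons;
both behaviours are asserted in tests. Bins left empty by strongly
concave outlines are excluded and the cell flagged when more than 25 %
of bins are empty.

The angular convention, used everywhere (polarity rendering, binning,
ray casting), is φ = `atan2(Δrow, Δcol)` about the centroid — one fixed
convention, so rotation equivariance is testable.

## Segmentation and the cortical partition

* **Threshold:** Otsu on the projected image, with a fixed-threshold
  override. Otsu is parameter-free and scale-invariant; because a dark
  nucleus class below the background can drag the bimodal split into
  the background, the threshold is re-estimated on the above-threshold
  pixels whenever the resulting foreground covers more than half the
  image (at most 3 iterations). Segmentation is invariant to a global
  intensity gain (asserted in tests).
* **Protrusion removal:** a morphological opening of radius
  `body_open_um` (default 0.5 µm) strips structures thinner than ~1 µm
  — i.e. filopodia — from the body mask while preserving the body.
* **Nucleus:** internal holes of the thresholded component and dark
  interior regions below `nucleus_fraction` (default 0.5) of the
  in-cell median, merged, kept if larger than `nucleus_min_area_um2`.
  This is a photometric definition (the nucleus is "dark"), not a
  morphological one.
* **Exclusions:** cells touching the image border (their partition is
  truncated) and cells whose mean intensity is below
  `background mean + 3×SD` (untransfected cells) are excluded; both are
  recorded as flags.
* **Cortical partition:** the band is every filled-body pixel whose
  exact Euclidean distance to the nearest outside-body pixel is within
  the band width; the transform runs on the *filled* body so the
  nucleus creates no internal boundary, and the threshold is applied in
  µm without rounding (0.8 µm is only 3.77 px at 0.212 µm pixels, so
  integer erosion would bias the band). One sub-pixel subtlety: the
  distance transform measures to outside pixel *centers*, which lie
  beyond the geometric boundary by ½ px for an axis-aligned edge and
  ~¼ px once averaged over edge orientations. The band threshold is
  therefore widened by `BAND_EDGE_OFFSET_PX = 0.25` px, which makes the
  measured band area of an ideal disk match the analytic annulus
  `π(R² − (R − w)²)` to within a few percent; the synthetic renderer
  uses the identical definition so photometric ground truth is exact.
  Cells thinner than twice the band (empty cytoplasm) are flagged
  `unmeasurable` rather than yielding a meaningless ratio.

## Radial tip search

Rays are cast from the centroid every `dtheta_deg` (default 1°); if the
centroid falls outside a pathologically concave body the interior point
farthest from the boundary is used instead. Along each ray, intensity
is sampled by bilinear interpolation at 0.5 px steps from the body
boundary out to `max_length_um` (default 15 µm), lightly smoothed
(Gaussian, σ = 1 sample) to suppress single-sample noise peaks, and the
**outermost** local maximum above `background median + k·robust SD`
(default k = 4) becomes a tip candidate — outermost because the marker
is tip-enriched. Background statistics come from pixels more than 3 µm
outside every body, using median and 1.4826×MAD so that filopodium
pixels (which lie outside the bodies) cannot inflate the noise floor.
Tip positions are refined by a quadratic fit around the 1-D peak
(sub-pixel matters at 0.212 µm pixels).

Candidates are merged by greedy non-maximum suppression in descending
peak intensity: a candidate is dropped when it lies within
`merge_angle_deg` (default 5°) **or** `merge_radius_um` (default 1 µm)
of an already-accepted tip. The OR-semantics makes two protrusions 10°
apart distinct at a 5° merge angle but merged at 15°, and
greedy-by-intensity guarantees that raising the detection threshold can
never *increase* the tip count (suppression decisions for a candidate
depend only on brighter candidates, which a threshold increase cannot
remove before it). Tips are registered to the cell with the nearest
boundary; ties go to the smaller cell id, and tips farther than
`max_length_um` from every boundary are dropped.

Count summaries follow the reporting convention: the percentage is over
all analyzed cells, the mean ± SEM only over cells with at least one
filopodium, reported as 0 with n_positive = 0 when no cell has any.

## Colocalization and profile averaging

Cytofluorograms pair all in-mask pixels of two aligned channels (the
union of cell masks of a field by default, a single cell optionally)
and report Pearson *r*; masks under 100 pixels are flagged unstable,
constant channels are an error. No Manders coefficients or Costes
randomization — Pearson *r* is the readout.

Linescans use bilinear interpolation at pixel-spaced samples with
optional perpendicular averaging (`width_px`); axis-aligned unit-width
lines reproduce raster values exactly. The longest-axis profile runs
through the centroid along the principal axis of the body mask
(second-moment orientation), clipped to the mask extent plus a margin;
near-circular cells (axis ratio < 1.05) keep a defined axis but are
flagged. Profiles are normalized to [0, 1] by min-max scaling
(idempotent, order-preserving; constant profiles are an error).

Profile averaging fits a **restricted cubic spline** — natural cubic
basis in the Harrell form, linear beyond the boundary knots — by least
squares to the pooled (position, intensity) points of all profiles,
with knots at the standard quantiles of the pooled positions
({5, 27.5, 50, 72.5, 95} % for the default 5 knots; count and placement
are config-exposed since no canonical rule exists). The SD band is the
pointwise standard deviation across the per-profile values interpolated
to the common grid, and SEM = SD/√n — the bands describe profile-to-
profile spread, not spline residuals.

## Statistics

Tests always run on the full cell-level datasets; per-experiment means
are computed only for display of replicate variability (superplot
convention). The ROUT outlier rule is applied to the cortex:cytoplasm
ratio only, before summarising.

**ROUT, constant-model reduction.** The published ROUT procedure is
defined for robust curve fits; for a univariate metric the applicable
special case is a constant model: location = median, scale = RSDR (the
68.27th percentile of absolute residuals, multiplied by the n/(n−1)
small-sample correction), per-point two-sided t p-values at n−1 degrees
of freedom, and a Benjamini–Hochberg step-up at the user's maximum FDR
Q (default 0.001, i.e. "definite outliers" at 0.1 %). Samples smaller
than 10 are passed through unfiltered with a warning; identical values
flag nothing. The commercial implementation's exact small-sample
constants are unpublished, so validation is tolerance-based: on clean
normal data the flagged fraction stays below 0.5 % on average, and a
+50σ contaminant is caught in ≥99 % of replicates.

**ANOVA and t-tests.** Classical one-way ANOVA with Tukey HSD over all
pairs (statsmodels) or Dunnett against a named control (scipy).
Validity anchors: F = t² for two groups to 1e-10, a from-scratch
sum-of-squares fixture to 1e-10, agreement with a permutation oracle,
and uniform null p-values. Significance stars use the conventional
cutpoints 0.05 / 0.01 / 0.001 / 0.0001 (config-exposed). The t-test is
pooled-variance by default with a Welch switch.

## Synthetic scenes: what they emulate, and what they do not

The generator renders: background-level field, in-body cytoplasm at
`cytoplasm_level`, a nucleus at zero signal, a cortical band at
`cytoplasm_level × E × (1 + A·cos(φ − θ₀))` (enrichment `E`, polarity
amplitude `A`), filopodia as thin rays with Gaussian cross-section and
a `tip_gain`-brighter Gaussian punctum at the end (rendered outside the
body mask only), and per-slice noise
`poisson_scale · Poisson(I/poisson_scale) + N(0, gaussian_sd²)`, so the
per-pixel variance is `poisson_scale·mean + gaussian_sd²` (verified to
10 %). z-slices share the ideal image and differ only in noise, because
analysis runs on maximum projections. Intensities are clipped at zero
and kept floating point; 16-bit quantization is optional at the I/O
boundary. Everything is reproducible: a seed fully determines the
scene, and fields use hierarchical seed sequences so results are
independent of execution order.

Default conditions (fixed once, used by tests and the reproduction
script): 0.212 µm pixels, 5 z-slices, cell radius 8 µm, roughness 0.06,
nucleus radius 2 µm offset 1 µm, cytoplasm 100 a.u. over background
10 a.u., Poisson scale 1.0 with Gaussian SD 3 a.u., band width 0.8 µm,
filopodium length 3 µm, width 0.25 µm, tip gain 3. Camera gain and
offset for the original instrument are not published, so the noise
levels are plausible rather than calibrated — which is why validation
relies on relative intensity claims (ratios, correlations, recovery of
generator parameters), never absolute intensities.

Two-channel scenes build channel B inside the cell mask as
`ρ·zA + √(1−ρ²)·zN` from the standardized channel-A field and an
independent standard-normal field, rescaled to channel-A levels, so the
in-mask correlation equals ρ by construction *per slice*. Correlation
studies therefore use single-slice scenes: a maximum projection over
independently re-noised slices selects large shared fluctuations and
biases the projected correlation upward at intermediate ρ.

What the generator does **not** emulate: point-spread-function blur,
photobleaching, stage drift, motility (no time-lapse), out-of-focus
light, overlapping or touching cells, irregular nuclear shapes, or
autofluorescence. Passing tests therefore demonstrate that the
*measurement operators* are correct and unbiased on images whose ground
truth is known exactly — not that segmentation is robust to every real-
world artifact. On real data the data-relative threshold, the border /
expression exclusions and the QC flags carry that burden, and the
config exposes every relevant constant.

## Numerical and design notes

* Image coordinates are row-major, origin at the top-left pixel center;
  all µm↔px conversions go through `pixel_size_um` with no implicit
  rounding. Pixel-size precedence on read: file metadata > caller
  override > error (strict mode) or 0.212 µm with a warning (lenient).
* The uniform-null and control-recovery studies
  (`cortifilo.studies.ratio_recovery_study`) use 30 cells each; the
  filopodia study uses 200 cells with counts drawn 0–6, lengths
  2.5–4 µm and ≥20° angular separation — sizes chosen so each study
  completes in seconds to minutes on one CPU while the sampling error
  of the reported means stays well inside the validation tolerances.
* Degenerate inputs are loud, not silent: empty cytoplasm flags the
  cell, constant profiles and channels raise, placement failure in
  multi-cell fields raises rather than overlapping bodies, zero-length
  linescans raise, and conditions with zero cells are omitted from
  summary tables with a warning.
* Known limitations: touching cells are not split (fields are generated
  non-overlapping; real touching cells should be flagged upstream);
  the asymmetry parameterization is angular about the centroid, which
  under-resolves strongly concave outlines (arc-length parameterization
  is a possible extension); filopodium lengths are exported but not
  summarised.
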