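# Methods

## Scene model and synthetic data

The generator emulates osmium-stained cortical EM cross-sections at a default
sampling of 12 nm/pixel. Each myelinated axon is an elliptical lumen
(semi-axes `a_in ≥ b_in`, orientation uniform on [0, π)) wrapped by a myelin
ring of uniform width `t` along the boundary normal, i.e. the outer boundary
is the offset curve of the inner ellipse. The ring width is derived from the
drawn g-ratio through the mean inner radius `r_eff = (a_in + b_in)/2` as
`t = r_eff (1 − g)/g`; for circular axons this makes `g = r_in/(r_in + t)`
exact, which the tests exploit as a closed-form oracle.

Default distributions (per scene):

| parameter | default | rationale |
|---|---|---|
| g-ratio | truncated normal, mean 0.70, sd 0.05, bounds [0.40, 0.95] | healthy white matter centers near 0.7; bounds span the biologically meaningful range (>0.8 = acute demyelination) without degenerate rings |
| lumen diameter (short axis) | truncated normal, mean 1000 nm, sd 200 nm, bounds [400, 1600] nm | realistic caliber range for cortical myelinated axons; keeps the minor semi-axis ≥ 3 px at 12 nm/px |
| aspect ratio `a_in/b_in` | uniform [1.0, 1.3] | near-transverse sections; mild obliquity only |
| intensities | myelin 60, lumen 160, background 180 (8-bit) | dark myelin on a lighter background, as in osmium staining |
| noise | additive Gaussian, sd 8, clipped to [0, 255] | moderate sensor noise; leaves the myelin/background modes separable |
| scene | 1536 × 1536 px, 25 axons, layer-1 band 384 px | the layer-1 band is the top quarter so layers 2/3 span exactly three times its depth |

Placement is rejection sampling on bounding circles of the outer boundaries
with 2 px clearance and a 1000-retry budget per axon; failure raises a
"density infeasible" error rather than silently truncating the scene.
Rendering classifies pixels on a 5× supersampled grid (the ring is resolved
with a Euclidean distance transform of the fine inner region), which keeps
boundary localization error near 0.1 px; the noiseless binary myelin raster
is kept as the truth mask. All outputs are pure functions of the spec and its
seed; cohort images derive per-image seeds from a master seed.

What the generator does **not** emulate: nuclei, mitochondria, unmyelinated
axons, paranodal thickness variation, touching or fused sheaths, 3-D section
obliquity beyond in-plane ellipticity, and structured segmentation errors of
a learned segmenter (only additive intensity noise). Passing tests therefore
demonstrate correctness of the measurement geometry and statistics under
clean ring topology, not robustness to the full variability of real tissue.

## Segmentation and curation

The reference segmenter thresholds the dark phase with Otsu's method (or a
fixed threshold). In Otsu mode the split must separate two real intensity
populations: the class means must differ by ≥ 2.5 pooled within-class
standard deviations, otherwise the image is declared to have no bimodal
intensity structure (constant images and background-only noise both fail
this). Candidate objects smaller than `min_object_px` (default 64) are
removed. External masks (e.g. DCNN output) are ingested from TIFF, validated
against the image shape, and binarized at 50% of their maximum; rasters with
more than two distinct values are rejected.

Curation into measurable sheaths uses 8-connectivity for foreground and
4-connectivity for holes (the standard complementary pairing). A component is
accepted only with exactly one hole and no border contact; multi-hole (fused)
components are rejected rather than split, and every rejection is logged with
its reason. These curation rules are this package's own definition of a
countable sheath and are reported as such.

## Morphometry

Contours are traced at the 0.5 level of the binary rasters
(`skimage.find_contours`), placing the boundary on the half-pixel midline
between foreground and background pixel centers. The inner-boundary ellipse
is fitted by the direct algebraic least-squares method (ellipse-constrained
conic fit via the stable block decomposition), with coordinate centering for
conditioning; parameters are canonicalized to `a ≥ b` and orientation in
[0, π), and the rms Sampson distance is reported as the residual. Fewer than
six points, or a degenerate/collinear set, is an error.

Thickness rays start at angle 0 measured from the image row axis and advance
in equal steps; with the default 10 positions, ray `i` pairs with ray `i+5`
to form diameters. The outer crossing is the nearest one beyond the inner
crossing; a ray that misses a contour marks the sheath as a broken ring,
which excludes it from statistics (logged, never imputed). The default
g-ratio is the mean of the five paired diameter ratios; a sensitivity
alternative (`g_mode="equivalent_diameter"`) uses the square root of the
inner/outer contour area ratio instead. Both are exact for circular rings.
The demyelination flag is strict: `g > 0.8` flags, `g = 0.8` does not.

Numerical behaviour worth knowing:

* Ray-based thickness measures along the ray, not along the boundary normal,
  so it overestimates the normal ring width by O(eccentricity²) — about 0.6%
  on average at aspect ratio 1.2, 1.2% at 1.3. Averaging 10 equally spaced
  rays cancels the low-order angular harmonics.
* Contour quantization contributes ~±0.25 px per crossing; measurements on
  rings thinner than ~10 px become noticeably noisier.
* Rotating a mask by 90° changes g by far less than 1%; the thickness mean
  moves by a few tenths of a percent for well-resolved sheaths but can
  approach 1% for thin or highly elliptical rings, because ray angles are
  anchored to the image axes by convention.

## Layering

Layer bands derive from one parameter, the layer-1 depth `d1` in pixels:
L1 = [0, d1), L2/3 = [d1, 4·d1), consistent with measured cortical
proportions in which layers 2+3 combined are three times deeper than layer 1.
Depth is the row coordinate of the fitted inner-ellipse center — a single
point, so boundary-straddling sheaths get an unambiguous label. Depths at or
beyond `4·d1` are unassigned and excluded from statistics. `d1` is a
per-image configuration value; no image-based laminar detection is attempted.

## Statistics

Per (metric × layer) cell: Shapiro–Wilk screen per group (scipy's Royston
implementation; validated against an independent R reference on a frozen
sample), then an unpaired t-test — Student's pooled-variance form by default,
Welch by option — two-sided at α = 0.05, reported as means ± SD with n. A
failed normality screen logs a warning but does not switch tests, matching a
validate-then-test workflow; no multiple-testing correction is applied across
the six comparisons and the report footer states this. The unit of analysis
defaults to the sheath (pooled across images); per-image means are available
by option, and reports always print n. Two groups that are constant and equal
yield t = 0, p = 1 rather than an error.

Statistical calibration (type-I error under null cohorts, power under a +0.1
g-ratio shift at 200 sheaths/group) is exercised through the compare stage on
per-sheath tables drawn from the generator's morphology marginals
(`sample_truth_metrics`, placement-free). Under identical group specs the two
groups are exchangeable regardless of the imaging stage, so this isolates the
calibration question while keeping the cohort sizes large; the imaging path
itself is validated separately by the end-to-end recovery runs (200 rendered
axons; mean absolute g-ratio error ~0.002, thickness and diameter relative
errors ~1% and ~0.1%).

## Problem sizes used in the shipped tests

Recovery and headline-quantity runs use 8 scenes × 25 axons (200 sheaths);
calibration uses 200 null cohorts × 200 sheaths/group and 100 shifted
replicates. These sizes put Monte-Carlo uncertainty comfortably below the
tolerances being checked while keeping the suite quick to run.

## Known limitations

* No instance separation of touching sheaths; fused rings are rejected, which
  under-samples dense neuropil.
* The g-ratio convention (mean of 5 diameter ratios) is one of several in
  use; the equivalent-diameter mode is provided for sensitivity analysis.
* Layer assignment trusts the configured `d1`; mis-specifying it shifts
  sheaths between bands.
* Sheath-level pooling treats sheaths as independent; with few animals or
  images per group this understates between-subject variance. Per-image
  aggregation is available, and n is always reported at every level.
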