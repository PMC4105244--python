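# Methods

This note describes the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Problem setting

Cereal grains (wheat-like, and elongated seeds such as *Brachypodium
distachyon*) are scattered on a flatbed scanner against a matte dark
background and scanned at a known resolution (typically 300 dpi) with no
colour adjustment. The pipeline must (i) segment every grain, including
touching ones, (ii) measure per-grain size in millimetres, (iii) report
per-grain colour either as raw scanner RGB or as device-independent
CIELAB after calibration against a 24-swatch colour-checker card, and
(iv) optionally locate each grain's longitudinal crease so colour can be
reported with or without the crease region.

## Segmentation

**Grayscale.** The working grayscale is the mean of the red and green
channels; these carry the strongest seed/background contrast on scanner
hardware, and blue is noisier for yellow-brown seeds.

**Preprocessing.** After Gaussian smoothing (σ = 1 px default), the image
is simplified by connected (attribute) morphological operators, which act
on whole flat components of the threshold decomposition and therefore
preserve contours — no new edges are created, a property the test suite
verifies against a brute-force component filter. The chain is:

1. width-attribute **closing** at 0.3 × minimum grain width — fills the
   dark crease so a grain thresholds as one solid object;
2. **elongation thinning** — removes bright scratches;
3. width-attribute **opening** at 0.7 × minimum grain width — removes
   thin debris;
4. length-attribute **opening** at 0.7 × minimum grain length — removes
   short, thick debris.

Attributes are computed from each component's central second moments with
a 1/12 px² pixel-variance correction: width = √(12·λ₂), length =
√(12·λ₁), elongation = √(λ₁/λ₂). Moment-based width/length (rather than
bounding-box dimensions) was a deliberate choice: a bounding box is not
rotation-invariant, and a thin crease in an obliquely lying grain spans a
large box in both dimensions, so a box-width closing never fills it. The
moment width equals the true width of a rectangle at any orientation.
The elongation threshold defaults to 12: scratches are tens of times
longer than wide, while even strongly elongated seeds stay below ≈ 8–9.

The operators run on a max-tree (bright structures, 8-connected) or on
the inverted image (dark structures, 4-connected), built by the standard
union-find construction with a stable intensity sort; construction and
the filtering passes are numba-compiled, which keeps 12-megapixel scans
in the seconds range on one core. The filtering rule is the direct one:
a failing component is lowered to its nearest surviving ancestor.

**Thresholding.** Scanner scenes are uniformly lit, so a single global
threshold suffices; the difficulty is only choosing it automatically. The
threshold is derived from a bivariate (grey level, gradient) histogram:
pixels with gradient magnitude above the median — object borders — are
excluded, and the between-class-variance-maximising split is computed on
the remaining low-gradient stratum. Two numerical details matter:

- when the variance curve is maximal over a flat plateau (an empty
  histogram gap between modes), the threshold is taken at the plateau's
  middle, not its lower edge, keeping anti-aliased rim pixels out of the
  foreground;
- if the resulting classes differ by fewer than 20 grey levels the scene
  is declared background-only (an empty scan is just noise; any split of
  it would be spurious). Legitimate scenes have contrast an order of
  magnitude above this.

**Splitting touching grains.** Seeds are the regional maxima of the
Gaussian-smoothed (σ = 2 px) Euclidean distance transform, and each
foreground pixel is assigned by watershed flooding of the negated
distance map, so cuts fall on the troughs between maxima and the union of
parts equals the thresholded mask exactly (asserted in tests). Raw
regional maxima are too fragile on digitised shapes: the distance ridge
of an elongated grain carries ~10⁻⁵ px ripples, and a symmetric grain
duplicates its exact maximum at two non-adjacent pixels. Both produce
phantom seeds. Seeds are therefore the regional maxima of the
h-reconstruction of the distance map, with minimum trough depth h = 10 %
of the minimum grain width (≥ 1 px): maxima separated by shallower
troughs merge into one connected plateau, while genuine necks between
touching grains are an order of magnitude deeper (empirically 5–15 px of
distance for grains overlapping by a couple of pixels, against
h ≈ 1–2.4 px).

**Area filter.** Fragments below 0.5 × minimum grain width × length (in
pixels) are removed and survivors relabelled consecutively from 1.
Raising the minimum grain size can only decrease the object count
(monotonicity, tested).

## Morphometry

- **Area**: exact pixel count × (25.4/dpi)² — no estimator ambiguity.
- **Perimeter**: Crofton four-direction estimate, which is far less
  biased by digitisation than boundary-pixel counting; absolute values
  may differ from other implementations by a few percent.
- **Length/width surrogates** ("majellipse"/"minellipse"): major and
  minor axes of the ellipse with the same normalised second central
  moments as the pixel set; robust to boundary bumps. Degenerate 1-px
  structures have the minor axis clamped to one pixel equivalent.
- Conversion assumes square pixels (scanners guarantee this) with
  25.4 mm/inch.

## Colour calibration

A 24-swatch colour-checker card scanned under the seed-scan settings
anchors device RGB to CIELAB. Swatch cells are segmented by thresholding
(walking the threshold from the Otsu split toward the background level
until 24 similar-sized cells appear — the darkest patch can sit below the
Otsu split), assigned to grid positions via the principal axes of their
centroid cloud (tolerant to ≈ 5° card rotation), and averaged over the
central 50 % of each cell. The map **Lab = RGB·Mᵀ + o** is fitted by
joint linear least squares over all three Lab channels; `residual_rms` is
the mean Euclidean ΔE over the training swatches. A single global affine
model is used deliberately — no polynomial terms — and per-grain Lab is
computed from the grain's mean RGB: an affine map commutes with
averaging, so this equals averaging per-pixel Lab under the model.

The packaged reference table is the published 24-patch CIELAB set
(D50, 2° observer); a user CSV can replace it. Absolute Lab output shifts
by a few units with the choice of reference illuminant — reported values
are in the reference table's illuminant. The fitted matrix and offset are
stored as float64 TIFFs (`*RGB2Labmat.tif`, `*RGB2Laboff.tif`) and
round-trip bit-exactly.

## Crease detection

Each grain is mean-filtered preferentially along its major axis (k = 9
samples, clipped to the grain) to suppress variation unrelated to the
crease, then resampled nearest-neighbour into an axis-aligned frame where
a dynamic-programming minimum-cost path runs column-by-column from one
end of the grain to the other, moving at most one row sideways per
column. Nearest-neighbour resampling keeps colour values unmodified so
masks transfer back to native coordinates exactly.

The path is confined to the grain interior (mask eroded by a 5×5
square): the anti-aliased rim is dark for reasons unrelated to the
crease and otherwise attracts the path, inflating false positives.

A crease is declared present when the interior mean intensity exceeds
the path mean by more than τ (default 15 grey levels) — the presence
criterion is this package's construct; τ is user-configurable. The crease
region is the dark valley below (interior mean − τ/2) contiguous with the
path, so its width follows the local valley rather than a fixed dilation.
Grains narrower than 3 px, or with no feasible end-to-end path, are
reported crease-free rather than erroring.

Colour is reported in three modes: whole seed (GS), whole seeds with no
detected crease (GSncd), and the non-crease area of seeds with a detected
crease (GSwc). Channel sums are accumulated as 64-bit integers, so the
whole-seed mean equals the area-weighted combination of the crease and
non-crease means exactly, bit for bit.

## Synthetic scenes

The generator renders ellipse-shaped grains (the measurement model is
elliptical) with per-grain dimensions drawn from clipped normals,
optional dark axial crease stripes, anti-aliased edges via 4×4
supersampled rasterisation, and additive Gaussian pixel noise; placement
uses a shuffled jittered grid sized to the largest grain, which makes
packing feasible by construction, with a configurable fraction of
deliberately touching pairs (~2 px overlap). All outputs are bit-
reproducible from (spec, seed).

Two presets mirror the target materials: wheat-like (mean length
6.71 mm, width 3.41 mm, area ≈ 18 mm²; scans of hundreds of seeds) and
an elongated-seed preset (mean length 8.71 mm, width 1.47 mm). Truth
labels mark pixels with ≥ ½ supersampled coverage, so a truth pixel
carries at least half the body/background contrast before noise; truth
areas match the analytic ellipse area within rasterisation tolerance.

What the generator does **not** model: scanner optics (shadows, flare,
chromatic aberration), real seed texture and curvature shading, dust, and
non-elliptical seed outlines. Passing benchmarks therefore demonstrate
the correctness and internal consistency of the algorithms under the
stated geometry and noise, not field performance on arbitrary real scans.

## Benchmark problem sizes

The packaged benchmarks (also run by `scripts/acceptance.py`) use:
20 segmentation scenes of 50–654 grains (touching fraction 0.15, crease
fraction 0.3); 40 noise-free ellipse grains for size accuracy, re-rendered
at 600 dpi for the scale-invariance check; 200 grains (100 creased at
40 grey levels depth, 100 crease-free at noise σ = 3) for crease
performance; and 10 scenes of 150 grains whose body colours differ by up
to ±30 grey levels — the scale on which wheat samples of different
pigmentation genotypes differ — for the colour-mode agreement
correlations. Scene sizes were chosen so sampling noise in per-scene
means is small relative to between-sample differences, as in multi-seed
scans of real material.

## Known limitations

- The bivariate-histogram threshold implements the documented principle
  (exclude high-gradient pixels, then a between-class-variance split);
  the original method's exact algorithm is not public, so absolute
  thresholds may differ.
- The perimeter estimator is a declared convention; cross-package
  absolute perimeter comparisons carry a few percent of estimator bias.
- Crease detection assumes one dominant dark axial valley; species with
  multiple grooves or heavily textured seeds will need a different τ or
  fail the presence test.
- Colour accuracy is bounded by the single-affine model (typical training
  ΔE of a few units on real scanners) and by the reference table's
  illuminant.
- Non-dark backgrounds and overlapping (stacked) seeds are out of scope.
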