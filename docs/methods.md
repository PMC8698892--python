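# Methods

## Problem setting

Screening mammograms digitized from film carry non-anatomical content:
scanner labels near a corner, thin white borders along an image edge, and
occasionally a bright straight line touching the breast contour.  These
artefacts share the intensity band of dense tissue and lesions, so they
must be removed before any downstream analysis; separately, lesions
embedded in dense tissue are low-contrast and benefit from local contrast
enhancement.  `mammoprep` implements the removal and enhancement chain as
composable, individually testable operations, with a synthetic phantom
generator standing in for a real image collection.

## Artefact removal

The chain is border masking → global threshold → morphological opening →
largest-component selection → bitwise-AND merge.

* **Border mask** (default thickness 5 px): the outermost frame is set to
  zero outright.  This is the deterministic equivalent of drawing a black
  rectangle along the frame and AND-ing it in; no anti-aliasing is
  involved, so the interior is bit-identical to the input.
* **Threshold** t = 127, maximum 255, with the equality case mapping
  *up* (`pixel >= t → 255`).  The convention matters for reproducibility
  and is asserted in the tests.
* **Opening** uses a rectangular 20×20 element.  Internally, erosion is a
  minimum filter and the subsequent dilation uses the mirrored window, so
  that the composition is a true opening — anti-extensive, idempotent,
  and equal to the union of all element translates contained in the
  foreground.  This matters for even-sized elements, where a naive
  erode-then-dilate with the same window origin is shifted by one pixel
  and is not idempotent.  Pixels outside the image count as background,
  which makes "every surviving vertical run is at least the element
  height" exact also at the frame; correlation-type filters (the Gabor
  stage) use edge-inclusive reflection padding instead, to avoid spurious
  edge responses.
* **Largest component**: 8-connectivity; area is the filled pixel count;
  the winner is hole-filled before merging so that dark structures inside
  the breast are not zeroed.  Empty masks pass through unchanged.

## Line removal

Brightness segmentation converts the (gray, replicated to RGB) image to
HSV — V = max(R,G,B), S and V scaled to [0,255], hue to the 8-bit
half-degree convention [0,180) — and keeps pixels with all channels in
[(0,0,200), (255,255,255)], i.e. V ≥ 200.  That mask contains the line
plus any other very bright content.  The real-valued Gabor kernel

    k(x,y) = exp(-(x'² + γ²y'²) / 2σ²) · cos(2π x'/λ + ψ)

with defaults 5×5, σ = 3, θ = π, λ = π/4, γ = 0.5, ψ = 20 rad acts as an
oriented band-pass detector: the short wavelength relative to the kernel
makes the response strongly positive on 1–3 px wide vertical bright
structures and negative inside wide bright regions, which suppresses the
breast-interior leak.  The correlation output is clipped to [0,255] and
re-binarized at 127 (the same convention as the global threshold).
The phase offset ψ = 20 is interpreted in radians (equivalent to
20 mod 2π ≈ 1.15); a degree interpretation is available as a
configuration flag.  A stated frequency-domain form of the filter is not
used; only the spatial kernel above is implemented.

Vertical opening with a 1×30 rectangle then keeps only components with
vertical runs of at least 30 px; a 5×5 dilation widens the detected line
by two pixels on each side; the inverted mask (255 − m) is AND-merged so
that exactly the dilated detected-line region is erased.  By
construction, pixels outside that region are never modified.

## Enhancement

* **Gamma correction**: o = 255·(m/255)^(1/g), g = 2.0, rounded half-up.
  The map is monotone with fixed points 0 and 255; g > 1 lifts mid-tones.
  (Implemented literally as the power-law with exponent 1/g, which
  brightens for g > 1.)
* **CLAHE**: the image is partitioned into an 8×8 tile grid
  (reflection-padded to a grid multiple when necessary).  Per tile the
  256-bin histogram is clipped at `C_L = max(1, int(N_CL · N_avg))` with
  `N_avg` the tile pixel count divided by the number of gray levels
  (N_CL = 1.0 by default, giving C_L = 3 for 28×28 tiles); the clipped
  excess is redistributed uniformly, leftovers round-robin from bin 0
  upward.  The equalization mapping is the scaled CDF, rounded half-up.
  Each output pixel blends the four surrounding tile mappings bilinearly
  (clamped at the frame), which removes artificial tile boundaries.  With
  one tile and no clipping, this degenerates exactly to global histogram
  equalization — the oracle used in the tests.  CLAHE is applied exactly
  twice; a third pass would over-amplify contrast and is deliberately not
  offered by the pipeline (the pass count is configurable downward for
  ablations).
* **Green-Fire-Blue LUT**: a 256×3 table built by per-channel linear
  interpolation through control points R: (0,0),(150,0),(235,255),(255,255);
  G: (0,0),(180,255),(255,255); B: (0,0),(100,255),(200,0),(240,0),(255,200).
  This yields the black → blue → green → yellow/white progression that
  separates background, dense tissue and lesion into distinct hue bands.
  An ImageJ `.lut` file (768 bytes: 256 R, 256 G, 256 B) or a 256-row CSV
  overrides the built-in table.

## Verification metrics

MSE, PSNR = 10·log10(255²/MSE) (identical images report +inf), RMSE
(optionally normalized by 255), and SSIM with an 11×11 Gaussian window,
σ = 1.5, stabilizers c1 = (0.01·255)², c2 = (0.03·255)².  The window size
is the standard choice; colour/gray pairs are reduced to luminance before
comparison.  All metrics are computed on the [0,255] scale.  A soft
plausibility note (not an assertion) logs images whose PSNR falls outside
the typical 30–50 dB band.

## Augmentation and splitting

Seven transforms — vertical, horizontal and combined flips, ±30°
rotations, and each rotation followed by a horizontal flip (rotate first,
then flip) — plus the original give exactly 8× the rows, preserving class
proportions.  Rotation is about the image center with bilinear
interpolation, zero fill, and an unchanged canvas, so ±30° clips the
corners; the central disc survives a rotation round-trip to within ±3
intensity levels on smooth content.

The split rule assigns per class `floor(0.20·n)` rows to test and
`floor(0.10·n) + 1` to validation, the remainder to training, after a
seeded shuffle.  The `+1` keeps the validation set slightly smaller than
the test set while the three partitions stay disjoint and exhaustive;
both fractions and the offset are configurable.  For the curated class
sizes (398, 417, 300, 327) augmented ×8 this yields 8074/1156/2306.

## Classification metrics

Per-class rates are one-vs-rest from a rows-=-actual confusion matrix;
multiclass summaries are unweighted macro averages (the aggregation
scheme is a package choice and is stated here because a single number for
a 4-class problem is otherwise ambiguous).  Cohen's kappa and the
multiclass Matthews correlation use their standard definitions; 0/0 rate
cases return 0 with a warning flag rather than NaN.  ROC AUC is computed
one-vs-rest by a threshold sweep over distinct scores with the trapezoid
rule, which equals the Mann–Whitney pair-counting statistic (ties count
one half) — the independent oracle in the tests.  MAE and RMSE are taken
over all (sample, class) probability terms.

## The phantom generator

Each phantom is fully determined by its spec (including the seed):

* **Breast**: a half-ellipse (horizontal semi-axis 0.50–0.60 of the
  width, vertical 0.38–0.45 of the height) with its flat side just
  inside the 5 px border band — a thin dark film margin separates the
  chest wall from the image edge, mirroring digitized film and keeping
  the specified border-masking stage from counting anatomy as loss.
* **Tissue**: base 150 plus smoothed Gaussian noise (σ = 8 px) scaled by
  the density parameter (default 0.7 — roughly the fraction of dense
  tissue reported for screening collections), clipped to [130, 195].
  The clip floor keeps the global threshold at 127 segmenting ≥ 99% of
  the breast; the ceiling keeps tissue below the 200 brightness bound of
  the line stage.
* **Lesion**: a Gaussian mass blob (radius 6–9 px, peak ≈ 28 above local
  tissue, capped at 199) or a cluster of 10–17 calcification speckles
  (radius 1–2 px, 13–21 above local tissue).  Lesions sit only modestly
  above the dense-tissue band: a mass or calcification embedded in dense
  tissue is low-contrast, which is precisely why the enhancement stage
  exists.  Lesion-to-surround contrast is measured as the mean intensity
  inside the lesion mask minus the mean over a 2–10 px ring of
  surrounding breast tissue (excluding the line neighbourhood).
* **Artefacts**: a solid 255 corner label (12–21 × 9–15 px, disconnected
  from the breast — small enough that the 20×20 opening removes it), a
  2–3 px white border line within the outer 4 px of one edge, and a 3 px
  wide vertical line at 225–245 intensity placed inside the breast at
  0.45–0.60 of the semi-axis, touching the contour band.  The lesion is
  then placed left of 0.24 of the semi-axis, at least ~23 px from the
  line column, beyond the combined Gabor and dilation reach.
* **Per-image seeds** in dataset generation are derived by feeding
  (dataset seed, row index) through a seed sequence and reducing below
  2³¹, giving distinct, reproducible images.
* **Noise injector**: zero-mean Gaussian noise with variance specified on
  the [0,1] intensity scale (the convention under which "0.1" is a heavy
  corruption), added per pixel, clipped to [0,255] and re-quantized.

What the phantoms do *not* emulate: photorealistic breast texture,
pectoral muscle, BI-RADS density categories, blank/corrupt scans, or
horizontal/oblique attached lines (the removal stage targets vertical
lines by design).  Passing the end-to-end suite therefore shows that the
pipeline recovers exactly the artefact classes it models, at the stated
intensity bands — not that it handles every failure mode of real scans.

## Problem sizes

The full-scale dataset run generates 1459 phantoms at 224×224, curates to
1442, writes 11536 augmented images and splits them — about a minute on
one CPU.  End-to-end recovery statistics use 100 phantoms carrying all
three artefact kinds; oracle-equivalence suites use 1000 random small
instances per primitive (24–32 px rasters), sizes chosen to keep the
whole suite fast while exercising every code path.

## Known limitations

* The attached line is removed only if bright (V ≥ 200) and vertical;
  the Gabor defaults are tuned to 1–3 px wide lines.
* CLAHE on images much smaller than the tile grid degenerates to
  near-global equalization.
* Table-based recoloring assumes 8-bit single-channel input; 16-bit
  rasters must be rescaled first.
* The double-CLAHE enhancement raises *local* lesion-to-surround
  contrast on average; on phantoms whose lesion is already high-contrast
  it can reduce the raw intensity difference (local equalization
  normalizes means by design).
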