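# Methods

This note documents the models, algorithms, and design choices behind
`plantarzone`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmark does and does not show.

## Problem setting

A plantar pressure map is a 2D grid of non-negative pressure magnitudes
recorded under the sole, aligned with the toes at the top and the heel at
the bottom. Dynamic (walking) recordings are reduced to a single per-pixel
peak-pressure image, so one sample is always one image. The pipeline
addresses two tasks:

1. **Anatomical zoning** — segmenting the map into four regions: hallux,
   metatarsal area 1 (met1), metatarsal areas 1–5 (met_all), and heel.
   met1 lies inside met_all by definition, so the four channels are
   independent binaries, not a partition.
2. **Landmark detection** — locating the interdigital space between toes 2
   and 3 (id23, height-referenced to the middle of the second toe), its
   shifted surrogate inside the metatarsal band, and the center of
   metatarsal area 1. These anchor an anatomical medial–lateral axis of the
   foot (id23 → heel center) and hallux-angle measurements.

## Coordinate and orientation conventions

Coordinates are 0-based and continuous: `x` is the column index
(rightward), `y` the row index (downward). Because toes are at the top, an
anatomically "higher" point has a smaller `y`. Pixel centers sit at integer
coordinates; polygon rasterization is pixel-center membership with an
inclusive boundary. Every resize records a `SpatialTransform`
(`x' = x·scale_x + pad_left`, `y' = y·scale_y + pad_top`) so points map
between raw, labeling, and model spaces exactly; forward-then-inverse
round-trips are exact to ~1e-9.

## Preprocessing

Two separate paths, never mixed:

* **Labeling path** (for human annotation): bilinear upsampling with a
  single isotropic scale `min(300/rows, 100/cols)` into a 300×100 box
  (fractional sizes floored), then symmetric zero-padding to 310×110; an
  odd padding pixel goes to the bottom/right so outputs are bit-stable.
  Maps are exported as PNGs under a jet-derived colormap whose zero bin is
  white, without axes or colorbars. Smoothing is implicit in the bilinear
  interpolation; an optional Gaussian blur exists but defaults to off.
* **Model path**: per-sample min–max normalization to [0, 1] followed by an
  anisotropic resize onto the square model grid — bilinear for images,
  nearest-neighbor for masks (masks stay binary). This resize does not
  preserve aspect ratio; the per-axis scales live in the transform.
  Masks are one-hot encoded in the fixed channel order
  (hallux, met1, met_all, heel).

Degenerate constant-pressure maps normalize to all zeros with a warning;
they cannot occur in the phantom but the behavior is pinned.

## Segmentation model

A U-Net with `depth` encoder stages. Every stage applies
(3×3 conv → batch norm → LeakyReLU) twice; the encoder halves resolution
with 2×2 max-pooling while doubling filters from `base_filters`; the
bottleneck block adds dropout (default rate 0.5); the decoder upsamples
2× (nearest), concatenates the matching encoder features, and convolves
again; a 1×1 convolution produces 4 sigmoid channels. Binary cross-entropy
is the loss because the channels overlap (met1 ⊂ met_all) — a softmax
partition would be wrong by construction.

Reference training schedule: Adam at 1e-4, batches of 16, 150 steps per
epoch, validation mean IoU across the four channels at threshold 0.5 as the
monitored metric, learning rate halved after 5 stale epochs, early stopping
after 5 (keeping the best weights). Paired augmentation applies one random
affine per draw — rotation ≤ ±20°, zoom ≤ ±10%, shift ≤ ±10%, shear ≤ ±5°,
fair-coin horizontal flip — identically to image (bilinear) and masks
(nearest, so they stay binary and nested), with nearest-edge fill.

The network runs on a compact numpy engine written for this package
(`plantarzone.nn`): im2col + GEMM convolutions, exact manual adjoints
(verified against finite differences in the test suite), float32 parameters,
and fully seeded randomness, so training runs are bit-reproducible.

## Key-point regression

Each landmark gets its own model with identical hyperparameters: the
trained U-Net is frozen and its bottleneck feature map (deepest encoder
output — the canonical reading of "latent features") feeds a head of
conv 3×3/128 → BN → dropout 0.2 → conv 3×3/64 → BN → global average
pooling → dense 128 → BN → a dense residual block (128→128 with additive
shortcut) → dense 2 (linear), trained with Huber loss (δ = 1.0,
configurable) on raw pixel coordinates, Adam at 1e-3, LR halved after 5
stale epochs, early stopping after 8 with best-weight restore, checkpointed
on validation Euclidean distance. Regression training uses no
augmentation. Because the U-Net is used inference-only, bottleneck features
are computed once and cached; the frozen-weights contract is checked
bit-exactly via parameter digests.

The met1 center is also derived directly from segmentation: threshold the
sigmoid outputs at 0.5 (inclusive) and take the per-axis median of the
foreground pixel coordinates — medians, not means, so irregular blobs and
stray pixels perturb the center little. The ensemble prediction is the
coordinate-wise mean of the segmentation-derived and regressed points.

## Landmark geometry

`shifted_interdigital` draws the line from id23 to the heel center (itself
a per-axis median center); a metatarsal-band pixel counts as "on the line"
when its center lies within 0.5 px perpendicular distance and its
projection falls inside the closed segment. Among those pixels the one
with minimal row index ("highest") is returned, ties broken toward id23
along the segment. The result carries the pixel's integer coordinates —
the construction is pixel-membership-based, not a sub-pixel line
intersection. If the half-pixel tube is empty (a very thin diagonal band
can slip between pixel centers), a dense-sampling fallback (≤ 0.5 px steps
rounded to pixels) is tried before raising a dedicated no-intersection
error so callers can fall back to id23. The tests verify the vectorized
selection against an independently coded brute-force enumeration.

## Evaluation protocol

Grouped 5-fold cross-validation: all samples of one subject (left/right
feet, static/dynamic repeats) share one partition role. Subjects are
assigned to sample-balanced test folds; within each fold the remaining
subjects are split so validation holds ≈ 1/8 of the non-test samples,
giving ≈ 70/10/20 overall. Metrics: Dice and IoU per region after
thresholding at 0.5 (both-empty pairs score 1.0, one-empty 0.0), Euclidean
distance in model-input pixels for the five key-point methods (met1 center
via segmentation / regression / ensemble, id23, shifted id23). Test values
are pooled across folds by default (a per-fold-median mode exists).
Summaries are the median with unscaled MAD and a percentile-bootstrap 95%
CI of the median from 1,000 seeded resamples. Samples whose thresholded
met1 channel is empty count as reported failures and leave the distance
summaries.

Inter-rater reliability uses the same metrics: per image, all rater pairs
are compared after rasterizing and resizing annotations to the model input
shape, pair values are averaged per image, and the per-image means are
summarized across images. Chance-corrected categorical agreement
(e.g. Fleiss' κ) is deliberately not used: with large background areas it
is dominated by class imbalance, while overlap metrics compare directly
with model evaluation.

## The phantom

The phantom generates feet as 2D Gaussian-mixture blob layouts on one of
two simulated sensor grids (device A 128×48, device B 96×40 — two devices
are simulated because multicenter data mixes hardware; the grids themselves
are stated assumptions, as real vendors do not publish a canonical pair).
Components: a heel ellipse at the bottom, five metatarsal-head lobes in a
band, a hallux blob top-medial, toes 2–5 as small blobs (toe 2 always
rendered so id23 is defined; toes 3–5 appear with per-toe probability,
emulating partially visible toes), and a midfoot component scaled by
`1 − arch_factor` (flat arches press with the midfoot; high arches leave a
gap). Left feet are exact mirrors of right feet from the same parameters.
Dynamic trials have 1.35× peak pressure and 0.85× lobe widths (sharper
contact). Additive Gaussian sensor noise is clipped at zero.

Ground-truth masks are level sets of the *noiseless, unblurred* component
fields, while the rendered image blurs each component by a region-specific
boundary blur. Two mechanisms set the segmentation difficulty ordering that
real data shows (heel easiest, met1 hardest):

* **Boundary blur** — heel 0 px (crispest), met band 1.8 px, hallux 0.8 px,
  met1 4.0 px (most diffuse): the first metatarsal head has no intensity
  boundary of its own in real pressure images.
* **Annotation-convention jitter** — the level defining the met1 truth mask
  is drawn per sample (0.33–0.55 of lobe peak; met band 0.28–0.33, with
  met1's lower bound equal to met_all's upper bound so met1 ⊆ met_all is
  guaranteed). The rendered image is unchanged, so this spread is
  irreducible — it emulates the documented disagreement between expert
  raters about met1's extent, and caps the achievable met1 Dice the way
  ambiguous anatomy caps it on real data.

Foot length (62–92% of grid rows), width (52–80% of columns, always less
than length), hallux size, arch, and peak pressure vary per subject; the
toe row is placed asymmetrically (the 2–3 interspace lies medial of the
foot axis), so landmark positions vary with side and foot size — the
variation a regressor must explain to beat a constant-location baseline,
as on real feet.

A cohort draws 2–4 samples per subject (left/right at minimum, repeat
trials for some), assigns devices evenly and conditions at the 53%/47%
static/dynamic mix. Simulated raters are produced by tracing the exact
pixel-boundary polygon of each truth mask (at zero noise this rasterizes
back to the mask bit-exactly), optionally simplifying and jittering the
vertices with zero-mean Gaussian noise, and jittering the id23 point.

**What the phantom does not emulate**: biomechanically realistic pressure
distributions (no finite-element modeling), temporal dynamics, shoes or
insoles, pathology-specific patterns (ulcers, severe deformity), sensor
calibration drift, or segmentation-relevant anatomy beyond the blob
template. Passing tests on the phantom demonstrate that the pipeline's
machinery is correct and that the models can learn zone geometry under
controlled ambiguity — not that the printed accuracy transfers to clinical
data.

## Scaled-down study conditions

The learning checks (and `scripts/acceptance.py`) run a deliberately
reduced configuration chosen once: 60 subjects (~150 samples), 128×128
model inputs, base 16 filters, depth 3, batch 8, one full pass over the
training split per epoch, Adam at 1e-3 (faster convergence at this scale;
the reference 1e-4 belongs to the full-size configuration), at most 10
epochs, no augmentation (the phantom cohort already varies geometry per
subject), evaluation on the first grouped fold, regression heads up to 60
epochs with the standard callbacks. Under these conditions the held-out
heel median Dice exceeds 0.85, the difficulty ordering
heel ≥ met_all ≥ hallux ≥ met1 emerges, and each landmark regressor beats
the constant-location baseline.

## Numerical choices and edge cases

* Threshold 0.5 is boundary-inclusive (≥).
* Median centers average the two middle values for even counts → sub-pixel
  centers.
* Odd padding remainders go to the bottom/right.
* Both-empty masks score 1.0 for Dice/IoU; one-empty 0.0.
* MAD carries no 1.4826 consistency factor.
* Degenerate phantom geometry (foot larger than the grid, empty or
  disconnected masks) raises explicit generation errors, never silent
  empties.
* The bootstrap CI is clamped to contain the sample median.
* All randomness flows through explicit numpy generators; backend-level
  nondeterminism does not exist in the numpy engine, so fixed seeds give
  bit-identical runs.

## Known limitations

* The numpy engine targets small models; the full-size reference
  configuration (256×256, base 32, depth 4, 150 steps/epoch) is expressible
  but slow without a GPU framework.
* GAP-based regression heads are largely translation-invariant, so
  landmark positions are recovered through size/side/shape cues rather
  than absolute position; large placement jitter would degrade them — as
  it would have in the original design.
* The phantom's annotation-convention jitter is a stylized model of rater
  disagreement (level-set jitter), not a cognitive model of annotators.
* `met_all` is annotated/generated as a single polygon region, mirroring
  the 4-label scheme; per-metatarsal subdivision is out of scope.
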