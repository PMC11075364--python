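# Methods

This note records the models, conventions and numerical choices behind
`seedxray`, and what its phantom-based tests do and do not demonstrate
about real radiographs.

## Coordinate and annotation conventions

Boxes are stored 0-based and half-open, `[x_min, x_max) × [y_min, y_max)`,
so `width = x_max − x_min` without off-by-one bookkeeping. On disk, PASCAL
VOC XML uses the common 1-based inclusive dialect (`xmin = x_min + 1`,
`xmax = x_max`); annotation tools differ on this point, and the 1-based
reading is the committed choice. YOLO lines carry a 0-based class index
plus center/size normalized to [0, 1], rendered with six decimals; reading
them back rounds to the nearest pixel, which reproduces integer boxes
exactly (well inside the 0.5 px round-trip bound). YOLO class indices come
from an explicit ordered class catalog persisted as `classes.txt`, never
from label sort order, so index assignments survive re-runs and partial
datasets.

Zero-area boxes are rejected on read rather than dropped: a degenerate box
is annotation corruption and should surface immediately.

## Segmentation

Seeds are bright objects on a near-black background (the sample holder has
negligible X-ray attenuation), so each crop is segmented independently
with a global Otsu threshold, keeping the largest 8-connected component
and filling interior holes. Hole filling is essential: empty seeds are
shells whose dark cavity still belongs to the seed. The operator is
deterministic and parameter-free; its known limitation is a box containing
a brighter fragment of a neighboring seed larger than the seed itself
(not possible under the grid layouts produced here, possible in dense real
acquisitions). Touching seeds are out of scope — real layouts separate
seeds on the holder, and watershed splitting is deliberately not
implemented.

## Balancing

`target_per_class = min_k(count_k) × r` with replication factor `r`
(default 2, matching the observed doubling of the minority class in the
motivating datasets: 1046 → 2092 and 1793 → 3586). Undersampling is
uniform without replacement; "oversampling" keeps each retained original
once and adds `r − 1` augmented copies, preserving original data rather
than resampling it. Each copy's parameters are drawn independently per
(class, replicate, seed-index), so re-running any class reproduces its
draws.

## Geometric augmentation

One affine transform per replicate, composed in the fixed order
flips → shear → rotation about the patch center → isotropic scale (the
order is a convention; it is recorded in each crop's history so any copy
can be re-derived). Patches are warped with bilinear interpolation, masks
with nearest-neighbor re-binarized at 0.5 — masks must stay binary. The
output canvas is sized from the exact (not floored) transformed
pixel-center extent, which makes flips and quarter-turn rotations map
pixel centers onto pixel centers exactly; arbitrary angles interpolate.
The result is re-cropped to the transformed mask's tight bounding box, and
identity parameters short-circuit to an exact copy. In rare cases
nearest-neighbor warping pinches off a one-pixel sliver; the largest
component is kept to maintain the single-component mask invariant.

Default ranges — rotation 0–180° (continuous, with both flips this spans
all orientations), scale 0.5–4, shear 0–0.2, flip probability 1/2 each,
contrast 0.8–1.25, brightness 0–1 — are the standard batch-augmentation
settings for this problem and sit in `AugmentationSpec` as defaults.

## Reassembly

Crops are pasted centered into disjoint grid cells
(`cols = ⌊(W − margin)/(cell_w + margin)⌋`, row-major, pages as needed) on
an all-zero canvas, copying only mask-foreground pixels. A grid rather
than random free placement guarantees non-overlap by construction, which
matches real single-layer acquisitions (~100 sugar-beet or ~50 faba-bean
seeds per plate) and makes the emitted boxes provably disjoint. Emitted
boxes are mask-tight, not cell-sized, because detectors are scored against
tight boxes. The default canvas is 2368×2340 px (the native detector
resolution this emulates); page capacity is fully configurable since
per-page seed counts vary by species and use. No attenuation model is
applied when compositing — pasting is a copy, so a decomposition of a
reassembled page recovers the pasted masks exactly, a property the tests
exploit end to end.

## Degradation model

Noise: `out = clip(round(in + n), 0, 255)` with `n ~ N(0, σ²)` i.i.d.,
σ drawn uniform on `[0, σ_max]`, `σ_max = 25` gray levels by default (the
level beyond which expert readers no longer recognize seed structure;
taken as given, not re-derived). Computation is floating point with a
single final quantization. At the black floor the clip biases the mean
upward and suppresses apparent noise — visible in mostly-black reassembled
pages, and the reason blind estimates are validated on smooth mid-gray
scenes.

Blind estimation uses Immerkær's 3×3 difference-of-Laplacians kernel:
`σ̂ = sqrt(π/2) · mean|I ∗ K| / 6`. The kernel annihilates constant and
linear structure; its response under pure i.i.d. noise is N(0, 36σ²), so
the mean absolute response is an unbiased σ estimator up to edge
contamination. On smooth scenes the injection–recovery error stays within
a few percent for σ ∈ [5, 25]; a wavelet-based estimator serves as an
independent cross-check in the tests.

Photometric: `out = clip(round(c·(in − 127.5) + 127.5 + b·255))`, pixel-wise.
Pivoting contrast at mid-gray decouples the two knobs; brightness is an
additive fraction of full scale applied after contrast, so large b drives
the image into the over-saturation failure mode seen at excessive tube
voltage. Note that "b = 1 saturates everything" holds only for c ≤ 1: with
c > 1 the darkest pixels map below 255 (e.g. pixel 0 at c = 1.25 → 223).
Degradation never touches geometry, so annotations are copied verbatim.

## Z-projection

`P(x, y) = (1/N) Σ Iₙ(x, y)` in floating point, quantized only at the final
min–max normalization to [0, 255] (a constant projection maps to zeros by
convention). Global min–max rather than percentile clipping is the
committed default — it is deterministic and parameter-free; percentile
normalization can be layered on by callers needing outlier robustness.
Averaging N slices of a shared scene with i.i.d. noise shrinks the noise
~√N-fold until the 8-bit clipping floor of the slices dominates.

## Evaluation

Matching is class-aware and greedy by descending confidence with IoU
threshold 0.5 by default (the community standard for box-level detection;
configurable). A detection can claim only an unmatched ground truth of the
same class, so a perfectly localized box with the wrong class counts as a
false positive of its predicted class and leaves a false negative behind —
cross-class confusions are double-penalized by design. Greedy matching is
within a factor two of the optimal assignment and agrees with it on almost
all small instances (verified against an exhaustive oracle). Macro
averages weigh all K classes equally; a class with a zero denominator
contributes 0 to the average (with a logged warning) rather than being
dropped, keeping K fixed. F1 is the harmonic mean of the macro P and R,
which therefore lies between them — but not necessarily between the
per-class F1 values, a common misconception.

## Phantom generator

Phantoms are parametric drawings, not texture-mapped real seeds: an
eccentric rotated ellipse (background 0, shell 120–180) with
class-defining internals — one germ blob (200–240) for monogerm, 2–3 for
multigerm, a dark cavity (≤ 40) behind an intact shell for empty, a dark
circular tunnel biting the boundary (radius 0.35–0.5 of the semi-minor
axis, a prominent insect exit hole) for damaged, a plain body for
undamaged — plus mild internal texture (σ = 4 gray levels). Intensities
were chosen once to be bimodal against the background (so Otsu is exact)
with internal contrast carrying the class signal; a rule on the generating
structure (tunnel → D, hollow → E, germ count) separates all classes
perfectly, guaranteeing the phantoms carry class information. An optional
coated style adds a fainter concentric halo outside the body to emulate
pelleted seeds.

What phantom-based passing tests show: the bookkeeping, sampling,
compositing, degradation and scoring machinery is exact and deterministic.
What they do not show: segmentation accuracy under real pericarp texture,
scatter, detector blur or overlapping seeds — phantoms have clean bimodal
histograms by construction.

## Determinism and problem sizes

Every random draw descends from one user seed through named substreams
(`SeedSequence([seed, crc32(stage), …])`), so stages are independently
reproducible and a pipeline re-run under the same configuration is
byte-identical (verified file-by-file, PNG encoding included). The run
report embeds a SHA-256 of the configuration (minus the output location,
which cannot influence the produced bytes).

Tests and the acceptance script run on desk-scale sizes chosen to exercise
every code path with comfortable statistical margins: phantom pages of
~10–60 seeds on 360–900 px canvases, 1000-box annotation round trips,
10⁶-pixel noise samples, 64-slice stacks. The balancing arithmetic uses the
real per-species class counts (8062 and 4701 seeds), which is exact at any
scale.

## Known limitations

* Compositing is copy-paste, not additive attenuation; overlapping-seed
  scenes are out of scope.
* The noise model is additive Gaussian only — no Poisson/quantum noise,
  detector MTF blur or scatter, and no signal-dependent coupling.
* Segmentation assumes one bright seed per box on a dark background.
* Blind noise estimates are biased low on mostly-black images (clipping)
  and high on edge-dense content.
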