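# Methods

## Pipeline model and assumptions

The quantification pipeline assumes a single already-stitched RGB leaf scan
per sample, at a magnification where one whitefly egg spans a bounding box of
roughly 22–88 px per side. Detection operates per tile because eggs are tiny
relative to the scan: tiling keeps them resolvable to any detector with a
bounded input size.

**Crop.** The scan is trimmed to an exact multiple of the 1400-px tile size.
The per-axis surplus `S = dims mod 1400` is split across the two opposite
sides of that axis; an odd surplus leaves the extra pixel on the
bottom/right (plain truncation convention, deterministic). Splitting per
axis across its two sides — rather than spreading one surplus over all four
sides — is the only reading that keeps the two axes independent.

**Tiles and padding.** Core regions partition the cropped image; each tile
is extracted with 100 px of padding on every side, so any egg whose centre
is within a core is fully visible in that tile (padding exceeds the maximum
egg extent of 88 px). Where a padded window leaves the cropped region the
extractor first uses real pixels from the surplus band of the original
image; only beyond the original image is the window filled synthetically,
by reflection by default. Reflection avoids fabricated dark borders, which
would create spurious contrast edges for any intensity-based detector.

**Duplicate handling.** Detections touching the padded tile frame are
discarded when padding is enabled: they are partial views of objects that a
neighbouring tile sees completely, and keeping them would leave thin
slivers whose IoU with the complete detection falls below the merge
threshold (a systematic overcount near tile boundaries). With padding
disabled nothing is discarded — that configuration deliberately exhibits the
double counting that padding plus merging exists to prevent, and the test
suite asserts the differential. Reflection phantoms in edge-tile padding
translate to coordinates outside the image and are dropped at the clip
stage; final boxes always lie inside the original image.

**Merge.** All pairs of translated boxes with IoU strictly above 0.5 are
linked, each connected group is replaced by its coordinate-wise envelope,
and this repeats until no pair exceeds the threshold. Merging whole groups
simultaneously (rather than one pair at a time) makes the fixed point
independent of input order; sequential pairwise merging is order-dependent
because an envelope can overlap boxes its constituents did not. A merged
box keeps the maximum constituent confidence: the strongest evidence for
the object survives, and confidence filtering stays monotone under merging.

**Filters.** The size filter rejects a box if *either* side is below
20 px or above 90 px (inclusive bounds kept); widths and heights come from
half-open pixel coordinates, so a 20-px side is exactly `x2 − x1 = 20`.
The confidence filter keeps boxes with confidence ≥ τ; keeping the boundary
makes a sweep over the grid {0.30, 0.35, …, 0.70} unambiguous. The stage
order is fixed: merge, then size, then confidence.

## Reference detector

The trained-model seat is a backend contract receiving the full 1600 × 1600
tile; any internal resizing is the backend's concern. The shipped reference
backend is a deterministic classical detector designed for the synthetic
scenes: it thresholds the red-minus-green channel difference at 10 (eggs
are the only rendered objects with R > G), labels connected components
(8-connectivity, minimum area 60 px²), and scores each component by

    confidence = gate(axis ratio) · contrast · (0.38 + 0.60 · fill_score)

where `fill_score = min(fill / (π/4), 1)` compares the component's fill
ratio to that of an ellipse in its bounding box, `gate` ramps from 0 at
axis ratio 0.08 to 1 at 0.25 (an egg's box ratio stays above ~0.25 at any
rotation, a thin strand's does not), and `contrast` is the component's mean
R−G difference relative to 25. The constants place a clean anti-aliased
ellipse above 0.8 even at the worst rotation (45°, where the fill ratio
drops to ~0.69), a sparse diagonal strand below 0.5, and out-of-focus blobs
lower than sharp ones — so the default 0.6 confidence threshold separates
them. These constants are part of the reference backend's definition, not
tuned per dataset.

## Evaluation conventions

Matching is greedy in descending IoU with ties broken by (truth index,
prediction index); one-to-one; a pair qualifies only for IoU strictly above
the threshold (0.5 by default). Greedy matching is the standard
reproducible choice; the suite checks it against an optimal-assignment
oracle on random instances and they agree on well over 95 % of them
(greedy can be suboptimal only in contrived overlap chains).

The printed formula for the image-level counting statistic,
`(TC − AC)/TC`, is a *signed relative error* — an algorithm 6 % short of
the truth scores 0.06. A "counting accuracy" near 1 for a good counter is
the complement `1 − |TC − AC|/TC`. Both are computed and exported under
distinct names (`counting_error`, `counting_accuracy`); the discrepancy is
documented rather than silently resolved.

r² is the squared Pearson correlation of predicted against true counts, the
convention for count scatter plots; an identity-line coefficient of
determination (which additionally penalizes bias) is available via
`r_squared(..., method="identity")`. Test-set aggregation is the unweighted
mean of per-image metrics. Images with zero true objects yield null
image metrics and are excluded from aggregates with a warning.

## Assay statistics

"Total whiteflies" in both assay formulas is the number *released* (five
per cage): several recorded cages recover fewer insects than released
(alive + dead < 5), so released is the only unambiguous denominator. Such
rows are kept and logged, not rejected. The two cages of a plant are pooled
before computing AS and OR, giving n = 3 plants per accession as the unit
of replication; testing per cage (n = 6) would treat pseudo-replicates as
independent. The transforms are the standard variance stabilizers —
arcsin(√p) for the survival proportion, √x for the count rate — and both
are monotone, so group orderings of means are preserved. The default test
is the two-sided equal-variance Student's t-test; Welch's variant is a flag,
and on the packaged table both agree at the 0.05 level for every planned
comparison. With n = 3 per group the equal-variance default follows the
common practice for small balanced designs. The packaged table's
transcription notes two low-confidence cells (documented in the data-module
docstring); neither affects any 0.05-level conclusion. At this pooling and
test choice the Moneymaker survival comparison lands at p ≈ 0.003 — clearly
significant at 0.05 and 0.01, though not below 0.001 under every possible
aggregation variant, which is why only 0.05-level conclusions are asserted.

## Synthetic scenes

The generator emulates what matters to the pipeline, not leaf photography:
a textured green background (low-frequency equal-channel undulation plus
per-pixel Gaussian noise, σ = 5), anti-aliased elliptical eggs whose colour
interpolates translucent green-olive to brown with maturity, and
distractors — pale 3-px trichome polylines, translucent honeydew discs
(equal-channel brightening), sub-20-px dark specks, >90-px elongated
smears, and circular out-of-focus patches (Gaussian blur, σ = 6). Egg
geometry follows the observed statistics: minor-axis bounding sides 22–40
px, axis ratio 0.40–0.55, longest side capped at 88 px, rotation uniform.
Default scenes are 2800 × 2800 px (a 2 × 2 tile grid — the smallest canvas
that exercises interior tile boundaries in both axes) with a 120-px minimum
centre spacing, comfortably above the maximum egg extent so neighbouring
eggs never merge.

Ground-truth boxes are the exact analytic bounds of each ellipse. All
randomness flows through one seeded generator per scene (rendering uses a
stream derived from the same seed), so a fixed seed reproduces a scene
bit-for-bit.

What passing on these scenes shows — and does not. Perfect recovery on
clean scenes demonstrates that the tiling/merging/filtering machinery loses
and invents nothing when the detector is adequate; it does *not* calibrate
performance on real leaves, where egg contrast, occlusion by trichomes,
honeydew sheen and focus vary far beyond the renderer. The noisy-scene
count agreement (r² across scenes of 10–200 eggs) exercises the failure
modes the renderer does model (splits under trichomes, misses under blur,
size-filtered salt) at realistic rates, not photometric realism.

## Numerical choices and degenerate inputs

* IoU is exact: closed-form inclusion–exclusion for two boxes, exact
  polygon union (shapely) for the k-ary form; a pixel-rasterization oracle
  checks it in the tests. The k-ary form is retained for completeness; the
  merge rule applies the pairwise form.
* Degenerate boxes (zero width/height, non-finite coordinates) are rejected
  at construction.
* Zero-prediction images: precision is null, recall 0, F1 0; with neither
  truths nor predictions all three are null with a warning.
* Sweep ties go to the smaller threshold.
* Scene placement is rejection sampling with a 4,000-attempt cap; an
  infeasible spacing constraint raises an error naming it.

## Problem sizes in the shipped checks

The acceptance script and end-to-end tests use 20 clean plus 20 noisy
2800 × 2800 scenes with 10–200 eggs each, 1,000-instance oracle checks for
IoU, merge and metric arithmetic, and a 10-image simulated sweep — sizes
chosen so the whole suite re-derives every headline number in well under a
minute on a single CPU while still crossing every tile-boundary and
distractor code path.

## Known limitations

* No trained detector ships with the package; real-image performance is
  entirely a property of the plugged-in backend.
* The merge envelope can chain across genuinely adjacent touching objects
  if a detector emits heavily overlapping boxes for distinct eggs; the
  spacing statistics of real clutches make this rare but not impossible.
* Whether the original deployment thresholds confidence before or after
  merging is not documented; this implementation follows the stated listing
  order (merge first). With max-confidence envelopes the final count can
  differ between the two orders only when a sub-threshold detection
  overlaps a super-threshold one.
* The assay module implements exactly the published design (two cages of
  five females, three plants); unbalanced designs are summarized correctly
  but the packaged comparison plan assumes the four reference accessions.
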