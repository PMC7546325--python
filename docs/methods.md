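# Methods

This note documents the models and procedures implemented in
`stomapore`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic test bed does and
does not establish about real micrographs.

## Imaging model and conventions

All rasters are row-major with a top-left origin; boxes are half-open
pixel rectangles `[row0, row1) × [col0, col1)`, so the area of a box is
exactly `(row1−row0)·(col1−col0)`. Intensities are 8-bit; 16-bit input
is mapped to 8 bits linearly between its own min and max. The physical
scale is carried as µm/px (default 0.25, the sampling of a 40×
brightfield slide scanner), and all areas convert as
`area_um2 = area_px · pixel_scale²` — exactly, with no hidden rounding.

Large scans are processed as overlapping tiles (default 2048 px with
128 px overlap, both configurable; the overlap is larger than one
detection window so no stomate is ever split between all the tiles that
see it). The last tile in each direction is shifted flush with the
border rather than padded, so no synthetic pixels enter classification.
Where overlapping tiles disagree, the positive class wins: a missed
stomate costs more than a duplicate, and duplicates merge in the
connected-component stage anyway.

## Detection

### Classifier

The detector is a three-class patch classifier — *stomate*, *vein*,
*background* — applied by sliding a square window across the image.
Veins get their own class because they are the dominant elongated dark
structure on leaf imprints and would otherwise contaminate the stomate
decision boundary; at box extraction the vein class is folded into
"not stomate".

The default descriptor (`IntensityAugmentedExtractor`) concatenates

* a cell-wise gradient-orientation histogram (6×6 cells over the
  window, 9 unsigned orientation bins, magnitude-weighted with linear
  bin sharing, one global L2 normalisation) — a constant window maps to
  the zero vector; and
* a 16-bin normalised intensity histogram of the central half-window —
  stomata contain intensity extremes (dark guard-cell outline, very
  dark or very bright pore) that pure gradient energy misses when the
  region is defocused.

A pure gradient-orientation variant (`GradientHistogramExtractor`) and
the `FeatureExtractor` protocol are exposed so that an external deep
backbone can be plugged in; nothing in the pipeline depends on the
descriptor beyond its fixed length and its `extractor_id` (models
refuse features from a different extractor).

The classifier is a quadratic-kernel SVM (`SVC(kernel="poly",
degree=2, coef0=1, C=10)`). Window size defaults to 96 px ≈ 24 µm, a
typical stomate span at 0.25 µm/px.

### Training-set construction

Training patches are sampled from seeded synthetic scenes with a budget
of `n_per_class` patches per class (150 by default), split across the
training scenes:

* *stomate*: windows centred on true stomata with jitter up to 1/8
  window, so near-centred sliding windows are represented without
  teaching the classifier to fire far off-centre;
* *vein*: windows centred on vein pixels away from stomata;
* *background*: one third texture-only crops (no stomate or vein pixel
  anywhere in the window), one third "off-centre" crops (no stomate in
  the central region, anything allowed at the periphery — the view most
  sliding windows actually have), and the remainder hard negatives:
  after a first training round, the classifier is slid over its own
  training scenes and windows it wrongly calls stomate replace
  canonical background patches, within the same budget, for a second
  round. Without the off-centre and mined tranches, every window that
  touches a stomate edge fires and precision collapses.

### Localisation

The stride is 8 px (1/12 window): each window writes its predicted
class into the stride-sized cell at its centre (whole-window voting is
available behind a flag but blurs localisation). Stomate cells are
grouped by 8-connected components; components above a small minimum
(half a cell) become candidate boxes, ordered by position for
reproducibility.

Each candidate is then *refined*: a standardised crop around the
candidate centre is re-segmented with the same region machinery the
pore stage uses, the box snaps to the segmented region's bounding
rectangle, and candidates with no segmentable central region are
dropped — false positives rarely contain a coherent central structure.
The refined box is inflated by 1.15× about its centre because the
threshold contour sits systematically inside the true guard-cell
boundary. Overlapping refinements of one stomate collapse to the same
box and are deduplicated.

### Scoring

Detection is scored on grid cells, not matched objects: the manual and
automatic label masks are discretised (a cell is positive when ≥ 50% of
its pixels are; partial edge cells use their true pixel count as the
denominator), and cell-wise TP/FP/FN/TN give precision, recall and
F-score. Cell size defaults to the detection stride. Summary metrics
are unweighted per-image means — the only averaging scheme consistent
with the published summary values this package's evaluation arithmetic
reproduces. On synthetic scenes the "manual" mask is the rasterisation
of the ground-truth boxes.

## Pore-area estimation

The stages run in this order; any stage can end the run with
`no_detection` (nothing to measure) or `rejected` (a sanity check
failed). All failure paths are statuses with reasons, never exceptions.

1. **Enhance.** CLAHE on luminance (RGB collapses by 0.299/0.587/0.114),
   then a global linear stretch to [0, 255], then an unsharp mask
   (radius 2 px, amount 0.5). CLAHE uses a 2×2 kernel grid and clip
   limit 0.005 (fraction-of-histogram semantics): stronger, finer-tiled
   equalisation amplifies epidermal wall texture until it competes with
   the stomata. The equalisation is *symmetrised* —
   `E(u) = (CLAHE(u) + 1 − CLAHE(1−u))/2` — which makes the whole
   enhancement exactly anti-symmetric under intensity inversion. That
   matters: it is what reduces the polarity problem to a sign flip (see
   below).
2. **Binarise.** Otsu's threshold over integer cut points (maximising
   between-class variance of `{≤t}` vs `{>t}`, smallest-t tie-break,
   verified against an exhaustive 256-candidate oracle). The
   *minority* class becomes foreground: the stomate occupies a minority
   of a bounding-box patch whichever side of the threshold it falls on,
   and the rule is invariant under inversion — the foreground pixel set
   of an inverted patch is identical, so polarity flips while the
   geometry stays fixed.
3. **Filter.** 8-connected components with area ≤ 50 px² are removed
   ("no larger than" read strictly: exactly 50 px² is removed). This is
   the dust/air-bubble filter; raising the cutoff can only shrink the
   surviving set (a property the tests pin).
4. **Select.** Among components whose centroid falls in the central 50%
   box of the patch, the largest wins (ties break toward the centre).
   The raw component is then regularised, because on textured imagery
   the thresholded component is rarely just the stomate:
   * components running border-to-border are split by erosion — a vein
     or wall band crossing the patch is erased while the (hole-filled)
     stomate body survives as a core and is grown back;
   * only *central* cavities are filled (the stomate interior around
     the pore); a background pocket enclosed between the stomate and
     attached wall fragments is left open, since filling it drags the
     centroid off the pore;
   * a small opening detaches thin wall tendrils; the mask is trimmed
     to its moment-equivalent ellipse (inflated 1.15×, anchored halfway
     between mask centroid and patch centre) and the shaved boundary
     sliver restored;
   * if the cleaned mask still fits its own moment ellipse poorly
     (1 − IoU > 0.12), the foreground is re-thresholded by a second
     Otsu pass over foreground pixels alone — the global threshold can
     lump the stomate with an adjacent structure of similar tone — and
     a sub-population's region replaces the original only if it fits at
     least twice as well while keeping ≥ 30% of the area.
5. **Align.** The image and mask rotate by the mask's major-axis
   orientation (second moments; angle in (−90°, 90°] from horizontal)
   about the canvas centre with expansion; grey bilinear, mask
   nearest-neighbour. Nearly circular masks (axis ratio < 1.05) skip
   rotation. The rotation's coordinate map is kept so that points can
   be carried back to the patch frame exactly.
6. **Cross-section.** The intensity trace along the column through the
   rotated mask's centroid, clipped to the mask's vertical extent
   padded by 2 px, smoothed by a centred 3-sample moving average.
   Strict local extrema with prominence ≥ 5% of the profile range are
   kept; fewer than 5 samples, no extrema, or more than 10 extrema
   (an oscillating profile has no single discernible pore) end the run.
7. **Pore centre.** The extremum nearest the centroid is the pore
   centre — a peak means the pore is lighter than its surroundings, a
   valley darker. Distances are compared with 3 px of slack (the
   centroid of an imperfect mask is only that accurate); within the
   slack band the most prominent extremum wins, residual ties go to the
   nearer, then to the valley.
8. **Grow.** The seed is mapped back to the *unrotated* patch through
   the exact inverse of the alignment transform, and the pore grows
   there by 8-connected flood fill with tolerance = 0.5 × the centre
   extremum's prominence. Growing on unresampled pixels avoids the
   ~1 px loss of back-rotating a thin mask; half-prominence growing
   places the boundary at the contour halfway between pore centre and
   shoulder, which adapts to local contrast and is what keeps the
   estimate stable under defocus (a fixed fraction of the profile range
   severely under-segments blurred pores).

Accepted estimates must additionally pass: the pore does not cover half
the patch border; the pore is at least 15 px (sub-resolution "pores"
in noise are meaningless at 0.25 µm/px); the pore is no larger than the
hole-filled stomate region; and the pore centroid lies inside it.

### Polarity robustness

The design goal is that inverting a patch's intensities changes
*nothing but the polarity label*. Every stage is inversion-equivariant
by construction: symmetrised CLAHE (anti-symmetric), linear stretch and
unsharp mask (linear), minority-class Otsu foreground (identical pixel
set), morphology on the same mask, peaks↔valleys swap on the mirrored
profile with equal prominences, and an identical flood region. The
test suite asserts this end to end: on clean synthetic patches the
inverted estimate has opposite polarity and a pore mask with IoU ≥ 0.9
against the original.

## Synthetic scenes

`synthgen` renders what the pipeline must cope with, not photorealism:

* **Stomata**: an outer guard-cell ellipse (annulus at intensity 140)
  around an inner ellipse (160) containing a lens-shaped pore — the
  intersection of two ellipses offset along the minor axis — at 70
  (dark) or 230 (light), on a 180 background. Polarity is an intensity
  swap only. Major axis 30–60 px, aspect 0.4–0.6, uniform orientation,
  centres rejection-sampled so pairwise distances exceed the larger
  major axis. The rasterised pore and stomate masks are the ground
  truth and stay exact because blur and noise are applied afterwards.
* **Background**: a Voronoi tessellation of epidermal cells with
  per-cell tone jitter and darkened walls (15 levels deep, 1.5 px
  wide) — the texture that makes region selection genuinely hard.
* **Veins**: dark curved strokes (2–5 px half-thickness) anchored in
  the interior and walked outward with random curvature.
* **Artifacts**: dust specks and bubble rings below the 50 px² cutoff.
* **Degradations**: spatially varying Gaussian blur (σ drawn from
  (0, 1.5) by default over a smooth 4×4 field, emulating focus
  variation across a scan) and additive Gaussian noise (σ = 3).

Scenes are pure functions of their `SceneSpec` (including the seed):
generation twice with the same spec is bit-identical, which the
determinism tests rely on. A `clean()` spec variant (no blur, noise,
veins or artifacts) is the oracle condition for the polarity tests.

What passing synthetic tests does **not** show: real imprints have
imaging physics the generator ignores (depth-of-field, imprint
deformation, species-specific morphology, staining); published per-image
accuracies on real micrographs are not reproducible from synthetic data
and are treated purely as arithmetic (their table values are inputs
whose derived columns the evaluation module recomputes). The synthetic
targets mirror the *structure* of those results — detection recall
above precision, a minority of patches rejected as having no measurable
pore — at smaller problem sizes: 3 training scenes × 50 patches/class,
10 evaluation scenes of 20 stomata each (768² px), and 50-patch cohorts
for the pore properties. These sizes keep the full suite and the
reproduction script within a few CPU-minutes while leaving each
statistic enough support to be stable across seeds.

## Numerical choices and edge cases

* Otsu ties break toward the smallest threshold; constant images are a
  degenerate-input error that callers map to `no_detection`.
* A stretch over a zero intensity range is the identity; 1-pixel
  patches pass through enhancement unchanged.
* Two-run determinism holds end to end (no randomness outside the
  seeded generators; SVM training is deterministic for a fixed seed).
* Mask connectivity is 8-connected everywhere, including the flood
  fill; diagonal-touching components merge (a documented choice —
  4-connectivity would split them).
* Degenerate metric denominators (no predicted or no true positives)
  raise a typed error that table writers render as NA rather than 0.
* The published pore-accuracy table's percentage column mixes rounding
  conventions in print; derived columns here use standard half-up
  rounding to 2 decimals, and both the pooled accuracy
  (correct/available over all rows) and the mean of per-row percentages
  are reported, since the two genuinely differ.

## Known limitations

* The pore boundary is pixel-quantised; no sub-pixel refinement.
  Aperture width/length decomposition and open/closed classification
  are out of scope, as is guard-cell (outer boundary) segmentation.
* Detection assumes roughly stomate-sized windows; scale is not
  searched. Changing magnification requires retraining and a new
  window size.
* The classifier is only as good as the scene family it was trained
  on; on real micrographs the synthetic-trained model is a starting
  point, not a result.
* Very heavily merged structures (a stomate sharing its full boundary
  with an equally dark neighbour) can still defeat region selection;
  such patches surface as `rejected`/`no_detection` rather than wrong
  areas, which is the intended failure direction.
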