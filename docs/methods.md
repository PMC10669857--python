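# Methods

## The quality model

`endoqa` treats image quality as the complement of accumulated artifact
penalties. Given detections B (box, class label, confidence) on one frame,

    QS = clamp(1 − Σ_B [ λ_A · wC(B) · wCo(B) · wA(B) + λ_L · wC(B) · wCo(B) · wL(B) ], 0, 1),
    score = 5 · QS,

with

| weight | meaning | default |
| --- | --- | --- |
| wC | class weight | artifact 0.50, blur 0.20, specularity/saturation/contrast 0.10, bubbles/instrument/blood 0.02 |
| wCo | detector confidence | taken from the detection, in [0, 1] |
| wA | fraction of the effective imaging area covered by the box | computed exactly against the effective-area mask |
| wL | location weight of the 3×3 grid cell containing the box center | center 0.5, edge cells 0.25, corner cells 0.125 |
| λ_A, λ_L | balance of the area vs location term | 0.5 each |
| confidence_floor | detections below it are ignored before scoring | 0.05 |

Assumptions worth making explicit: penalties are additive and independent
across detections; the area term counts each detection's own coverage, so
two fully-overlapping boxes penalise twice (a union-area variant,
`WeightConfig(union_area=True)`, counts overlap once and exists for
sensitivity analysis); a box's location is its center point, so a box
spanning several grid cells is attributed entirely to one zone; and the
mapping to the 0–5 expert rubric is linear. The clamp at zero is required
because an arbitrarily loaded frame would otherwise go negative; it means
the score saturates (all fully-degraded frames score 0 regardless of how
much worse one is than another).

The balance λ_A = λ_L = 0.5 deserves a note: for realistically small
artifacts (wA of order 10⁻²–10⁻³) the location term dominates the penalty,
so the score behaves mostly like a class- and position-weighted *count* of
artifacts, with area as a secondary correction. This is consistent with the
rubric's wording (few/small vs numerous/large artifacts) but matters when
validating against area-based severity (see the synthetic-data section).

## Effective-area extraction

Raw frames hold the informative field of view on a black border with
burned-in overlays. The mask is `largest_component(CLOSE(gray > t))`, where
CLOSE is dilation followed by erosion with a disk footprint. Defaults:
threshold t = 15/255, disk radius 5 px — both exposed, chosen so that JPEG
noise in the border stays below threshold while dim mucosa stays above, and
so that text gaps and speckles up to ~2·radius are absorbed. The closing is
computed on a zero-padded copy (pad = 2·radius) so it matches the ideal
plane-embedded operator; this makes it exactly idempotent and extensive,
both of which are property-tested. Working frames are cropped to the mask's
bounding rectangle and resized (aspect-distorting) to a square target
(default 800×800); the affine box transform is returned and invertible to
±0.5 px. A mask-multiply mode (`crop=False`) is available where cropping is
not wanted.

## GIoU

GIoU = IoU − (Ac − U)/Ac with U the union area and Ac the minimum
axis-aligned enclosure. Implemented in closed form, vectorised; degenerate
boxes raise instead of returning 0 (silent zeros mask upstream jitter
bugs). The regression loss is 1 − GIoU with mean/sum reduction. A
rasterising pixel-count oracle (`rasterized_giou`) provides the independent
cross-check on integer boxes.

## Feature-fusion components

The detector-side contributions are implemented as standalone numpy
operations so they can be tested without a training framework:

* bilinear upsampling with corner-aligned sampling (factor 1 is the
  identity; affine ramps are reproduced exactly);
* squeeze-excitation channel attention: global average pool → two-layer
  bottleneck (default reduction 16) → sigmoid gate per channel;
* the improved pyramid: lateral 1×1 projections of C2–C5 to a shared
  channel count, attention gating of C5 (per-level gating behind a flag),
  top-down 2× upsample-and-add, a high-resolution aggregate
  P0 = L2 + up₂(L3) + up₄(L4) + up₈(L5′), and a PANet-style bottom-up
  path-enhancement pass (stride-2 3×3 conv + add) yielding P2–P5.

Projection weights carry no bias, so the fusion is exactly linear in its
inputs when attention is bypassed — the degenerate case C3=C4=C5=0 yields
P0 identical to the projected C2, which is asserted bitwise-close in tests.
A 4-stage toy backbone (random fixed weights) and a linear box-refinement
head close the loop: one gradient step (central finite differences over the
tiny head, with backtracking) on the GIoU loss of a 3-box scene must
decrease the loss. Full-scale detector training is out of scope; the
backbone is an interface.

## Detection evaluation

Matching is greedy in descending confidence with a same-class constraint;
a detection is TP iff its best-IoU unmatched ground truth reaches the
threshold. AP uses all-point interpolation, AP = Σ (r₊ − r)·max p over
recalls ≥ r₊, computed from the pooled staircase; the report averages IoU
thresholds 0.50:0.05:0.95 and stratifies by box area at the 32² / 96² px
cutoffs. In the size strata, ground truths and detections are filtered by
their own area — a simplification of the ignore-list mechanism some
toolkits use, adequate at the scale exercised here. The confusion matrix
matches class-agnostically (otherwise off-diagonals would be empty by
construction) and books unmatched items against a background row/column.

Spearman's ρ is the Pearson correlation of average ranks; the p-value uses
the t approximation (fine at the n = 50–100 used here), with an exact
permutation option for n ≤ 8. scipy's implementation serves as an
independent cross-check in the tests, not as the implementation.

## Synthetic scenes

No public dataset exists for this task, so validation runs on generated
scenes. Defaults are fixed once and shared by tests and the acceptance
script: 512×512 frames (tests drop to 256 where only relative geometry
matters, to keep the suite fast); a disk effective area of radius 0.46·size;
modality palettes (reddish WLI, teal NBI, brown iodine) with mild Gaussian
texture; class frequencies proportional to the real annotation statistics
(specularity 46.98 %, artifact 23.33 %, …, instrument 0.73 % — imbalance
≈ 64.5:1); 20 % small targets (both sides 8–28 px, matching the < 30 px
small-target regime; non-small boxes keep both sides ≥ 30 px so the small
fraction is controlled by this parameter alone); artifact load specified
either as a box count or as a target fraction of the effective area. Each
primitive (saturated blobs, ring clusters, local low-pass patches,
exposure shifts, dark occluders, red blobs, textured fragments) gets a
tight ground-truth box. The recorded latent severity is the summed box-area
fraction of the effective area.

The detector simulator drops boxes at a miss rate, jitters corners with
Gaussian noise, draws confidences from clipped normals, confuses classes
through a row-stochastic matrix, and adds Poisson-distributed spurious
boxes; the zero-noise setting is an oracle detector (detections ≡ ground
truth, confidence 1), which anchors the AP = 1.0 checks.

What the scenes do *not* emulate: tissue texture, vasculature, lighting
gradients, lens distortion, interlacing, or correlated artifact placement.
Passing tests therefore demonstrate the correctness of the geometry,
evaluation and scoring machinery — not detection difficulty or clinical
score validity on real frames.

### Known limitation: score-vs-severity rank agreement

Because the score weighs classes across a 25× range and its location term
does not scale with box area, while the recorded latent severity is raw
area, the two rank scenes differently when the class mix varies. Over 50
oracle-detected scenes with loads swept 0–50 % under the default class
frequencies, Spearman |ρ| lands around 0.75 (≈ 0.88 when scenes sit at four
well-separated load levels; ≈ 0.94 for single-class scenes). The
correlation is strongly negative and highly significant, but a ≥ 0.9 bound
is not met under these conditions: the shortfall is a property of the
scoring model's intentional class weighting, not an implementation defect,
and the corresponding acceptance test is left failing rather than relaxed.

## Augmentations

Mosaic splits the canvas at a random point in the central 30–70 % band,
fills each quadrant with one input scene resized to the quadrant, clips
boxes to their quadrant and discards boxes retaining < 25 % of their area.
Rescale, flips and rotations are box-consistent; rotations are restricted
to right angles so boxes stay axis-aligned. Box/raster consistency (IoU
≥ 0.95 after transforming either representation) is property-tested.

## Numerical choices

* Boxes are continuous, 0-based corner coordinates; COCO [x, y, w, h] on
  input/output; boxes are clipped to the image extent and zero-area
  remnants dropped.
* wA is computed by exact cell-overlap integration against the binary
  mask (partial pixels weighted by covered length), so rectangle-on-
  rectangle cases are exact rather than rounded.
* All generators use `numpy.random.default_rng` seeded from the spec or
  CLI; equal seed ⇒ bit-identical output.
* Problem sizes: 10⁴ box pairs for the GIoU oracle sweep, 30 scenes for
  the oracle-AP table, 50 scenes for severity tracking, 100 binary images
  for idempotence — sizes at which every check is stable across seeds.
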