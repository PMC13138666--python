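# Methods

## Problem setting

A hemocytometer slide has four counting chambers, each with a 1 mm² etched
grid at 0.1 mm depth, so each grid sees 0.1 mm³ = 10⁻⁴ mL of suspension.
Counting the cells inside the grid of each chamber and averaging gives

    concentration [cells/mL] = mean count per chamber × dilution factor × 10⁴.

The package automates the two hard steps when the input is a phone
photograph rather than a calibrated microscope frame: finding the grid
region in a cluttered image, and counting quasi-circular cells without
counting grid lines.

## Synthetic scenes

No public dataset of phone-photographed counting chambers is available, so
the package defines its study conditions through a seeded generator.

A *chamber scene* (default 400×400 px) is a bright field
(background intensity 200) ruled by darker grid lines (intensity 150,
spacing 50 px, width 2 px) containing `n_cells` anti-aliased dark discs
(intensity 70) with radii drawn uniformly from 8–12 px. Cell centres are
rejection-sampled with a minimum separation of 24 px (= 2·r_max), which
guarantees non-overlap; a bounded number of attempts guards against
impossible packings. A multiplicative illumination ramp (default 10 %
across the width) and additive Gaussian noise (σ = 4 grey levels) are
applied last, and the image is replicated to RGB. Ground truth records the
exact centres, radii and count.

A *phone scene* pastes a chamber scene at a random offset into a larger
(1.6×) darker canvas with clutter: a low-frequency intensity field, random
filled rectangles, and thin text-like strokes, all scaled by a clutter
level in [0, 1]. The pasted rectangle is the ground-truth ROI box. At
clutter level 0 the background is exactly uniform.

The *training set* for the ROI classifier contains chamber crops (label 1)
and non-chamber crops (label 0). Positives vary in size and aspect ratio,
grid geometry, intensities, noise and illumination. Negatives are a mixture
of cluttered canvases (50 %), blank patches at arbitrary brightness (30 %),
and elongated slivers (20 %) — the three kinds of content region proposals
actually produce on phone scenes. Early versions lacking the blank-patch
negatives produced classifiers that equated "bright" with "grid" and
accepted featureless bright rectangles; the mixture is part of the study
design, not a tuning knob.

Determinism: every generator call derives all randomness from the seed in
its parameter object; identical parameters give bit-identical images.

What the generator does *not* emulate: lens distortion, JPEG artifacts,
perspective tilt, overlapping or out-of-focus cells, debris that mimics
cell texture. Passing the synthetic benchmark therefore demonstrates the
pipeline's correctness and calibration under clean, non-overlapping
conditions — not clinical-grade accuracy on real phone photographs.

## ROI extraction

**Proposals.** True selective search over an oriented feature set is
approximated by: Felzenszwalb over-segmentation (scale 150, σ 0.8,
min size 80), then greedy hierarchical merging of adjacent regions by a
similarity that sums colour-histogram intersection (8 bins/channel), a
size term favouring small merges, and a bounding-box fill term. Every node
of the merge hierarchy contributes its bounding box; boxes from high in
the hierarchy (large grouped objects) are ranked first, then initial
segments by size, deduplicated, truncated to `max_proposals` (default
200). Boxes under 256 px² are dropped.

**Classifier.** A sequential network: Conv 2×2×256 → BatchNorm → ReLU →
MaxPool 2×2 → Conv 2×2×128 → BatchNorm → ReLU → MaxPool → Dropout 0.25 →
Flatten → Dense 128 → BatchNorm → ReLU → Dense 128 → BatchNorm → ReLU →
Dense 64 → ReLU → Dropout 0.5 → Dense 2 → softmax. ReLU activations,
dropout rates and the exact placement of normalization are design choices
surfaced in `ClassifierConfig`. Inputs are crops resized to
`input_size` and scaled to [0, 1]; the nominal input size is 256×256, and
tests/acceptance train at 32×32 (architecture unchanged) to keep
single-CPU runtimes in seconds — the synthetic contrast is
low-frequency enough that the reduced resolution is sufficient.

**Training protocol.** 90/10 train/validation split, 10 epochs, batch 32,
horizontal-flip augmentation (ROI-ness is flip-invariant by construction),
categorical cross-entropy, Adam (lr 10⁻³). All randomness (split, shuffle,
flips, dropout, init) flows from one seed.

**Selection policy.** Among proposals classified ROI, highest ROI
probability wins, with ties broken toward larger area. Scores are compared
at three decimals: once the softmax saturates, many boxes score
indistinguishably and the area tie-break must engage, otherwise float
noise picks an arbitrary (often tiny) sub-crop of the grid. If no proposal
is classified ROI the extractor raises `NoRoiFound`; the CLI can fall back
to counting the whole frame.

## Cell counting

Stages: RGB → grayscale (ITU-R 601 weights) → morphological opening →
Canny → Hough circles → perimeter verification.

*Morphology* implements grayscale erosion/dilation as neighbourhood
min/max over the structuring-element footprint (3×3 square by default,
disc available) with reflect padding, which reduces exactly to the
binary fits/hits definitions on 0/1 images. Opening removes structures
smaller than the element; it is idempotent and anti-extensive, and the
test suite verifies equivalence with a brute-force evaluation and with
scipy's rank filters.

*Canny* thresholds couple to the Hough edge parameter: high = `param1`,
low = `param1`/2, both overridable; Gaussian σ = 1.4.

*Hough transform.* Votes for candidate `(a, b, r)` are the number of edge
pixels whose rounded Euclidean distance to `(a, b)` equals `r`
(implemented by scatter-adding precomputed circle offsets; verified
identical to the exhaustive per-centre oracle). Candidates above the
accumulator threshold `param2` are reduced by greedy non-maximum
suppression, strongest first, enforcing `min_center_dist` (default
= `min_radius`) between centres. Because a stricter threshold only
truncates the sorted candidate list, detections are monotone: raising
`param2` or the support threshold can only remove detections.

*Perimeter verification.* Each surviving circle is sampled at ≈2πr points;
the support is the fraction of samples within 1 px of an edge pixel, and
the circle is accepted if support ≥ `support_threshold`. This is the
mechanism that rejects grid-line artifacts: straight-line edge structures
can accumulate votes but never trace most of a circular perimeter.

**Calibration.** The defaults (param1 = 60, param2 = 28,
radius band 6–14 px, support threshold 0.8) were calibrated once on the
synthetic benchmark. Two findings drove them: (i) param1 = 60 keeps
grid-line edges *in* the edge map (≈10⁴ edge pixels on a cell-free
chamber), so rejection is done by the circle transform and the perimeter
check rather than by making the grid invisible — mirroring real images
where grid lines do produce edges; (ii) a support threshold of 0.3 is far
too permissive in edge-dense images: circles threaded between neighbouring
cell arcs and grid lines reach 30–50 % accidental support, inflating
counts several-fold, while genuine cells achieve >85 % support. With the
calibrated defaults the per-scene counting error on 20 benchmark scenes is
≤2 %. For images at other magnifications the radius band must be set to
the apparent cell radius in pixels; all parameters are exposed on
`CellCounter`.

**Border rule.** Circles whose centre lies inside the crop are counted
regardless of rim clipping; the classical count-two-edges hemocytometer
convention is not implemented (the generator keeps cells fully interior,
so the benchmark cannot distinguish the two rules).

**Aggregation.** Exactly four chambers are required by default
(overridable), and the report carries every accepted circle with its
support, the total, mean, dilution and concentration.

## Evaluation metrics

Per-class precision, recall and F1 (one-vs-rest), accuracy, and macro
(unweighted) and weighted (support-weighted) averages. Zero denominators
return 0 with a warning. Report formatting rounds to two decimals; raw
values are kept. For counts, accuracy = measured/actual × 100 % and
error = |100 − accuracy| (undefined at actual = 0). The suite checks all
formulas against sklearn on random confusion matrices, and the identity
weighted recall ≡ accuracy for the 2-class one-vs-rest construction.

## Numerical and design notes

* The neural-network engine is float32 numpy (im2col + GEMM convolution,
  argmax-routed max-pool gradients, batch-norm with running statistics,
  inverted dropout, Adam with bias correction); backpropagation is checked
  against central finite differences, with a small failure budget for
  perturbations that cross ReLU/max kinks.
* Hough NMS tie-breaks are lexicographic on (votes desc, y, x, r), making
  detection order deterministic.
* Accumulator resolution is fixed at 1 px (the `accumulator_resolution`
  field validates this); sub-pixel centres are not estimated.
* Box convention everywhere: 0-based (row, col) pixels, boxes
  (x0, y0, x1, y1) half-open with x = column.
* Problem sizes used by tests and the acceptance script — 32×32 classifier
  input, 400-image training sets, 10-scene benchmark, 3 training seeds —
  are the package's chosen benchmark scale; all are parameters, not
  constants.

## Known limitations

* No declumping: overlapping cells merge into one or zero detections; the
  generator's non-overlap guarantee sidesteps this deliberately.
* The ROI classifier is trained on synthetic contrast statistics; applying
  it to real photographs requires retraining on a real `ROI/`–`Non_Roi/`
  directory pair (supported by `hemocount train --data-dir`).
* Per-cell-line Hough presets (PC3 / LN-CaP / DU-145) currently share the
  calibrated defaults; the label is metadata threaded into reports.
* Very low contrast (cell vs background < ~40 grey levels) pushes cell
  edges under `param1` and produces undercounts; lower `param1` and
  `param2` together in that regime.
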