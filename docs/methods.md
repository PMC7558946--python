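# Methods

## Scope and model

`tabletscan` classifies the film-coating level of pharmaceutical tablets
from RGB raster images of scanned sheets. Four ordinal classes are used —
1 uncoated, 2 slightly, 3 moderately, 4 fully coated — plus class 0, a
rejection label emitted by discriminant models for tablets not strictly
predicted into any single class. The physical premise is colorimetric: a
yellow dye film (e.g. tartrazine) absorbs blue light, so the blue channel
of a scanned tablet declines monotonically with deposited coating, while
red and green respond later and more weakly. All methods in the package
reduce to reading that structure out of per-tablet pixel statistics.

## The synthetic scanner

Real scanned sheets live in an external archive, so the package carries a
seeded generator (`tabletscan.synthetic`) whose outputs stand in for them
everywhere. It emulates the *statistical* structure the analysis relies
on, not scanner physics.

**What is modelled.** Tablets are filled ellipses on a dark neutral
background, placed uniformly at random under two constraints: pairwise
boundary gaps of at least `min_gap_px` (checked on bounding circles) and
no contact with the sheet border. Color varies at two levels: each tablet
draws one base color from its class's per-channel normal distribution
(between-tablet variation — uneven spray deposition), and i.i.d. Gaussian
scanner noise of sd `noise_sd` is added per pixel afterwards
(within-tablet variation), with clipping to [0, 255] at both stages. One
`numpy.random.Generator` (PCG64) per sheet is consumed in a fixed order —
placement draws per tablet, base colors per tablet, one noise field — so
a (spec, seed) pair regenerates a sheet bit for bit.

**Default parameters and why.**

| parameter | default | rationale |
|---|---|---|
| sheet size | 1024 × 768 px | desk-scale; the 600 dpi full-sheet geometry (9921 × 7015) is metadata-compatible but wasteful for tests |
| background | RGB (40, 40, 42) | dark, neutral, far from all class colors: binarization is unambiguous by design |
| tablet radii | 14.7–15.3 px semi-axes | pressed tablet batches are dimensionally uniform to roughly ±2%; area uniformity is what makes a raw intensity *sum* a usable class statistic (a ±7% radius spread would confound class with size) |
| class means (R, G, B) | (242, 240, 235), (241, 231, 178), (237, 211, 128), (223, 178, 86) | saturating absorption kinetics: blue decrements shrink (57, 50, 42) as the film builds, green and red fall late and progressively faster; the kinetics curve the class-mean path in RGB space, as real dye deposition does |
| per-channel sd | 8 (default), 4 (`well_separated` preset) | default gives adjacent-class blue gaps of ~6 sd — a regime with rare borderline tablets; the separable preset widens that to ~12 sd |
| scanner noise sd | 3 | small relative to the ~150-unit tablet/background luminance contrast, so thresholding is unaffected while flat interiors are avoided |
| batch sizes | 623 / 596 / 595 / 504 | the reference study layout; `batch_fixture(scale)` scales them with half-up rounding (2318 tablets at scale 1) |

**What is not modelled**, and hence what passing tests cannot show:
illumination gradients, specular highlights, surface texture (orange
peel, speckle), shape defects, touching tablets, compression artifacts.
Tablets are *flat-colored* ellipses; every within-tablet pixel is the
base color plus white noise. One measurable consequence is discussed
under PLS-DA below.

## Segmentation

Luminance is the BT.601 combination `round(0.299R + 0.587G + 0.114B)`;
the default threshold is Otsu's, and whichever side of it covers less
than half the sheet is foreground (tablets are sparser than background in
either scan polarity). A constant sheet yields an empty mask. Components
are labelled 8-connected (scipy), ids dense from 1.

Outer boundaries are traced by Moore-neighbor tracing, starting at the
topmost-leftmost region pixel entered from the West, scanning the
neighborhood clockwise. The textbook stopping rule (re-entering the start
from the original direction) does not terminate on some spur shapes, so
termination is generalized to a repeat of any (pixel, entry-direction)
state — a strict superset of the textbook rule that provably terminates
and returns the same closed walk. The traced set equals, on every random
mask tried, the set of foreground pixels 4-adjacent to the
border-connected 4-connected background; the test suite enforces this
characterization as an oracle. Holes are not re-labelled and inner
boundaries are not traced. A single-pixel region traces to itself.

Filtering drops regions below `min_area` (default: 25% of the area of the
smallest configured tablet radius, ≈170 px for radius 14.7) and, under
the default `border_policy="drop"`, any region whose bounding box touches
the sheet edge — partially scanned tablets are worthless downstream. The
count of rejected regions is reported, not silently discarded. Crops are
plain bounding-box rectangles (inclusive bounds, 0-based, x right, y
down), background corners retained.

## Features

`downsample` reduces a crop by integer factor *d* with output dims
`ceil(in/d)`. Default mode is `decimate` (keep every *d*-th pixel from
index 0) — the cheapest reading of "downsampling by a factor"; 
`block_mean` (partial edge blocks averaged over available pixels, half-up
rounding to 8 bits) is offered since the resampling kernel is otherwise a
free choice. Desk-scale runs use *d* = 4, which leaves a ~30 px synthetic
tablet about 8 px across — the same post-downsampling size that *d* = 50
leaves a ~10 mm tablet at 600 dpi.

Crops are centered onto a canonical canvas (the per-axis maximum over the
dataset's downsampled crops, computed in a first pass) with fill value 0,
so padding changes no summed intensity. Summed intensity
`s_c = Σ_{x,y} I_c(x,y)` is taken over the whole rectangular crop,
background included — matching what a bounding-box crop of a traced
object naturally gives; with a dark background the contamination is a
small additive offset common to all classes. Vectors are flattened
row-major within channel planes, planes ordered R, G, B.

## Classifiers

**NTC.** Three thresholds `t1 > t2 > t3` on one summed channel (blue by
default; configurable for differently colored coatings). Prediction:
`s > t1 → 1`, `t2 < s ≤ t1 → 2`, `t3 < s ≤ t2 → 3`, `s ≤ t3 → 4`; a value
exactly on a threshold goes to the higher (more-coated) class. Fitting
sorts intensities descending and minimizes training misclassifications
exactly over all cut-position triples via a dynamic program (O(n) after
sorting); among minimizers the widest total margin wins, then the lowest
cut positions, and each threshold is the midpoint of the straddling
values (extreme cuts fall one unit outside the data range). When an
optimal solution leaves a predicted interval empty, coincident thresholds
are separated by a relative epsilon to preserve strict ordering. The test
suite checks the achieved training error against an exhaustive scan over
every candidate triple.

**PLS-DA.** PLS2 regression of one-hot class indicators on the flattened
vectors, mean-centering only (no variance scaling). The latent-variable
count is selected by venetian-blinds cross-validation (sample *i* → fold
*i* mod *k*, default *k* = 10) minimizing held-out misclassifications
under the same strictness rule used at prediction time; ties go to the
smaller count. The default rule is `unique_above_cut` at 0.5: accept
class *j* only when its score alone exceeds 0.5, else class 0. Centered
one-hot responses make every score vector sum to exactly 1 (asserted in
tests).

*Known behavior:* on the synthetic presets PLS-DA reaches only ~45–60%
held-out accuracy while NTC/SVM/CNN are at or near 100%. This is the
classic masking of linear indicator regression: flat-colored tablets make
the informative structure essentially the one-dimensional yellowing
direction (weakly curved into three dimensions), and least-squares score
functions for the inner classes are then nearly flat, so argmax and
strict rules both fail them. It is a property of the data model, not a
defect of the fit; richer within-tablet structure (gloss, texture,
shading — all outside the generator's scope) is what a linear
discriminant needs to separate inner classes well.

**SVM.** One-vs-one multiclass SVC, RBF kernel, host-library default
regularization (C = 1, gamma = "scale"), features scaled to [0, 1] by
/255. `channel_subset="B"` restricts to the blue plane's columns — one
third of the features — mirroring the univariate-knowledge variant.

**CNN.** Blocks of 3×3 same-padded convolution → ReLU → 2×2/stride-2 max
pooling (filter sizes fixed by construction), then a dense softmax.
Implemented directly on numpy (im2col convolutions, argmax-routed pooling
gradients), trained with mini-batch Adam on cross-entropy, training set
reshuffled every epoch, everything driven by one seeded generator —
fits are bit-reproducible. Inputs are scaled to [−0.5, 0.5]
(`x/255 − 0.5`); without centering, all-positive inputs put every
first-layer ReLU on one side and the net is prone to dead units at usable
learning rates. Defaults: 3 blocks of (8, 16, 32) channels, learning rate
0.01, batch 32, 128 epochs, 372 training images drawn per class — the
full-scale budget, in which 11 iterations per epoch cap the optimizer at
`128 × 11 = 1408` steps. Desk-scale configurations (2 blocks, ~30 epochs,
`train_per_class=None`) are used in tests and the acceptance script;
classes with fewer images than the per-class quota are an error rather
than a silent shrink.

## Evaluation

Accuracy is `100 · n_correct / n_total` rounded **half-up** to one
decimal (`decimal.Decimal`, not banker's rounding), matching printed
precision conventions; 2237/2297 → 97.4, 2294/2297 → 99.9,
2288/2297 → 99.6. Class-0 predictions are always misclassifications and
occupy their own confusion-matrix row (5×4: predicted 0–4 × true 1–4).
Model comparison requires identical truth marginals, sorts by accuracy
descending with alphabetical tie-break, and reports per-class recall.

## Problem sizes

Tests and the acceptance script run the pipeline at desk scale, chosen so
the whole suite completes in well under a minute on one CPU: 512×384 or
1024×768 sheets, 20–232 tablets per experiment, downsample factor 4,
100-sheet segmentation sweeps, 500-mask labeling oracles, 200-instance
NTC oracles, CNN runs of 2–30 epochs on 8×8 crops. The acceptance script
simulates 10% of the reference batch sizes (232 tablets, 62/60/60/50) and
evaluates on a stratified held-out half (116 tablets); the full-scale
2318-tablet bookkeeping is verified via the generator's placement-only
mode, which computes geometry and truth without rasterizing.

## Limitations

- The generator's flat-color tablet model understates within-class image
  structure; classifier accuracies on it say nothing about texture-driven
  failure modes on real scans, and they place PLS-DA at a structural
  disadvantage discussed above.
- Touching tablets are out of scope (no watershed splitting); the
  workflow assumes sheets are laid out with separated tablets.
- Placement uses bounding-circle overlap tests, so very elongated
  ellipses waste sheet area; radii within the package's defaults make
  this negligible.
- The strictness rule's 0.5 cut is a convention; discriminant toolboxes
  differ in how they derive per-class thresholds, and no claim of
  bit-compatibility with any of them is made.
- CNN training is CPU-scale and single-threaded numpy; it is meant for
  crops of tens of pixels, not full-resolution images.
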