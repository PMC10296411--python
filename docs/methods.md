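# Methods

`mayseg` implements a three-stage tumor-detection pipeline for 8-bit
grayscale brain images: entropy-based multilevel segmentation driven by a
mayfly swarm, dual feature extraction (HOG + residual embedding) with
entropy-based fusion, and a bidirectional-LSTM classifier.  Every stage is
exercised end to end on seeded synthetic phantoms with exact ground truth.
This note records the model choices, the parameters that matter, and the
known limitations.

## Kapur multilevel thresholding

A threshold vector `T = (t_1, …, t_{n−1})`, strictly increasing over the
gray range `[0, L)` (default `L = 256`), induces half-open classes
`[0, t_1), [t_1, t_2), …, [t_{n−1}, L)`; a threshold assigns its own level
to the upper class.  For class `C` with mass `ω = Σ_{s∈C} p_s` the class
entropy is `H(C) = −Σ (p_s/ω) ln(p_s/ω)` in nats, and the objective to be
maximized is `Σ_C H(C)`.  Conventions:

- Zero-mass classes contribute zero entropy rather than NaN.  Numerically,
  any class with mass below `1e−12` is treated as empty — the interval
  table below cannot distinguish smaller masses from cancellation noise.
- Ties in the exhaustive arg-max are broken toward the lexicographically
  smallest threshold vector, for determinism.

`exhaustive_best_thresholds` enumerates all valid vectors for 2–4 classes
(`C(255, 2) ≈ 32 k` pairs for 3 classes, `C(255, 3) ≈ 2.7 M` triples for 4)
using a precomputed interval-entropy table: with cumulative sums of `p` and
`p ln p`, the entropy of `[a, b)` is `ln ω − (S_b − S_a)/ω`.  The
cumulative differences cancel catastrophically for near-empty intervals, so
the table is built in extended precision and each entry is clipped to its
analytic range `[0, ln(width)]`.

A property worth knowing: on spiky histograms Kapur's criterion can prefer
a *degenerate* split that leaves one class empty, because merging two
narrow modes into one class raises total entropy (two deltas: any
separating threshold scores 0, while an empty class plus the merged pair
scores `ln 2`).  The exhaustive search and the raw objective report this
faithfully.  For segmentation, where an empty class is useless, the
threshold search subtracts a penalty of `(n+1)·ln L` per empty class, which
no entropy gain can offset; the reported objective value is always the
unpenalized one.

## Mayfly optimization

The swarm holds equal male and female populations (default 20 + 20, 100
iterations).  Moves follow `loc ← loc + velocity` with sex-specific
velocity rules; the stated source gives only the position update and the
mating equations, so the velocity updates follow the canonical mayfly
algorithm:

- non-best male: `v ← g·v + a1·e^{−β r_p²}(pbest − x) + a2·e^{−β r_g²}(gbest − x)`
- best male (nuptial dance): `v ← g·v + dance·U(−1, 1)`
- female, paired by rank: toward her male if he is fitter
  (`a3·e^{−β r_mf²}`), else a random walk of amplitude `fl`.

Defaults: `a1 = 1.0, a2 = a3 = 1.5, β = 2, g = 0.8, dance = 5, fl = 1`,
dance/walk damped by 0.99 per iteration.  All are configuration, not code.
The attraction distances `r` are measured in box-normalized coordinates
(divided by each dimension's bound width); without this the visibility term
`e^{−β r²}` underflows on wide domains such as the gray range `[1, 255]`
and distant agents never move.  The dance and random-walk amplitudes remain
in absolute units.

The top half of the ranked male/female pairs mate each generation; children
are convex combinations with mixing weight `P ~ N(0.5, 0.1)` truncated to
`[0, 1]` (truncation keeps children on the segment between their parents).
Children replace the worst-ranked agents of each sex with zeroed
velocities.  The global best is a monotone record over male evaluations, so
elitism holds by construction, and everything is driven by one seeded
generator: traces are bit-reproducible.

Thresholds are searched in a continuous box `[1, L−1]^{n−1}`; a position
decodes by sort → round → clamp → resolve duplicates upward (walking down
when clipping at the top re-collides).  On 256-bin histograms with all bins
populated, the swarm reaches the exhaustive optimum at the default budget
essentially always; on histograms with wide zero plateaus the landscape
develops near-ties and the match rate drops — the acceptance checks
therefore use fully populated random histograms.

## Segmentation and metrics

`segment` builds the histogram, optimizes thresholds (with the empty-class
penalty), maps pixels to classes, and picks the tumor-candidate class as
the non-background class whose mean intensity lies farthest from the global
foreground mean — tumors here are hyper- or hypo-intense relative to
tissue.  The mask is that class's largest 8-connected component.  An image
with a single gray level yields an empty mask flagged `degenerate`.
Default `n_classes = 4`; the phantom studies use 5 (one class per intensity
population: background, three tissues, tumor).

Overlap metrics are the Tanimoto coefficient `|A∩B| / |A∪B|` (identical to
the Jaccard index) and the Dice overlap `2|A∩B| / (|A|+|B|)`; both are
defined as 1 when both masks are empty, and `TC ≤ DOI` always.  Mask area
is `n_pixels × pixel_area` with `pixel_area` supplied by the caller.

## Feature extraction

**HOG.**  Gradients come from central differences (one-sided at borders);
magnitude `√(i_x² + i_y²)`, orientation folded to the unsigned range
`[0°, 180°)`, with vertical gradients at 90° and zero-magnitude pixels at
0° with zero weight.  Per 4×4-pixel cell, a 9-bin magnitude-weighted
orientation histogram with linear interpolation between the two nearest
bin centers (wrapping across 0°/180°).  Blocks of 2×2 cells advance with a
4-pixel stride (one cell) and are L2-hys normalized (L2, clip at 0.2,
renormalize).  Images are resized to 32×32 before extraction, giving 7×7
blocks × 36 values = 1764 raw dimensions.  The emitted descriptor is
**fixed at 1236 dimensions** by truncation (or zero-padding for smaller
layouts): the published configuration states the feature count but no
standard cell/block layout reproduces exactly 1236 (it is divisible by
neither 9 nor 36), so the count is enforced as an interface contract
rather than derived from geometry.

**Residual embedding.**  A small pre-activation residual network in plain
numpy: the input is resized to 32×32, contrast-normalized, and tiled across
all channels by a parameter-free stem; each of the 3 blocks computes
`x + W₂ * relu(norm(W₁ * relu(norm(x))))` with 3×3 convolutions (im2col +
BLAS) and an identity shortcut; the embedding is the global average pool
(64 channels = 64 dimensions).  With every convolution weight zero each
block is exactly the identity — the pre-activation property the tests
assert.  Default weights are seeded He-scaled Gaussians: an untrained
random convolutional embedding is a fixed, spatially structured random
projection, which is sufficient for the phantom classes and keeps the
package free of any downloaded weights; a `.npz` weight file can be loaded
for users who have trained one.

## Fusion and selection

Fusion is concatenation, deep embedding first: `P = m + D` (64 + 1236 =
1300 at defaults).  Each feature is scored by the Shannon entropy of its
empirical distribution; the default probability model is a 16-bin histogram
of the feature across the batch (a constant feature scores exactly 0; an
alternative softmax-over-sample model is provided).  Scores carry a
configurable normalization constant (default 1).  The top `select_n = 1126`
features are kept in their original order, ties toward the lower index;
selection is idempotent and the selected index set fitted on the training
batch is reused verbatim for every later sample.

## BiLSTM classifier

The selected vector is zero-padded and reshaped into 100 steps of
`ceil(1126/100) = 12` values.  Forward and backward LSTMs (100 hidden units
per direction, forget-gate bias 1) run over the sequence; their per-step
outputs are concatenated (width 200), max-pooled over time, passed through
a 50-unit ReLU layer with dropout 0.5, and a softmax output over the 3
classes.  Softmax (not per-class sigmoids) because the classes are mutually
exclusive and the probabilities must sum to 1.  The network and its exact
backward pass (BPTT, max-pool gradient routing, inverted dropout) are
implemented directly in numpy and verified against finite differences.

Training: cross-entropy, Adam with learning rate 0.001 and batch size 32,
default 60 epochs; shuffling and dropout use one seeded generator, so
training is deterministic.  Evaluation reports the confusion matrix,
macro-averaged one-vs-rest precision/recall/F1, accuracy, and the mean
one-vs-rest ROC AUC computed by the rank (Mann–Whitney) statistic with
half-credit for ties.

## Phantom generator

Each phantom is a 256×256 uint8 image: an elliptical brain (axes 0.42/0.36
of the side) of three concentric tissue bands with means (80, 120, 160) and
within-tissue σ = 6, on a background at level 0, plus additive Gaussian
pixel noise σ = 4 clipped to [0, 255].  One tumor blob is placed per image;
its shape, location and intensity encode the class label:

| label | name             | shape             | location      | intensity |
|-------|------------------|-------------------|---------------|-----------|
| 0     | pituitary-like   | disc              | lower-central | 250 (hyper) |
| 1     | glioma-like      | lobed (3 discs)   | upper-left    | 205 (hyper) |
| 2     | meningioma-like  | elongated ellipse | upper-right   | 40 (hypo) |

Tumor radii are drawn from [10, 16] px.  Every tumor level sits at least 40
gray levels (the `contrast_margin`, ≈ 5.5 combined σ) from every tissue
mean and from the other class levels, so the tumor occupies its own
histogram mode and the classes remain separable by intensity alone.  The
label names are geometric stand-ins, not clinical claims.  Datasets are
balanced by construction, with per-sample seeds spawned from a master seed.

What the phantoms do *not* emulate: Rician MRI noise (the additive
Gaussian model is a simplification), partial-volume effects, bias fields,
anatomical texture, multi-focal or infiltrative tumors, and scanner
variability.  Passing tests demonstrate that the pipeline's machinery is
correct and that it recovers and classifies well-separated lesions; they
say nothing about performance on clinical MRI.

## Problem sizes and numerical choices

The study configuration is deliberately desk-scale: 20 seeded phantoms for
segmentation recovery, 150 training / 60 test phantoms (50/20 per class)
for the classification study, 20 seeded histograms per oracle-equivalence
check.  Oracle equivalence is asserted at 1e−9 on the objective;
histogram/entropy identities at 1e−10; the HOG binning oracle at 1e−8.
Degenerate inputs: single-gray-level images segment to an empty mask with
a warning flag; constant features score zero entropy; zero-mass classes
score zero entropy; an empty mask pair scores TC = DOI = 1.

## Known limitations

- Kapur's criterion itself (not this implementation) is biased toward
  balanced-entropy splits and can behave oddly on sparse or spiky
  histograms; the empty-class penalty removes only the degenerate-split
  mode of that behavior.
- The residual embedding is untrained by default; its discriminative power
  on real images would come from trained weights, which the package loads
  but does not ship.
- The fixed 1236-dimension HOG contract discards a fixed suffix of the raw
  descriptor at the default layout; the discarded blocks are the
  bottom-most image rows.  Cell geometry is configurable when that
  matters.
- The BiLSTM is numpy on one CPU: adequate for thousands of desk-scale
  samples, not for training at clinical scale.
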