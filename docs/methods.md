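# Methods

## Circle geometry

Two circles with radii R ≥ r at center distance d fall into three regimes:
disjoint (d ≥ R + r, overlap 0), containment (d < R − r, overlap πr²), and
the lens (R − r ≤ d < R + r), where the overlap is
`θR² + φr² − ½R²sin2θ − ½r²sin2φ` with `θ = arccos((R²+d²−r²)/2Rd)` and
`φ = arccos((r²+d²−R²)/2rd)` — θ and φ are the half-angles subtended at each
center by the chord through the two intersection points. IoU is
overlap/(πR² + πr² − overlap), which reduces to (r/R)² under containment.

Numerical choices. The arccos arguments are clamped to [−1, 1]: near
tangency the rational expressions drift outside the domain by a few ulps and
would otherwise return NaN. The regime tests use `d < |R − r|` for
containment and `d ≥ R + r` for disjoint; exactly on a boundary the lens
formula is used and is analytically exact there (its value is continuous
across both boundaries, verified to 1e−9 in the tests). Degenerate circles
(r = 0) are defined to have IoU 0 — including two coincident points — so
that NMS and matching never divide by a zero union. Coordinates are
continuous pixels, origin top-left, y down; nothing in the geometry snaps to
integers.

## Non-maximum suppression

Plain greedy NMS: select the highest-confidence remaining detection, emit
it, delete every remaining detection with IoU ≥ λ against it (≥, not >),
repeat. Ties on confidence break toward the lower original input index,
which makes the output a deterministic, permutation-invariant function of
the detection *set*. λ defaults to 0.5, the community default for
single-class suppression; the tests compare against an independent
list-scan reference on a thousand random instances. Class-agnostic by
default (the motivating task has one class); a per-class switch exists.

## Anchor clustering

Anchors are clustered from ground-truth box dimensions with Lloyd k-means
under the distance `1 − IoU` of concentrically placed boxes — for circles
`1 − (min(r,r′)/max(r,r′))²`, for rectangles one minus the concentric area
ratio. Centroids are updated as the arithmetic mean of member dimensions
(the YOLOv2 recipe), initialization is k-means++ under the same distance,
empty clusters are re-seeded from the worst-fit point, convergence is
stable assignments or 300 iterations, and the best of `n_restarts`
seedings by mean best IoU is kept (default 10; the objective is non-convex
and single runs can land in poor local optima). Anchors are sorted by area
and split into three equal groups; the smallest third serves the
finest-resolution detection scale, the YOLOv3 convention. Default k = 9.

## Decoding, targets, loss

Per grid cell (offset cx, cy from the image top-left, in cells) and per
prior radius pr, the raw prediction (tx, ty, tr) decodes as
`x̂ = σ(tx) + cx`, `ŷ = σ(ty) + cy` (grid units, scaled by the stride to
pixels), `r̂ = pr·e^{tr}`; confidence and class probabilities are sigmoids.
Encoding is the exact inverse; a ground-truth center exactly on a cell edge
is nudged inward by 1e−6 cell units to keep the logit finite.

Each ground truth occupies exactly one (scale, cell, anchor) slot: the
anchor with the highest concentric IoU to its radius fixes the scale, the
cell containing its center fixes the position. Slot collisions are resolved
last-writer-wins with a logged warning. Three scales with 3 anchors each,
strides 8/16/32 at a 416-pixel input.

The loss is the sum of λcoord-weighted squared errors on the decoded center
(grid units) and radius (pixels) at object slots, binary cross-entropies on
confidence at object and no-object slots (the latter weighted λnoobj), and
per-class binary cross-entropy at object slots; λcoord = 5, λnoobj = 0.5.
Probabilities are clipped to [1e−7, 1 − 1e−7] before logs. Design choices
where the convention is genuinely open: the coordinate terms operate in
*decoded* space (the loss is conventionally written in the decoded symbols,
and this keeps the radius term in pixels); the confidence target is binary
C = 1 at the responsible slot (the no-object term −(1−C)log(1−Ĉ) presumes
it); the radius term is left unnormalized, with scale imbalance accepted;
no ignore-region refinement — the object/no-object partition is strict. An
analytic gradient of the whole loss with respect to every raw head value is
provided and is checked against central finite differences at 1e−4 relative
tolerance, which guards the σ/exp decode chain.

## Evaluation metrics

Matching is greedy in non-increasing confidence order: a detection claims
its best-IoU unmatched ground truth if that IoU ≥ 0.5 (the threshold is a
flag; 0.5 circle-IoU is the default), else it is a false positive;
unclaimed ground truths are false negatives. Greedy matching has the prefix
property — the top-k matches do not depend on lower-ranked detections — so
one pass yields the whole precision–recall sweep by cumulative sums. Over
multi-image sets, matching is per image and the sweep pools all
detections. AP uses all-point interpolation: `p_interp(r) = max precision
at recall ≥ r`, integrated over the distinct recall levels. F1 is the
harmonic mean of recall and precision, reported as 0 (with a warning) when
both vanish.

The paired-comparison protocol resamples 30 random 80-image subsets
(without replacement within a subset, independent across subsets), computes
AP per subset for each detector, and applies a two-sided Wilcoxon
signed-rank test at α = 0.05: zero differences dropped, mid-ranks for tied
absolute differences, exact null by enumerating all 2ⁿ sign patterns for
n ≤ 12 effective pairs, normal approximation with continuity correction and
tie-corrected variance above.

## Synthetic scenes

The generator emulates what a fruit-detection pipeline sees, not what a
camera sees: 256-px scenes with 4–8 quasi-circular fruits, log-normal radii
(median 18 px, σ_log 0.25 — plausible for greenhouse fruit at working
distance), moderate deliberate overlap (probability 0.3, with center
distances kept above 0.75 of the radius sum so the pairwise IoU of distinct
fruits stays below the 0.5 suppression/matching threshold), elliptical leaf
occluders over half the fruits sized to cover ~0.6 of the disc, and two
per-scene illumination regimes (bright/high-contrast vs dim/low-contrast,
probability ½ each). Ground truth is amodal: the circle covers the full
fruit extent even when hidden. Occlusion tags are measured from the
rendered masks (severe when > 50% covered), not assumed from the occluder
placement.

Detection noise is planted, so the evaluation stack can be validated
against known rates: each ground truth is missed with probability
`miss_rate`, survivors get Gaussian center jitter (σ 1.5 px) and log-normal
radius jitter (σ_log 0.05), with confidence decreasing in the jitter
magnitude so precision–recall curves are non-degenerate; false positives
arrive as Poisson(fp_rate·n_gt) random circles with low-skewed
confidences. What this does *not* emulate: real image statistics, texture,
color, confusable background objects, or a detector's correlated errors —
passing the loop shows the geometry/NMS/metrics chain is correct and
unbiased, not that any real detector reaches these numbers. Because jitter
occasionally drives a detection below the matching threshold, recovered
recall sits a few tenths of a percent below the planted survival rate;
tests use binomial confidence intervals around the planted values.

Augmentation follows the training-time policy: with probability ½ keep the
original image, otherwise scale by Uniform[1.15, 1.25] (bilinear) and crop
a random patch of the original size; then flip horizontally with
probability ½. Circles transform affinely; a ground truth whose center
leaves the crop is dropped, one whose center stays is kept even if cut
(standard practice; the alternative — dropping on any cut — discards most
large objects).

## Architecture validation

The backbone is described as a declarative graph, never executed: five
dense blocks of 6/12/24/16/16 layers, each layer a 1×1 bottleneck (4× the
growth rate, DenseNet convention) followed by a 3×3 convolution on the
concatenation of the block input and all previous layers' outputs — hence
L(L+1)/2 direct feature connections per block, which the validator counts
from the concat edges. Transition layers (1×1 conv halving channels,
stride-2 downsampling) sit between consecutive *blocks*; growth rate
defaults to 32 and the transition compression to ½ (DenseNet defaults,
configurable — these are open parameters of the design). Detection branches
hang off the last three blocks with deeper-to-shallower 1×1-conv + upsample
+ concat routing; each branch has exactly two convolutions before a 1×1
detect convolution with `n_anchors × (4 + n_classes)` output channels —
one channel fewer per anchor than a rectangular head, since a circle needs
(tx, ty, tr, conf) only. Parameter counting is k²·in·out per convolution
plus 2·out per batch-norm.

## Problem sizes in tests

The test and acceptance runs use the sizes the properties need, kept
deliberately modest: 10⁶-sample Monte-Carlo oracles over ~500 circle pairs,
1000 random NMS instances of up to 50 detections, 300 ground truths for
anchor recovery, 1000 encode/decode round trips, and a 200-scene (~1200
ground truths) end-to-end loop — large enough that binomial intervals
around the planted rates are a percent or two wide. One statistical note:
with ~500 independent Monte-Carlo comparisons, per-pair |z| > 3 events are
expected ~1.35 times by chance, so the geometry suite asserts the ensemble
(≥ 99% of pairs within 3 SE, none beyond 5 SE) rather than an all-pairs 3σ
bound that a correct implementation would fail a third of the time.

## Known limitations

- No training or tensor execution anywhere; the architecture module is
  bookkeeping only, and the loss/gradients serve validation, not learning.
- The synthetic renderer is deliberately crude (discs, ellipses, smoothed
  noise); conclusions about real imagery require real data.
- Circle IoU assumes exactly circular ground truth; elliptical or rotated
  shapes are out of scope.
- The Wilcoxon normal approximation is used above 12 effective pairs; at
  the protocol's n = 30 its error against the exact null is negligible
  (checked at n = 12 to within 0.02).
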