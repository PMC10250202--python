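# Methods

This note documents the models and procedures implemented in
`embryoscreen`, the parameters that matter, the synthetic data the tests
rely on, and the design choices made where the design was genuinely open.

## Problem setting

Fish embryos develop in the wells of a microtiter plate under time-lapse
bright-field imaging (one image per well per timepoint; the emulated
regime is 720 frames at 120-s intervals, i.e. a 24-h window starting
around 2 h post-fertilization).  Perturbing a signalling pathway produces
a characteristic morphological defect that becomes recognisable only
after a class-specific onset time; before that, all embryos look alike
(`unknown`), and any embryo may die (`dead`) and never recover.  The
pipeline assigns each embryo, per frame, one of a configurable set of
phenotype labels and aggregates wells into screen calls.

## Detection

Embryos in their chorion are near-circular, so detection is a circular
Hough transform: Canny edges (σ = 2 px) on the unit-range grayscale frame,
an accumulator over radii `r_min..r_max` in 2-px steps (these bounds are a
per-experiment acquisition parameter, not a learned quantity), candidate
peaks above a normalized accumulator threshold (default 0.30), and greedy
non-maximum suppression at a minimum center distance (default `r_min`),
highest score first.  Scores are accumulator counts divided by the full
circumference support, hence comparable across radii and bounded by 1.
Because the detector works on gradients it is invariant to constant
intensity offsets.  The detector sits behind a one-call interface so a
different detector (e.g. watershed segmentation for non-spherical
species) can be swapped in by configuration.

Crops for classification are squares of side `2r(1 + m)` centred on the
detection (margin m = 0.25 by default), median-padded at frame borders and
resampled to the classifier's input size.

## Tracking

Embryos barely translate, so appearance features are unnecessary:
tracking is motion-gated assignment.  Each live track predicts its next
position with a constant-velocity model; predictions are matched to
detections by Hungarian assignment on a (1 − IoU) cost over the circles'
bounding squares, gated by IoU ≥ 0.1 **or** center distance ≤ the
smallest live radius.  Unmatched detections seed new tracks; a track
unmatched for more than `max_age` = 5 consecutive frames terminates and
is never resurrected (no re-identification); tracks shorter than
`min_track_length` = 10 detections are dropped.  The age and length
defaults are this package's own (the behaviourally important contracts —
gap tolerance, no merging — are fixed; the numbers are configurable).
Determinism: tracks are processed in id order and cost ties resolve to
the lower track id.

## Class taxonomy and time conditioning

Default base classes, in normative order: `unknown, normal, dead,
bmp_lof, nodal_lof, ra_gain, wnt_lof, fgf_lof, shh_lof, pcp_lof`.  The
BMP and Nodal loss-of-function classes carry severity tiers
weak/intermediate/severe (≈30/60/100 % penetrance), giving 14 flat labels.
`cut` (partially visible embryo) is excluded from training, prediction and
metrics.  Developmental time in h.p.f. maps linearly onto τ ∈ [0, 1]
between anchors t₀ = 2 and t₁ = 26 h.p.f., clamped outside — clamping is
this package's choice for out-of-range times; the intended experiments
stay inside the window.  Severity is modelled as tiers *of* a base class
(not independent classes) so the transition logic can reason at base-class
level.

An annotation-shift utility moves each track's phenotype onsets a fixed
number of frames earlier (floored at frame 0; `dead` and `cut` untouched),
the retraining trick for earlier-than-eye detection; 120 frames at the
default interval is exactly 4 h.

## Classifier

Input is a 4-channel raster: RGB (grayscale replicated when needed) plus a
constant plane holding τ; τ is also concatenated to the pooled feature
vector entering the final fully connected layer.  Two backbone presets
share this contract:

* `tinycnn_timed` — four conv(3×3)/ReLU/max-pool stages (12/24/48/64
  planes), global max pooling, dense head.  The desk-scale backbone: it
  trains on one CPU in minutes at 64-px input.
* `resnet18_timed` — a ResNet18-style residual network (7×7 stem, four
  stages of two basic blocks, 64→512 planes) for larger runs.  Plain
  conv+bias residual blocks, without batch normalization: at the batch
  sizes and depths exercised here it trains stably, and omitting
  normalization keeps the engine small and exactly reproducible.

The network engine is a compact numpy implementation (im2col convolutions
on BLAS, explicit backward passes, Adam) written for this package; a
numeric gradient check is part of its development history and the test
suite exercises forward/backward of both presets.

Training: softmax cross-entropy L = −(1/n) Σ ln pᵢ (pᵢ floored at 1e−12 to
avoid −∞; L = 0 exactly iff every true-label probability is 1).  Class
balancing resamples every class to the **median non-unknown class count**
(the overrepresented `unknown` is subsampled without replacement, minority
classes are replicated with a seeded random remainder).  The progressive
schedule divides training into steps; each step can add data fraction and
augmentation groups, resets the learning rate to its initial value
(default 1e−3) and decays it ×0.1 after every epoch.  Full-scale defaults
are 8 steps / 152 epochs at batch 350; desk-scale runs use 2 steps × 3
epochs at batch 32 — chosen as the package's standard small-CPU
configuration.  "Iteration" for the learning-rate reset is read as *step*
(matching the progressive design), not batch.  Augmentation groups:
horizontal flip, vertical flip, rotation (uniform over 1°–90° in 1°
steps), random crop (75–100 % side, resized back), salt-and-pepper noise;
one random member of each enabled group is applied per example; all
randomness flows from the single training seed.

Test-time augmentation averages class probabilities over the eight
symmetry variants of the crop — the full dihedral group of the square,
realised as the four 90°-rotations of the crop and of its horizontal
mirror, each element exactly once.  (Enumerating "identity, h-flip,
v-flip, diagonal transpose, each also rotated 90°" literally produces
duplicates — rot90 of the transpose equals the vertical flip — so the
implementation enumerates the group directly; rotation/mirror invariance
of embryo appearance is the premise either way.)  The timestamp plane is
constant and unaffected by the spatial transforms.  Per frame, the embryo
is assigned the argmax class, ties broken by taxonomy order.

## Transition logic

A valid track history is piecewise constant with at most three segments:
`[unknown) [X) [dead)` where X is one phenotype class or `normal`, any
segment possibly empty; forbidden transitions are excluded from the search
space outright rather than finitely penalized (the search-over-valid-
candidates reading).  The corrector selects, over all X and change points
0 ≤ t₁ ≤ t₂ ≤ T, the candidate minimising the number of frames whose raw
argmax label disagrees with it; outliers are replaced by the model label.
Ties break by fewer transitions, then later first transition, then
taxonomy order of X, then (deterministic completion) larger t₁, larger t₂.
The scan is O(T·C) via prefix sums with a running late-preferring argmax;
an exhaustive O(T²·C) oracle is kept for verification and the two are
fuzz-tested to exact agreement.  An optional probabilistic cost
Σₜ (1 − pₜ(candidateₜ)) is available behind a flag but is not the default.
Severity tiers are collapsed to base classes before the search; the final
tier is the modal tier among tiered raw frames inside the phenotype
segment, ties resolving toward the more severe tier.  A `no_unknown` mode
pins t₁ = 0 for species imaged from stages where phenotypes are already
distinguishable.

## Class activation maps

The classification head is linear in the globally pooled feature planes,
so the spatial evidence map for class c is mapᶜ(x, y) = Σₖ w₍c,k₎ fₖ(x, y),
with the τ weight excluded from the projection.  (The map formula itself
involves no pooling; which pooling the classifier head uses — max by
default — is an independent config choice.)  All class maps of a crop are
normalized by one shared affine transform sending the global min/max to
−1/+1 (a constant map set degenerates to all zeros), remapped by
Ṽ = sgn(V)·√|V| — taking √ of |V|, since a square root of a negative value
is undefined and the sign factor indicates the intended magnitude — and
rendered to 8 bits (−1 → 0, +1 → 255, round-half-up so 0 → 128) with the
jet colormap, bilinearly upsampled.  Normalization is per frame across
classes.

## Metrics and baselines

Subset accuracy is the fraction of exactly correct labels; per-class
precision/recall/F use one-vs-rest counts with F = 2PR/(P+R) and the 0/0
case defined as 0; macro-F averages over classes present in the truth
vector.  Displayed confusion matrices exclude `unknown` while the overall
metrics include it; both are reported.  The random-guessing baseline
assigns each of n images a label drawn uniformly from n_c candidates; its
mean accuracy converges to 1/n_c regardless of the truth distribution
(with n_c = 11 and n = 98 this is 9 % to the nearest percent).  The
generator is seeded numpy; only the distribution, not any particular
pseudo-random stream, is reproduced.

## Synthetic phantoms: what they do and do not show

The phantom renders each embryo as a disk (dark rim, flat interior) that
is class-neutral before its onset frame, carries a class-specific
geometric motif afterwards, and collapses to a low-contrast speckle from
its death frame.  Motifs are deliberately geometric stand-ins — bright or
dark rings, blobs, spot pairs, stripes, dots — chosen so that every class
differs from every other by rotation/mirror-invariant structure and
polarity, never by orientation alone (embryos lie in random poses and TTA
averages over the dihedral group, so an orientation-only class would be
ill-posed, exactly as it would be for real embryos).  Severity tiers scale
motif contrast by 0.3/0.6/1.0.  Disks never overlap at generation time
(rejection sampling; infeasible packings raise before rendering), drift is
a small clamped random walk (default ≤ 1 px/frame), and Gaussian
(σ = 0.02) plus salt-and-pepper (0.5 %) noise is applied after rendering.
Defaults follow the emulated regime — 720 frames × 120 s — with geometry
at a 512-px frame (a quarter of the emulated 2,048-px sensor) carrying
radii 28–42 px and 3–10 embryos per well; denser packings are possible at
larger frame sizes.  A template-correlation oracle classifier achieves
100 % on noise-free renders after onset, which the tests assert — this is
the sense in which classes are separable *by construction*.

Consequently, passing tests show that the pipeline's machinery is correct
(detection geometry, identity maintenance, learnability of separable
classes, cost-minimal correction, metric arithmetic); they do not show
that any particular CNN reaches any particular accuracy on real embryo
images, which depends on data the phantom does not model (chorion and
yolk texture, optics, debris, touching embryos, biological variability).

## Problem sizes used by the test suite

Unit tests run on 128–256-px frames with 1–30 frames per well.  The
end-to-end check trains `tinycnn_timed` on 5,000 labelled 64-px crops
(six labels including `unknown`; 2 steps × 3 epochs, seed 7), evaluates
held-out crops with TTA, then runs the full
detect→track→classify→correct chain on four held-out 40-frame phantom
wells; correctness bars are ≥ 0.85 held-out per-frame accuracy and
≥ 0.90 corrected per-track final-class accuracy.  Detection/tracking
suites run across 20 phantom seeds; the corrector-vs-oracle fuzz uses
1,000 random sequences with T ≤ 60.

## Known limitations

- No appearance embedding in tracking: two embryos drifting into contact
  can swap identities; the phantom's drift keeps this rare, as do real
  embryos' near-stationarity.
- The Hough detector slightly underestimates radii (edges sit on the
  rim's inner boundary); crops absorb this via the pad margin and the
  training-crop radius jitter.
- No batch normalization in the residual preset; very deep training at
  scale would likely want it.
- Dead embryos are rendered as a deterministic low-contrast texture, not
  actual disintegration dynamics.
- One phenotype segment per track: combinatorial (multi-pathway) labels
  are out of scope.
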