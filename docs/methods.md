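# Methods

This note documents the models, numerical choices, and the synthetic data
this package is validated on, including what passing tests do and do not
establish.

## Patient-wise stratified splitting

The unit of allocation is the patient, never the image: bilateral knees
share anatomy, acquisition and habitus, so image-level splits leak
patient-specific cues and inflate agreement metrics. Each patient's
stratum is their maximum KL grade across images. The split is two-stage:

1. Hold out ⌈(f_val + f_test)·N⌉ patients; train keeps the remainder.
2. Split the holdout into test = ⌈holdout·f_test/(f_val+f_test)⌉ and
   val = the rest.

Within each stage, per-stratum counts come from largest-remainder (Hare
quota) apportionment against the fixed global partition sizes, and
patients are drawn by a seeded shuffle inside their stratum. This keeps
every stratum within ±1 patient of the target fractions while making the
global partition sizes exact and deterministic. With 70/15/15 the rule
gives 2891/619/620 patients for a 4130-patient bilateral cohort and
1606/344/345 images for a 2295-patient single-image cohort. Note the
ceiling lands on *test*; a rule with the ceiling on val instead would give
620/619 — the two conventions differ by a single patient and nothing else
in the pipeline depends on the choice. Integer quotas are rounded to 9
decimals before the ceiling because binary floating point can place
0.15 + 0.15 a hair above 0.30, which would otherwise bump an exact quota
to the next integer.

`assert_no_leakage` re-verifies every split exhaustively (zero patient
intersection, bilateral co-assignment) and is run by the splitter itself,
by the CLI, and before training.

## Preprocessing

Letterbox bars from image export are trimmed by scanning border rows and
columns inward while a line is ≥99.5% near-black (<8) or near-white
(>247), never reducing an axis below 50% of its original extent. Trimming
is per-side and line-by-line, so ragged bars are handled; the operation is
idempotent. Images are then bilinearly resized to S×S, replicated to three
channels, and normalized with the conventional ImageNet statistics
(means 0.485/0.456/0.406, SDs 0.229/0.224/0.225).

Training augmentation samples one realization per image — horizontal flip
(p = 0.5), rotation ±8°, resized crop (scale 0.88–1.0, aspect 0.9–1.1),
brightness/contrast jitter ±0.08 — in the fixed order flip → rotate →
crop → jitter → normalize (the order is a documented implementation
choice). The midline patches are cut *after* the global augmentation, so
all three streams see the same realization; cutting before would
decorrelate the views. Augmentation is a hard error at eval time. TTA uses
8 deterministic views (identity first, then flip, ±3°, ±5°, ±7°); TTA = 4
is defined here as identity, flip, ±5° — the smaller budget's composition
is a package convention, not an established one. Rotations use bilinear
resampling with black fill.

## Architecture

Encoders satisfy a minimal contract — 3×S×S batch in, feature vector or
D×h×w map out, last spatial activation exposed for Grad-CAM — so the
method is independent of any particular backbone. The bundled encoders are
three-block strided conv stacks (<1M parameters) appropriate for CPU-scale
experiments; the large pretrained backbones of production-scale systems
(ConvNeXt-Base, ResNet-50, NFNet-F4) exist as named configuration stubs
that fail fast with a clear message, since no pretrained-weight dependency
is bundled. The entire network and its reverse-mode gradients are
implemented in NumPy (`klgrade.nn`); the end-to-end backprop is verified
against central finite differences in the test suite.

Design points that were genuinely open and are fixed here:

* Heads are linear with biases on the L2-normalized fused embedding.
* Dropout (p = 0.1) is applied once, before normalization.
* The patch streams share one encoder object; sharing is asserted by
  parameter identity, not value equality. The right patch is *not*
  mirrored before the shared encoder.
* Each GeM exponent belongs to its stream's backbone parameter group and
  is clamped to ≥1 after every optimizer step.
* Patch views are resized to the patch encoder's input size after the
  midline cut (default 224 at full scale, 32 in the desk-scale study).

Baseline configurations: `flat5c_global` (global stream only, one 5-class
softmax head trained with one-hot targets — plain cross-entropy) and
`dualhead4c` (both streams, KL0 and KL1 merged into one class, 4-class
head plus binary head). The Gaussian-smoothed distribution target belongs
to the multitask configuration only.

## Objectives

Ordinal targets t_k = 1[y > k−1] are nonincreasing in k and recover the
grade as Σt_k. The ordinal loss averages BCE over batch and the four
thresholds with optional multiplicative weights on the first and last
threshold, normalized by the weight sum; the defaults (both 1.0) reduce
exactly to the unweighted form. The distribution target is the Gaussian
kernel exp(−(c−y)²/2σ²) truncated to the five grades and renormalized
(σ = 1.0); the loss is KL(target ‖ softmax(logits)), the standard
label-distribution-learning direction, with 0·log 0 := 0. All BCE terms
use the overflow-safe log1p formulation. Every loss function returns its
analytic logit gradient; these are what the training engine backpropagates.

## Training

AdamW (β = 0.9/0.999, ε = 1e-8) with decoupled weight decay 1e-4 over two
groups: backbones at the base rate, heads at 2×. Linear warmup over 3
epochs, then cosine decay to zero at max_epochs (60). Early stopping
monitors validation QWK with patience 12. The weight EMA (decay 0.999)
updates every optimizer step; on each validation improvement both raw and
EMA weights are snapshotted, and at the end whichever scores the higher
validation QWK becomes the selected checkpoint (which of the two a
production run should report is genuinely ambiguous; selecting by
validation QWK is this package's documented resolution). Training
accuracy is logged from the distribution head's argmax — cutpoints do not
exist until after training. Validation QWK during training likewise uses
the distribution-head argmax; the tuned ordinal decoding applies only at
final inference.

Fine-tuning warm-starts from a checkpoint with **all** parameters
unfrozen, backbone/head rates 1e-5/5e-5, patience 5, at most 15 epochs,
and the same composite loss. Cutpoints are never carried across domains;
they are retuned on the target domain's validation split.

## Decoding and cutpoint tuning

A grade is the number of thresholds whose cumulative probability strictly
exceeds its cutpoint. The count rule (rather than "first failure") is
well-defined when independent sigmoids produce non-monotone probability
vectors, and is monotone: raising any cumulative probability never lowers
the grade. Ties at a cutpoint do not count as exceedance.

Tuning is coordinate descent from (0.5, 0.5, 0.5, 0.5) over a
0.01-resolution grid on [0.30, 0.70]: each proposed value projects its
neighbors to preserve nondecreasing order, moves are accepted only on
strict QWK improvement (ascending sweep order makes ties keep the lowest
cutpoint), and sweeps repeat until a full pass changes nothing. The result
never scores below the 0.5 start on its tuning data; on coarse grids the
suite checks it against exhaustive search over all nondecreasing grids.
Tuning on test-labeled inputs is refused outright, and the CLI stores a
hash of the tuning set in the checkpoint so `evaluate` can refuse the same
data later.

TTA aggregation averages probabilities (sigmoid/softmax per view, then
arithmetic mean), which keeps class probabilities on the simplex; raw
logit averaging is available behind a flag. Headline multiclass metrics
use the decoded ordinal grades; multiclass ROC/PR use the distribution
head's class probabilities; the KL≥2 ROC uses p2+p3+p4 from the same head;
the binary head's own sigmoid is logged but not used for headline metrics.

## Metrics and uncertainty

QWK uses quadratic disagreement weights w_ij = (i−j)²/(n−1)² on observed
vs chance-expected confusion counts; when both marginals degenerate on a
single class the statistic is defined as 1 for a perfectly diagonal table
and an error otherwise. Accuracy, MAE, per-class precision/recall/F1 and
macro-F1 are computed from one-vs-rest confusion counts; classes absent
from the truth are dropped from the macro average with a warning (classes
present but never predicted contribute F1 = 0). ROC/PR curves are
delegated to scikit-learn with trapezoidal AUCs; the macro AUC averages
classes with both outcomes present, the micro AUC pools decisions.

Confidence intervals are percentile bootstrap (B = 2000, 2.5/97.5) over
*patients*: each resample draws patients with replacement and a drawn
patient contributes all of its images, every time it is drawn. This
respects within-patient correlation; an image-level bootstrap would
understate the variance of bilateral cohorts. The percentile method (vs
BCa) is a deliberate simplicity choice.

## Grad-CAM

Heatmaps backpropagate the distribution head's argmax-class logit to a
stream's last convolutional activation; channel weights are the spatial
means of those gradients, the map is the rectified weighted channel sum,
min-max normalized to [0,1] (constant maps are defined as all zeros), and
bilinearly upsampled to the input. Maps are computed per stream with no
cross-stream fusion. Overlays alpha-blend a jet colormap at α = 0.35.
The gradient path never touches parameter gradients.

## Synthetic cohorts: what they are and are not

The generator emulates cohort *structure* and an ordinal image cue, not
anatomy. Rosters follow `{patient_id}{L|R}` naming; bilateral patients
draw their maximum grade from the cohort marginals (so the stratification
variable follows the marginals exactly) and the other knee uniformly from
0..max. Default marginals (0.394, 0.181, 0.263, 0.131, 0.031) reflect a
large screening population where grade 0 dominates and grade 4 is rare.
Images contain two bright bands separated by a dark gap of
`gap_base − grade·gap_step` pixels (laid down as an exact integer row
count so the noise-free cue is measurable to the pixel), 2·grade
osteophyte-like blobs, a sclerosis strip brightening with grade, Gaussian
intensity noise, and optional letterbox bars. The "external" domain shift
applies a fixed contrast scale (0.85), brightness offset (+25) and a high
letterbox probability (0.8) — exactly the kind of photometric scanner
difference that breaks naive transfer, and one that intensity-sensitive
features will feel.

Passing tests on these cohorts demonstrates that the pipeline's machinery
is correct (splitting, optimization, decoding, evaluation, adaptation)
and that the qualitative cross-site pattern — internal > zero-shot,
fine-tuned > zero-shot — emerges under a controlled shift. It demonstrates
nothing about clinical images: the synthetic cue is far easier than real
radiographic grading, so absolute agreement values here exceed what any
real system achieves and must not be compared to published clinical
numbers.

## Desk-scale study conditions

The reference experiment (`klgrade.experiments`) uses an internal
bilateral cohort of 300 patients (600 images) and an external single-image
cohort of 160 patients at 64×64, gap 18 px at grade 0 shrinking 3 px per
grade, noise SD 6. The tiny encoders train for 10 epochs at base rate
2e-3 with 2 warmup epochs — a randomly initialized small network needs a
larger step than a pretrained large one — and fine-tune for 8 epochs at
5e-4/2.5e-3, preserving the 1:5 backbone:head ratio of the full-scale
fine-tuning protocol. The cycle completes in well under a minute on one
CPU. With only ~24 external test images the external QWK carries
substantial seed-to-seed variance, and when zero-shot transfer already
performs near ceiling the fine-tuning gain can vanish into a tie; the
directional claims are therefore evaluated under the package's fixed
default seed rather than averaged over seeds.

## Known limitations

* Encoders are CPU-scale; no pretrained weights, so absolute performance
  on real radiographs is out of scope by construction.
* The synthetic severity cue is partly a brightness/area cue; models can
  exploit global intensity in ways real graders cannot.
* The cutpoint tuner is a local search; the suite bounds its gap to
  exhaustive search on coarse grids only.
* TTA = 4's transform set, the raw-vs-EMA reporting convention, and the
  percentile CI method are package conventions where the field has no
  single standard.
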