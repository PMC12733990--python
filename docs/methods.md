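# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Synthetic phantoms

Each phantom patient is one axis-aligned ellipsoidal kidney (semi-axes
roughly a third of the field of view, jittered ±8%) in a soft-tissue
background, with at most one pathology class per patient (configurable up
to three lesions). Voxel (i, j, k) sits at `(i, j, k) * spacing_mm`; the
default grid is 64×64×16 voxels at 1.0×1.0×2.5 mm — deliberately
anisotropic, matching clinical through-plane spacing — and a full
96×96×32 grid is available through the spec.

Tissue intensities are Hounsfield-like conventions chosen to reproduce
the qualitative radiology of contrast CT rather than any published
quantitative ranges (none exist for this cohort): background −80±20 HU,
enhancing parenchyma 110±15, cysts 10±8 (hypodense, sharply
circumscribed), stones 700±150 (calcification), and tumors a two-level
mixture of 60 and 140±20 arranged in smooth random patches
(heterogeneous enhancement). Tumor margins are irregularized by a
low-order real spherical-harmonic radius perturbation (orders 1–3,
amplitude 15–30% of the nominal radius). The tissue-mean map is smoothed
with a small Gaussian (0.7 voxel in-plane) so borders have partial-volume
softness; per-tissue noise and a global 5 HU noise floor are added
unsmoothed. Default lesion radii: cysts 5–10 mm, tumors 6–12 mm, stones
3–5 mm; a lesion whose full reach cannot fit inside the kidney with a
one-voxel margin raises a sizing error (drawn radii are clamped into the
feasible range when only the draw, not the spec, is infeasible).

The per-patient class assignment follows the cohort proportions of the
study population tables in `study_tables` (normal 0.407, cyst 0.303,
tumor 0.179, stone 0.110). Everything is a pure function of
`(spec, seed, patient_id)`: the per-patient stream is seeded by the spec
seed plus a SHA-256 digest of the patient id, so cohorts are reproducible
and order-independent.

What the phantoms do *not* emulate: scanner physics (beam hardening,
partial-volume streaks, bias fields), multi-organ anatomy, peri-renal
fat planes, lesion co-occurrence, and the intensity overlap between
complex cysts and cystic tumors that makes the real clinical problem
hard. Passing tests on phantoms therefore demonstrates that the pipeline
is implemented correctly and can learn separable 3D structure — not that
it reaches clinical accuracy on real CT.

## Preprocessing

Kidney windowing clips to level 40 ± width 400/2 HU, i.e. [−160, 240],
then rescales to [0, 1]. Resampling targets 1.0×1.0×2.5 mm (the stated
protocol triple, taken literally although it is anisotropic), trilinear
for images and nearest-neighbour for masks, with half-pixel-centre
sampling. Stacks shallower than 8 slices are brought up to 8 by a cubic
B-spline along the through-plane axis (endpoint-preserving sample
positions; the spline order drops below cubic only for stacks with fewer
than 4 slices, where a cubic is undefined).

The three-stage intensity normalization is (1) global z-score, (2)
recentering by the kidney-voxel mean/std when an organ mask is available
(skipped otherwise), (3) local standardization in sliding cubic patches
of side 16 with stride 8, mean-blending overlaps. The patch side and
blending rule are package choices — 16 divides every padded shape and
half-overlap keeps seams smooth. Stage 3 deliberately equalizes local
contrast for texture analysis; its side effect is that the interiors of
large homogeneous regions carry less absolute-intensity information,
which is why ROI patches for the classifier are cut from the *windowed*
image (stage 0 output), matching the ROI pipeline's own two-step
normalization (windowing, then patch z-score clipped to ±3).

Padding is symmetric zero-padding to the next multiple of 16 per axis
(extra voxel on the high side), with an exact inverse. Bias-field
correction is a configurable no-op hook: the phantoms carry no bias
field, and the external correction algorithm is out of scope.

## Segmentation network

The encoder stacks one Enhanced Convolutional Block per level over
channel widths (32, 64, 128, 256) by default; depth and widths are
configuration, since the source architecture does not pin them.
Downsampling is a strided 2×2×2 convolution; upsampling is trilinear
interpolation followed by a 1×1×1 projection (checkerboard-free).
GroupNorm uses min(8, C) groups, suiting batch sizes of 4–8. The 7×7×3
depthwise kernel keeps its through-plane extent 3 even at shallow depths
via symmetric padding.

ASPP dilation rates (1, 3, 6) are applied in-plane only, with
through-plane dilation 1: at desk scale the bottleneck is 2–4 slices
deep, which cannot support a rate-6 span through-plane; the per-axis
span precondition is enforced by the convolution. Weight initialization:
He-normal for depthwise kernels, Xavier-uniform for pointwise/dense
kernels, LayerScale 1e-6, zero biases, under the fixed model seed 123.

A configurable "patchify" stem (strided 3×3×3 entry convolution plus a
matching trilinear upsample before the head) lets the desk-scale
configuration — channels (8, 16, 32), expansion 2, stem stride
(2, 2, 1), ~114k parameters — avoid full-resolution block work. The
default configuration keeps stem stride 1.

## Segmentation objective

Weights are fixed at α=0.4 (CE), β=0.3 (Dice), γ=0.2 (boundary), δ=0.1
(focal), with focal exponent 2.0 and Gaussian smoothing σ=1.5 voxels on
the signed distance transform. CE and focal are voxel means with
probabilities clamped at 1e-7; Dice averages the four foreground classes
(background is excluded: it dominates the volume) with an additive
smooth of 1e-5, so classes absent from both prediction and target score
as perfect. Distances are measured in voxel units by default (a spacing
triple switches to millimetres); the signed transform is negative inside
the region and positive outside, and degenerate (empty/full) masks
return a flagged unsigned surrogate measured from the grid edge.

The boundary term exists in two forms. The *normalized* form,
`Σ_s φ_c(s) D_c(s) / Σ_s φ_c(s)`, is the distance-weighted mean of the
predicted class mass and is the default of the `boundary_loss`
operation. It is, however, invariant to the overall scale of φ_c, so a
gradient-based learner can minimize it by concentrating the class mass
at the distance minimum instead of covering the region — measured on a
single-phantom overfit, the foreground Dice stalls near 0.4 with the
ratio active and reaches 1.0 without it. Training protocols therefore
use the *integral* form `mean_s φ_c(s) D_c(s)` (the classical boundary
loss), selected by `SegLossWeights(boundary_form="mean")`; it rewards
mass inside the region (D < 0) and penalizes mass outside, complementing
the Dice term.

## Confidence and ROI extraction

Pixel confidence is `w1·max_c p + w2·(1 − H/ln 5) + w3·Consistency` with
w = (0.5, 0.3, 0.2) and 5 Monte-Carlo dropout passes. The entropy enters
as its normalized complement so that confidence *decreases* with
uncertainty; consistency is the fraction of passes agreeing with the
modal voxel-wise argmax. The weights and pass count are package defaults
(the formula's coefficients are not published).

Components use 26-connectivity with an inclusive minimum-volume
threshold (keep if ≥ 27 voxels), ordered by size descending then
lexicographic minimum voxel. Boxes grow by ceil(0.15 × extent) per side
(never losing context to rounding) in 0-based half-open coordinates.
Resizing to 96×96×32 is direct trilinear unless the per-axis scale
factors differ by more than 2×, in which case the crop is scaled
uniformly and zero-padded symmetrically. Region confidence S averages
three unit-interval terms: mean pixel confidence over the component;
mean probability-gradient magnitude over the component surface rescaled
by 0.5 (the central-difference response to a unit step along the
normal); and the component's share of the class's predicted mass inside
its expanded box. Patients with no surviving pathological component
yield one whole-kidney ROI routed to "normal".

## Classifier

Pathways use kernels 3×3×3 / 5×5×3 / 7×7×5 and channel schedules
(256, 512, 1024) / (128, 256, 512) / (64, 128, 256) at full scale —
inside the published ranges — with one Adaptive Convolutional Block per
stage and 2×2×2 strided downsampling between stages, ending in global
average pooling. The desk-scale configuration divides the schedules by
16 and uses strided stems ((4,4,2) / (3,3,2) / (2,2,1)), a size the
package chose so a complete cascade study runs in CPU minutes; other
scalings (e.g. /8) remain available through the config. The block-scale parameter α starts at 0.1
with a per-channel LayerScale at 1.

Fusion weights are a softmax over a two-layer transform of the pooled,
spatially-attended stream descriptors concatenated with the scalar
segmentation confidence S — the "context" conditioning is read as the
pooled multi-stream state, the only reading consistent with
confidence-aware fusion. Confidence-modulated scaling multiplies the
fused vector by `κ + (1 − κ)S` with κ = 0.5, so zero-confidence ROIs are
attenuated but still classified. The evidential head uses softplus
evidence (smooth, positive, bounded gradients; exponential and ReLU are
the obvious alternatives) with α = evidence + 1, guaranteeing α ≥ 1.

## Classification objective and adaptive weighting

The evidential term is the expected cross-entropy under Dir(α),
`Σ_k y_k (ψ(Σα) − ψ(α_k))` (the canonical digamma form; an MSE-style
Bayes-risk form would be the main alternative). The KL term regularizes
*misleading* evidence: the true-class concentration is reset to 1 before
the closed-form KL to the uniform Dirichlet. The confidence-alignment
term is `(u − (1 − S))²` — the uncertainty of the classifier should rise
when segmentation quality falls; no published formula exists, and the
squared alignment is the simplest coupling with that monotonicity. The
plain CE term operates on the Dirichlet mean (no separate softmax head).

Learning progress z_i is an EMA (momentum 0.9) of the relative one-epoch
decrease of each term, and λ = softmax(z/τ) with τ = 2.0, updated once
per epoch (per-step updates would make λ a function of batch noise).
λ is shift-invariant in z by construction.

## Training protocol

Full-scale defaults follow the published recipe: AdamW (β₁ 0.9, β₂
0.999, ε 1e-8, weight decay 0.01), gradient-norm clipping at 1.0,
segmentation 100 epochs at lr 1e-4 batch 4, classification 50 epochs at
5e-5 batch 16, linear warmup from 1e-6 over 5 epochs then cosine decay
to 1e-7, seeds 42 (split) / 123 (model init). Training runs in float32;
the test suite's gradient checks run in float64.

The desk-scale protocol (the one `scripts/acceptance.py` runs) keeps the
fixed study conditions — 120 phantom patients at 64×64×16, 70/15/15
split under seed 42, model seed 123, 5 segmentation + 10 classification
epochs, tiny networks — and chooses the free hyperparameters for a
~60–110-step budget: lr 3e-3, batches 8/8, warmup 1 epoch, dropout 0.05
in the tiny blocks. ROI batches are drawn class-balanced (uniform over
classes, with replacement, epoch length unchanged): stones are both the
rarest cohort class (~11%) and, after patch z-scoring, the most easily
confused with whole-kidney "normal" ROIs, and proportional sampling
starves them. Checkpoints are selected on the task metric — validation
foreground Dice for segmentation, validation accuracy for
classification — rather than validation loss: the compound objectives
(signed boundary integral, evidential regularizers) are not monotone in
the task metrics, and at desk scale the validation-Dice peak was
observed one epoch before the validation-loss minimum.

Classifier training in the desk study uses *oracle-mask* ROIs (patches
extracted from ground-truth masks with one-hot probabilities), isolating
the classifier's own discrimination ability from segmentation error; the
cascade inference path (predicted masks, MC-dropout confidence) is
exercised separately.

## Metrics

Dice from voxel counts; HD95 as the 95th percentile of the pooled
two-way surface distances (surface = region voxels with a 6-neighbour
outside, volume border included; distances spacing-scaled to mm);
boundary IoU on 1-voxel-dilated surface bands. Classes absent from both
masks score Dice 1 / HD95 0 / bIoU 1; classes absent from exactly one
side score Dice 0 / bIoU 0 with HD95 undefined (NaN, NaN-aware
averaging). Classification reports use zero-division-0 precision/recall,
rank-statistic one-vs-rest AUC, and a confusion matrix whose rows equal
class supports; AUC is reported as missing for classes without both
outcomes.

## Numerical layer

No deep-learning framework is used: `diagnext.nn` is a tape-based
reverse-mode autodiff engine over numpy arrays with exactly the
operations the networks need. Dense/strided/dilated convolutions use a
shift-and-contract decomposition (one channel-mixing contraction per
kernel offset); large depthwise kernels use real FFTs at circular sizes
≥ spatial + kernel − 1, where forward output, input gradient and kernel
gradient are all exact slices of circular correlations, with the forward
transforms cached for reuse in backward. Every primitive is checked
against central finite differences, and the FFT path against the shift
path. Python-scalar operands take a promotion-safe fast path so float32
training stays float32 end to end.

## Known limitations

- Phantom realism bounds what the end-to-end numbers mean (see above).
- The desk-scale cascade trains for minutes, not hours; its Dice
  (~0.6–0.8) and oracle-ROI accuracy (~0.9–1.0) characterize the
  implementation at that budget, not the method's ceiling.
- The normalized boundary ratio is retained as an operation but unused
  in training for the reason documented; revisiting it with a coverage
  safeguard (e.g. combining both forms) is future work.
- MC-dropout confidence uses 5 passes; calibration of S against true
  segmentation quality on phantoms has not been quantified.
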