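# Methods

## Problem and model

The package classifies AD vs CN from dual-phase amyloid-PET features: a
regional time-activity curve (TAC) from the dynamic early phase (a perfusion
surrogate) and a regional mean SUVr vector from the delay phase (amyloid
load). Either phase alone is an imperfect witness — amyloid reading and
clinical diagnosis disagree for a minority of subjects, and perfusion
carries noise of its own — so the classifier learns per-subject convex
weights over the two phase representations.

**Inputs.** Six cortical target regions (frontal, temporal, parietal,
occipital, anterior cingulate, posterior cingulate); the cerebellum is the
reference region. TAC: 6 regions × 27 frames, each frame's regional means
divided by that frame's cerebellar mean (per-frame normalization keeps every
column a proper SUVr and makes the features invariant to global intensity
rescaling; a global-normalization alternative would differ only by a shared
time profile). SUVr: 6 values, cerebellum-normalized. Both feature blocks
are min-max scaled per feature; the scaler is fitted on the training split
only and stored inside the trained model, and out-of-range values at predict
time are mapped affinely, not clipped, so the transform is invertible.

**Architecture.** Early encoder: 2 LSTM layers of hidden width D = 6, each
followed by layer normalization; the last time step feeds one FC layer with
the standard block (batch normalization → ReLU → dropout). Delay encoder:
4 FC layers of width 6, each with the standard block. First aggregation:
h′ = FC(concat(h_e, h_d)) followed by the standard block (the block on h′ is
optional via `aggregate_block`; the default keeps it, treating h′ like every
other FC output). Attention: for each phase i, x_i = concat(h_i, h′),
e_i = tanh(x_i W + b_i) with W ∈ R^{2D×1}, b ∈ R^{N×1}; a = softmax(e);
C = Σ a_i h_i. Head: 2-logit FC on concat(C, h′), softmax; the AD-class
probability is the positivity score. The attention weights are non-negative
and sum to one by construction, so C always lies in the convex hull of the
phase features — this is property-tested, not assumed.

**Training.** Cross-entropy against one-hot labels plus an L2 penalty of
0.01 on all dense/LSTM kernels (not biases or normalization parameters),
Adam, dropout 0.2, full batch by default (cohorts of a few hundred subjects
fit in one batch; `batch_size` is configurable). Early stopping keeps the
weights of the best validation-loss epoch with patience 200; after a
100-epoch plateau the learning rate decays along the plateau as
lr₀ / (1 + 0.001·k) (k = epochs past the plateau threshold; a one-shot
multiplicative mode is provided) and is restored on improvement. Weight
initialization is Glorot-uniform from the run seed; training is
deterministic given (data, seed). The classification threshold for
accuracy/F1/G-mean is 0.5, i.e. the argmax of the 2-node softmax.

The reference recipe (learning rate 1e-5, up to 10,000 epochs) is the
default `ModelConfig`. With full-batch Adam, 1e-5 moves each weight by about
1e-5 per epoch, so desk-scale runs in this package's tests and scripts use
the same recipe at lr = 1e-3 with max_epochs = 200–300 and proportionally
reduced patience — the stopping and decay semantics are identical, only the
step size and budget are scaled.

**Compute core.** The network runs on a package-internal reverse-mode
autodiff over float64 numpy arrays. Gradients (including backprop through
27 unrolled LSTM steps, both normalizations and the attention softmax) are
verified against central finite differences at 1e-5 precision in the suite.

## Relevance attribution

First-order Taylor attribution: r[g, t] = ∂f/∂x[g, t] · x[g, t], with f the
pre-softmax AD logit (post-softmax gradients vanish once the model is
confident; CN logit and AD probability targets are available). x is the
min-max-scaled TAC — the tensor the network actually consumes. Gradients
are exact, so the maps match a finite-difference oracle to 1e-4 relative.
Mean composites average over subjects first, then over regions (per-frame
profile) or over time (per-region profile).

## Synthetic cohort generator

The generator emulates the statistical structure of a dual-phase FBB study
and defines the conditions under which the package's claims are tested.

- **Early phase.** Each region's delivery is a gamma-variate bolus
  K·t^α·e^(−t/β) with mildly region-specific (α, β) so SUVr ratio curves are
  genuinely time-varying; frames follow a contiguous 27-frame schedule over
  1200 s (15 × 20 s + 12 × 75 s — the acquisition gives only the frame count
  and span, so the schedule is a package choice, configurable). AD scales
  target-region amplitudes by (1 − perfusion_effect): cortical
  hypoperfusion tied to the clinical diagnosis.
- **Delay phase.** Target-region SUVr = region baseline (≈1.05–1.20) +
  amyloid_effect for read-positive subjects + N(0, noise_sd). Uptake depends
  on the amyloid reading only, which is what makes the discordant subgroups
  (amyloid-positive CN, amyloid-negative AD) irreducible for a delay-only
  classifier: its ceiling on the reference composition is ≈0.81 AUROC.
- **Noise.** Two components share one scale: i.i.d. Gaussian noise per TAC
  cell / SUVr entry (sd = noise_sd), and a per-subject global perfusion
  amplitude factor with sd = subject_noise_scale × noise_sd shared across
  regions and frames. The second models between-subject biological
  variability; without it, frame-averaging would make the early phase
  near-perfectly separable at any i.i.d. noise level. Tying both to
  noise_sd keeps the zero-noise limit exact: noise_sd = 0 reproduces the
  group-mean curves identically.
- **Composition and cognition.** Stratum counts are exact (defaults 74 CN /
  190 AD with 15 amyloid-positive CN and 32 amyloid-negative AD; a stated
  20.83% positive-CN figure in the source demographics is inconsistent with
  its own counts, 15/74 = 20.27% — the generator follows the counts). MMSE
  is drawn per diagnosis from truncated normals (CN 27.5 ± 1.7, AD
  19.5 ± 4.3 on [0, 30]) independent of the imaging features given
  diagnosis, so correlation checks assert sign and monotonicity only.
- **Default effects** perfusion_effect = 0.25, amyloid_effect = 0.35,
  noise_sd = 0.08, subject_noise_scale = 2: moderate effects under which
  neither phase alone is perfectly separable (early-phase subject-level
  d ≈ 1.6; delay phase capped by discordance), chosen once as the standing
  study conditions for all experiments.

What the generator does **not** model: compartmental kinetics and arterial
input functions, scanner PSF/noise texture, partial-volume effects, spatial
misregistration, within-region heterogeneity, and any feature–MMSE coupling
beyond diagnosis. Passing tests therefore demonstrate correctness of the
pipeline and the qualitative phase logic, not clinical performance.

A voxel phantom exporter writes each subject as 4D dynamic + 3D delay NIfTI
volumes (constant value per atlas block, arbitrary global scale) so the
feature-extraction path is exercised end to end: extraction recovers the
generator's stored TAC/SUVr exactly and is invariant to intensity rescaling.

## Evaluation

Stratified splitting allocates each diagnosis × reading stratum by
largest-remainder rounding of size × (0.6, 0.1, 0.3) (ties by partition
order) after a seeded shuffle, so every partition is within one subject of
its exact proportion in every stratum. AUROC is the Mann–Whitney statistic
with ties counted ½; its standard error is DeLong's structural-components
estimator (var = var(V10)/m + var(V01)/n), which matches the standard R
implementation to 1e-9 on a frozen instance and a pairwise-enumeration
oracle exactly. G-mean is √(sensitivity × specificity) — the usual summary
under class imbalance, with AD as the positive class throughout. Spearman
correlation uses mid-ranks via scipy. Subgroup AUROCs restrict scoring to
one amyloid-reading stratum at a time; a separate concordant/discordant
partition (reading agrees/disagrees with diagnosis) is provided because a
delay-only classifier separates the former and inverts on the latter.

## Experiments (desk scale)

`dualpet.experiments` packages two designs used by the tests and the
acceptance script. The *directional* experiment trains early-only,
delay-only and dual models over 5 seeds on reference-composition cohorts
(n = 264, test n = 79) at 300 epochs and compares median test AUROCs; the
expected ordering dual ≥ early and dual ≥ delay mirrors the motivating
finding that the fused score dominates either phase. The *recovery*
experiment places signal in one phase at a time and measures the other:
with amyloid_effect = 0 the delay model is evaluated on a 500-subject
held-out cohort (the larger evaluation set tightens the at-chance estimate;
the small-test-set sampling sd of a null AUROC is ≈0.07, comparable to the
margin being asserted) and sits within 0.08 of 0.5; with perfusion_effect =
0.5 and noise_sd = 0.02 the early model exceeds 0.8. Problem sizes and
epoch budgets are the package's standing choices for these experiments.

## Numerical choices and edge cases

- Min-max scaling maps a constant feature to 0; feature-count mismatches
  are rejected.
- Attention with a single phase degenerates to a = [1], C = h₁.
- A frame with non-positive cerebellar mean, an empty mask, a non-positive
  reference, or a static window selecting no frames are hard errors, not
  warnings.
- The gamma-variate curve peaks at t* = α·β; non-positive parameters are
  rejected.
- Batch normalization uses running statistics at inference, so scores are
  independent of batch composition; dropout is inference-disabled; repeated
  prediction is bit-identical.
- Checkpoints are JSON (weights, config, scaler, history) — small networks
  make a text format practical and diffable.

## Known limitations

- The LSTM/attention model is small by design (D = 6); the package does not
  target image-space (convolutional) models, nonlinear registration,
  template construction, or partial-volume correction.
- Real-cohort performance figures cannot be reproduced here: the clinical
  data behind the motivating study are not public. Synthetic experiments
  assert orderings and recovery properties, not absolute AUROC values.
- The delay-only ceiling argument assumes delay SUVr depends on the reading
  alone; real amyloid load is continuous and partially coupled to
  diagnosis, so real delay-phase AUROCs can exceed the synthetic ceiling.
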