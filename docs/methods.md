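# Methods

## Problem setting

Single-trial P300 detection is a binary classification of stimulus-locked
EEG epochs: did this trial contain the attended (target) stimulus? For
patients with a disorder of consciousness (DOC) the practical obstacle is
cross-subject transfer: patient P300 responses are weakened, delayed and
less reliable than healthy responses, patient data are scarce, and a
classifier trained on healthy subjects does not transfer directly. The
package implements a three-part remedy:

1. **Source screening.** Each candidate (healthy) source subject is scored
   by the empirical Wasserstein-1 distance between their epochs and the
   target subject's unlabeled epochs,

   W(p_s, p_t) = inf over couplings γ ∈ Π(p_s, p_t) of E_{(x,y)~γ} ‖x − y‖,

   and only nearby sources enter the training pool (default rule: distance
   at or below the median).
2. **Supervised pre-training.** A spatio-temporal CNN feature extractor
   M_s and a fully connected softmax classifier C are trained on the pooled
   labeled source epochs with the cross-entropy loss.
3. **Adversarial discriminative adaptation.** A target extractor M_t,
   initialized as a copy of M_s, is trained on *unlabeled* target epochs
   against a domain discriminator D. Alternating updates minimize

   L_D = −E log D(M_s(x_s)) − E log(1 − D(M_t(x_t)))        (D step)
   L_M = −E log D(M_t(x_t))                                  (M_t step)

   with M_s and C frozen throughout. Target epochs are then classified as
   C(M_t(x_t)) on a held-out labeled split. The M_t objective uses the
   inverted-label (non-saturating) form rather than the minimax form.

## Preprocessing

Continuous 10-channel recordings (O1, Oz, O2, P7, P3, Pz, P4, P8, Fz, Cz,
250 Hz, microvolts) are band-pass filtered at 0.1–20 Hz with a zero-phase
4th-order Butterworth, epoched into [0, 1000) ms post-stimulus windows with
a [−100, 0) ms baseline segment, baseline-corrected per channel, and
resampled to 150 time points.

Numerical choices that matter:

* Filtering happens on the *continuous* signal, before epoching, to keep
  filter transients out of the epochs. Zero-phase filtering uses
  Gustafsson's initial-condition method: the default odd-extension padding
  interacts with the very slow 0.1 Hz edge and leaves multi-second boundary
  transients on finite recordings.
* A 1000 ms epoch at 250 Hz has 250 samples but the network input is 150
  time points. We resample each epoch 250 → 150 (polyphase, anti-aliased,
  effectively 150 Hz) rather than cropping, preserving the full window.
  Epochs are demeaned per channel before resampling and the mean restored
  afterwards, which makes constant signals exact and reduces edge error.
* All windows are half-open, sample indices 0-based, units fixed at
  microvolts.

## The network

For a 150 × 10 input (time × electrodes), scaled by a fixed 10 µV input
gain so tanh units start in their linear range:

* spatial convolution: kernels spanning all 10 electrodes (learned spatial
  filters), 16 filters, tanh — time axis unchanged (150);
* temporal convolution: valid kernels of length 4 mixing all spatial maps,
  16 filters, tanh — 147 time steps;
* max pooling (2, 1) along time — 73 steps, flattened to 16 · 73 = 1168
  features;
* classifier: one 32-unit tanh hidden layer, softmax over 2 classes. The
  classifier's output layer is initialized near zero so an untrained
  network predicts 0.5/0.5 (cross-entropy ln 2) on balanced data.

Pre-training uses Adam (lr 1e-3), batch 32, at most 100 epochs with early
stopping on a training-loss plateau (patience 10). Filter counts, the
classifier width and the optimizer settings are not forced by the
architecture; they are desk-scale defaults exposed in `STCNNConfig` /
`TrainConfig`. Everything is implemented on numpy with hand-derived
gradients (verified against numerical differentiation in the tests); no
deep-learning framework is required.

## The adversarial stage

Small-sample adversarial games are easily won by the discriminator: with a
few hundred fixed feature vectors per domain, a discriminator trained at
the same rate as the extractor memorizes both clouds, its loss collapses,
and the extractor is pushed into degenerate maps that destroy class
structure. The defaults therefore handicap D deliberately:

* D is a single-hidden-layer (32-unit tanh) network over the 1168
  features, trained with Adam at lr 1.5e-5 — roughly an order of magnitude
  slower than M_t (lr 1e-4);
* D inputs are corrupted with Gaussian instance noise (sd 0.4, feature sd
  is ≈0.4) during training, and source labels are one-sided smoothed to
  0.9;
* batches of 64 per domain, 700 alternating steps (fixed, no early stop by
  default; an optional stop when D sits at chance is available).

With these settings the game converges on alignable shifts: on a target
that is a channel-mixed version of a source subject, the held-out
discriminator accuracy lands near 0.5 and target accuracy is unchanged.
The post-adaptation discriminator accuracy is measured on held-out
(20%) balanced source/target features with the trained D on clean
(noise-free) inputs.

The target subject's epochs are split stratified 50/50: one half (labels
hidden) drives adaptation and the Wasserstein screening, the other half
(labels kept) is the test set. M_s and C are frozen from the end of
pre-training; tests assert their weights are bit-identical before and
after adaptation, and that deleting target labels changes nothing.

## Wasserstein screening

Epochs are embedded one-point-per-epoch (flattened 150·10 vectors by
default; per-class mean ERPs and PCA projections are alternatives), with
uniform weights, subsampled to at most 200 epochs per subject (seeded) for
tractability. Three estimators:

* `exact_lp`: the transportation linear program (HiGHS); any sizes and
  weights; returns the coupling γ.
* `assignment`: Hungarian algorithm; exact for equal-size uniform sets
  (an optimal coupling is then a permutation) and much faster; the default
  when applicable.
* `sliced`: averaged 1-D projections (seeded); an approximation used only
  when explicitly requested; returns no coupling.

Tests pin the estimators to an exhaustive-permutation oracle, to the 1-D
sorted closed form, and to the metric axioms. The selection rule default is
`below_median` (keep sources at or below the median distance); `top_k` and
a fixed threshold are alternatives. Which representation, estimator and
rule the original protocol used is not documented anywhere we could rely
on; these defaults are this package's choices, all exposed in config.

## Synthetic cohorts

Real DOC recordings are not available, so the simulator generates the
study conditions end to end. Each subject emits 250 Hz, 10-channel epochs
over [−100, 1000) ms. A target epoch contains, with probability
`occurrence_rate`, a positive Gaussian deflection (amplitude × latency ×
FWHM width) projected on a fixed parieto-central topography peaking at
Pz/Cz; non-targets never do. Every epoch adds white noise (sd 4 µV) and a
10 Hz, 3 µV alpha-like oscillation with random phase. Finally a
per-subject invertible channel-mixing matrix is applied.

Populations:

* **Healthy** (sources): amplitude 4–8 µV, latency 280–320 ms, width
  150–250 ms, occurrence 0.9–1.0, mixing strength 0–0.15.
* **DOC-like** (targets, default): the phenotype on which cross-subject
  adaptation is claimed to work — weakened (2.5–3.5 µV), moderately
  delayed (330–380 ms), occurrence 0.75–0.9, and a strong spatial shift:
  random mixing of strength 0.5–0.8 composed with a 0.6–0.85 attenuation
  of the parieto-central channels (damaged generators). The spatial shift
  is linear and invertible — exactly the structure the adversarial stage
  can undo — while the temporal/occurrence components are mild.
* **Severe DOC-like** (`SEVERE_DOC_RANGES`): 1–2 µV, 420–500 ms,
  occurrence 0.3–0.5. On this phenotype neither direct transfer nor
  adaptation achieves usable accuracy; it reproduces the failure mode
  reported for patients with no clinical improvement, and is provided for
  exactly that negative check.

Background noise and rhythm are held common across subjects: the
inter-subject covariate shift is carried by the deflection parameters and
the mixing, which is the design the adversarial stage is meant to undo. A
subject-specific background (individual alpha frequency/power) would add a
domain cue that *no* extractor map can remove — under such conditions the
discriminator never reaches chance and prolonged adversarial pressure only
degrades the features. This is a known limitation of marginal feature
alignment, not of the implementation; real patient EEG has such cues, and
passing desk-scale tests here does not certify performance on real
recordings. Likewise the Gaussian-bump ERP, the absence of 1/f noise,
artifacts and non-stationarity, and the 1:1 class ratio are deliberate
simplifications; all are configurable.

The per-subject generative truth (amplitude, latency, width, occurrence,
noise, rhythm, mixing norm, seed) is written to a manifest for ground-truth
recovery checks. All seeds derive from a master seed via
`numpy.random.SeedSequence`, so cohorts are bit-reproducible.

## Transfer benchmark

`evaluation.run_transfer_benchmark` simulates, per master seed, 8 healthy
sources (160 epochs/class) and DOC-like targets (300 epochs/class; patients
are recorded over multiple sessions and their data must feed both the
adaptation and test splits). For each target it reports, on the held-out
labeled half:

* **direct**: the pre-trained source model applied unchanged;
* **adapted**: the same model after adversarial adaptation on the
  unlabeled half;
* **oracle**: a model trained on the *labeled* adaptation half — an upper
  reference for what any adaptation could achieve;
* the held-out discriminator accuracy and the recovered fraction
  (adapted − direct) / (oracle − direct).

Aggregation is median-over-seeds of per-seed means. Problem sizes (5 seeds,
1–2 targets per cohort, the epoch counts above, 700 adversarial steps, ≤40
pre-training epochs) are the package's desk-scale defaults; they keep a
full benchmark run in single-digit minutes on one CPU while leaving the
qualitative ordering stable. On these conditions adaptation recovers the
direct-to-oracle gap essentially in full and the discriminator ends near
chance; Wasserstein screening is approximately neutral (every default
healthy source is adequate), consistent with the mixed per-subject effect
of source selection reported in the literature.

## Statistics

The benchmark table (methods × subjects) is analyzed with a classical
one-way repeated-measures ANOVA: methods as the within factor, subjects as
the repeated measure, F = MS_methods / MS_error with
(m−1, (m−1)(s−1)) degrees of freedom and no sphericity correction. Some
software reports a between-style error df (ms − m); both conventions are
surfaced on the result object. Degenerate tables (zero method effect)
report F = 0, p = 1 by convention. Post-hoc comparisons are paired t-tests
against a reference method with Bonferroni correction
(p_corr = min(1, p · n_comparisons); identical columns give p = 1).
The chance-level flag uses a fixed 64% criterion by convention of the
paradigm's literature (strict inequality), with an exact-binomial
alternative because a fixed criterion is sample-size-specific.

## Known limitations

* Marginal adversarial alignment cannot correct class-conditional
  temporal shifts: a length-4 temporal kernel is translation-equivariant,
  so a large P300 latency delay is structurally uncorrectable and drives
  feature degradation instead (hence the severe phenotype's failure).
* The oracle model is itself trained on limited labeled data and can sit
  below a well-transferred source model; the recovered-gap statistic is
  unstable when the gap is within test-set resolution (medians are used
  for this reason).
* EDF writing is minimal (16-bit plain EDF + sidecar events TSV); EDF+
  annotation writing is out of scope, annotations are parsed on read.
* Sliced Wasserstein underestimates the LP value at finite projection
  counts; it is never used in the default pipeline.
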