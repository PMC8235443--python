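# Methods

This note documents the model, the synthetic cohort generator, the
numerical choices, and what the desk-scale experiments do and do not
establish.

## Problem setting

Two sensor streams are recorded while a subject performs unscripted
kitchen activity: a privacy-preserving binary silhouette video
(nominally 8 frames/s) and a wrist-worn tri-axial accelerometer
(100 Hz). The task is binary classification of Parkinson's disease
(PD, positive class) versus healthy control (HC) at the level of short
observation windows, evaluated with leave-one-pair-out cross-validation
over spousal pairs so that no subject ever appears in both train and
test. The modalities are complementary: whole-body mobility and posture
are visible in the silhouettes, while fine hand movements — notably
4–6 Hz resting tremor — appear in the wrist acceleration.

## Input construction

**Silhouette temporal encoding.** The input at frame `i` is an
`H x W x D` stack whose channel `d` is the arithmetic mean of the
`t_d` binary frames ending at `i`. Defaults: `D = 3`,
`t = (5, 150, 250)` frames, spanning 0.6 / 18.8 / 31.3 s at 8 fps.
Frame indexing is 1-based in the public API (the earliest valid index
equals `t_D`); storage is 0-based internally. Channel means are
computed as integer window sums divided once by `t_d`, so they equal
brute-force per-pixel averaging bit-for-bit.

**Accelerometer windows.** The raw 100 Hz stream is decimated to 10 Hz
by polyphase anti-aliased resampling (`scipy.signal.resample_poly`,
linear-extension padding so the gravity offset is exact at the edges);
output length is `floor(duration x 10)`. Windows hold `t_D = 250`
samples (25 s) — the same *count* as the deepest silhouette channel,
which at 8 fps spans 31.25 s; the mismatch in physical span is by
design. Note the Nyquist consequence: after 10 Hz resampling only the
lower half of the 4–6 Hz tremor band survives, so tremor visibility
varies across PD subjects with their drawn tremor frequency.

**Pairing.** A silhouette frame is paired with the accelerometer window
whose last sample is the nearest timestamp at or before the frame time
(causal; an exact tie is the window end; a gap larger than one frame
period, or fewer than `t_D` preceding samples, skips the frame). A
stride parameter thins consecutive samples; the desk-scale experiments
use stride 4.

## Architecture

* **Silhouette VAE.** Encoder: three 3x3 convolution stages with 2, 4
  and 8 filters, sigmoid activations, 2x max-pooling after each stage;
  two dense heads of width 64 produce the posterior mean and
  log-variance. Decoder mirrors the encoder (dense, three
  upsample-convolution stages, sigmoid output in [0, 1]). The `D`
  temporal-average planes enter as input channels of the 2-D
  convolutions; with `D = 3` a true volumetric axis would be nearly
  degenerate, so only the channel treatment is implemented.
* **Accelerometer VAE.** Encoder: three grouped 1-D convolution stages
  (kernel length 5), each axis with its own filter bank of 2, 4, 8
  filters, ReLU activations; pooling only after the last stage; dense
  heads of width 64. Decoder mirrors it with a linear output head
  (accelerations are unbounded).
* **Classifier.** Concatenation of the two posterior means (silhouette
  part first), two ReLU dense layers of width 64, sigmoid output;
  decisions threshold the PD probability at 0.5.

Posterior scale is parameterised as `sigma = exp(logvar / 2) + 1e-6`
(standard deviations, never zero); the KL closed form
`0.5 * sum(sigma^2 + mu^2 - 1 - ln sigma^2)` treats `sigma` as a
standard deviation throughout. Under the default 64x80 geometry the
full model has ~717k parameters; the architecture also builds and runs
at 256x320.

## Losses and training

`L = alpha (L_S + L_A) + beta L_C + gamma L_D` with
`alpha = beta = 0.1`, `gamma = 1`. Each term is defined per sample and
averaged over the batch, so magnitudes are batch-size invariant and the
relative weighting is unchanged. `L_C` is standard binary cross-entropy
(computed stably from logits in the training graph; the probability-
space form is the public contract and the two are tested to agree).
`L_D` squares the full `(1 - cos)` term, giving range [0, 4]. Variant
semantics: autoencoder (AE) variants drop sampling and the KL terms;
`*_noLD` variants set the effective `gamma` to 0; unimodal variants
keep one branch and a half-width classifier.

Training uses Adam for 5 epochs. Batch size 8 and learning rate 3e-3
are the package defaults, selected in pilot runs for convergence within
the fixed epoch budget at desk scale (a few hundred optimiser steps;
both remain `TrainConfig` knobs).

Three initialisation choices matter at this scale and are part of the
package's init scheme:

1. **Sigmoid gain.** Sigmoid-activated layers use Glorot-uniform init
   scaled by 4 (the sigmoid's linear regime is four times shallower
   than tanh's); without it, sample-to-sample signal variance collapses
   through the three sigmoid convolution stages.
2. **Small posterior heads.** The mean/log-variance heads use a 0.1
   gain so both branches' latents start near the prior mean at matched
   scales; otherwise the silhouette latents start with large constant
   offsets that dominate the joint representation.
3. **Narrow initial posteriors.** The log-variance bias starts at -3
   (`sigma ~ 0.22`). With `sigma ~ 1` at init, the sampled latent is
   essentially prior noise, reconstruction collapses to the mean image,
   the silhouette posterior mean stays nearly constant across samples,
   and the alignment loss then collapses the accelerometer latents onto
   that constant direction, destroying their class signal. Narrow
   initial posteriors let reconstruction individualise the latents
   first; the KL term relaxes `sigma` toward 1 as training proceeds.

## Missing-modality inference

With exactly one modality absent, the available branch is encoded to
`(mu_N, sigma_N)`; one draw `z ~ N(mu_N, sigma_N)` fills the missing
slot of the joint representation and `mu_N` fills the available slot,
preserving the canonical (silhouette, accelerometer) order. One draw is
the default; averaging the probability over `k` draws is available.
Two reference strategies are implemented for comparison: copying the
available embedding into both slots (for AE models trained with the
alignment loss) and pushing a standard-normal draw through the missing
modality's decoder then encoder (for VAEs trained without it).

The 50%-removal protocol removes the named modality from a random half
of each fold's test samples, scores them by substitution and the rest
with both modalities, and repeats 10 times; removal masks are a pure
function of (seed, fold, repeat). Full removal scores every test sample
by substitution.

Metrics are computed per fold from that fold's own confusion counts
(zero-denominator convention: 0) and macro-averaged across folds — so
the averaged F1 is generally not the harmonic mean of averaged
precision and recall.

## Synthetic cohorts

The generator emulates the study design the architecture targets:
spousal pairs (one PD + one HC), kitchen activity, paired streams with
UTC-like timestamps. Class effects enter only through per-subject
profiles drawn from class-conditional distributions:

| parameter | PD | HC | unit |
|---|---|---|---|
| walk speed | 0.6 ± 0.10 (clipped < 75% of HC mean) | 1.4 ± 0.20 | px/frame |
| tremor amplitude | 0.25 ± 0.05 (min 0.05) | 0 | g |
| tremor frequency | uniform 4–6 | — | Hz |
| low-freq activity amplitude | 0.18 ± 0.04 | 0.30 ± 0.04 | g |
| postural sway | 1.5 | 1.5 | px |

Defaults: 120 s per subject, 64x80 frames (quarter linear scale of a
256x320 camera; a config switch restores full scale), exactly 8 fps,
100 Hz accelerometry. The silhouette is a body-shaped template (head,
torso ellipse, limb strokes) performing a station-based walk: dwell at
a waypoint (mean 4 s), transit at the profile's walk speed, with slow
sinusoidal sway and a hand blob oscillating at the tremor frequency
(12 px/g attenuation). The wrist stream is a per-subject tilted gravity
vector, a <2 Hz multi-sine activity component, a tremor sinusoid on a
wrist-dominant axis mix, and white noise (sigma 0.03 g). PD subjects'
lower activity amplitude reflects bradykinesia; the dwell mean was set
so the class gap in mean centroid speed is detectable over cohorts of
the tested size (rank-sum p ~ 4e-7 over 20 subjects/class) despite the
duty-cycle compensation a station walk introduces (slower transit means
more transit frames).

What the generator does **not** emulate: articulated gait, camera
noise, segmentation errors, occlusion, multi-person scenes,
non-stationary symptom fluctuation, or realistic activity taxonomies.
Passing tests therefore demonstrate that the pipeline recovers planted,
physiologically plausible class structure under the stated protocols —
not clinical performance on real patients.

## Desk-scale study and its reading

The replicated study (`mcpdnet.study`) uses three independent two-pair
cohorts, 2 min/subject, stride 4, 5 epochs — a few hundred optimiser
steps per model, roughly two orders of magnitude less data than a
realistic deployment. At this scale held-out generalisation rests on
two unseen subjects, so per-replicate metrics are intentionally noisy
and all claims are directional, pooled over replicates:

* the alignment loss raises the held-out latent cosine far above the
  no-alignment variant's (~0.5–0.9 versus ~0) in every replicate;
* pooled cross-validated F1 of the full model exceeds each unimodal
  variant's;
* with a modality fully removed, latent substitution matches or beats
  the roundtrip baseline in most replicates.

Individual replicates can collapse to near-chance (all-one-class
predictions at the 0.5 threshold) when the drawn cohort is genuinely
hard — e.g. a PD subject whose tremor frequency falls in the upper half
of the band that 10 Hz resampling removes. This mirrors the per-fold
volatility reported for small real cohorts and is left visible rather
than smoothed away.

## Known limitations

* The autodiff core is single-threaded NumPy; it is sized for the
  desk-scale study, not for large cohorts or full-resolution video.
* `gamma = 1` alignment measurably slows classification learning early
  in training (the alignment gradient dominates the posterior heads
  until the spaces agree); with the short epoch budget this can cost
  accuracy relative to the no-alignment VAE on easy replicates, a
  trade-off that buys the missing-modality capability.
* The 0.5 decision threshold is fixed; no calibration is attempted.
* Timestamp jitter, dropped frames and sensor clock drift are not
  simulated; pairing tolerances are exercised in tests only.
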