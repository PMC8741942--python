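# Methods

This note documents the models, algorithms and design choices behind
`rppg_afib`: a synthetic end-to-end test bed for contactless atrial-
fibrillation (AF) screening from facial remote photoplethysmography
(rPPG).  The pipeline mirrors a camera-based screening protocol — a
subject is filmed at 84 frames/s, the mean skin color of a facial
region is reduced to one pulse channel, band-passed, cut into 30-s
clips, classified by a deep 1-D CNN, and the subject is called AF when
strictly more than half of their clips are called AF — but every stage
runs on simulated recordings, because no clinical recordings are
distributed with the protocol.

## 1. Rhythm simulation

Ground truth is a beat-to-beat (RR) interval series with one of three
group labels (AF, NSR, other abnormality) and, within "other", six
subtypes.  No RR statistics were available for the population being
emulated, so the generators are deliberately minimal processes that
reproduce each rhythm's clinically discriminating feature; every
parameter below is exposed in `RRParams` rather than hard-coded.

- **NSR** — base interval 60/HR scaled by `1 + a sin(2π f_resp t)`
  (respiratory sinus arrhythmia, defaults a = 0.03, f_resp = 0.25 Hz)
  times multiplicative Gaussian jitter with CV 0.02.
- **AF** — i.i.d. Gamma intervals with CV 0.24 (clipped to 0.3–2.0 s):
  heavy variability with *no serial correlation*, the
  "irregularly-irregular" signature.  Ensemble checks: CV in
  [0.18, 0.30], |lag-1 autocorrelation| < 0.15.
- **APC / VPC** — NSR backbone with per-beat probability 0.1 of a
  premature beat at 0.6× (APC) or 0.5× (VPC) of the base interval,
  followed by a 1.4×/1.5× compensatory pause; ventricular ectopics
  additionally eject with a 60 % pulse-amplitude deficit.
- **Sinus arrhythmia** — NSR with respiratory modulation a = 0.15.
- **Sinus tachy / brady** — NSR dynamics pinned at 110 / 50 bpm.
- **Atrial flutter** — regular ventricular response at 150 bpm (2:1
  block of a 300/min atrial rate) switching abruptly to 4:1 and back
  every ~30 s (uniform 15–45 s), with 1 % interval jitter.

All intervals are clipped to the physiological range 0.25–3.0 s, and a
series stops before its cumulative sum would exceed the recording
duration.  Mean heart rates of the free-rate classes are drawn from
overlapping ranges (NSR/ectopy/sinus-arrhythmia 55–95 bpm, AF
60–120 bpm) so that *rate alone cannot separate the classes* — the
classifier must use interval structure.

## 2. Pulse and camera observation model

Each beat renders a two-Gaussian template — systolic peak at 30 % of
its RR interval (width 0.08 s, amplitude 1) and dicrotic wave at 55 %
(width 0.10 s, amplitude 0.35) — summed over beats and normalized to
unit peak.  The camera sees, per channel c ∈ {R, G, B}:

    c(t) = baseline_c · (1 + k_c · s · pulse(t) + drift(t)) + ε(t) + artifacts

with pulsatile signature (k_R, k_G, k_B) = (0.33, 0.77, 0.53) (the
standard skin-reflection ratios; hemoglobin absorbs green most),
pulse strength s = 0.5 % of baseline, a shared illumination drift
(white noise low-passed at 0.1 Hz, SD 1 % of baseline), white sensor
noise (SD 0.2 intensity units) and sparse motion artifacts (Poisson
rate 1/min, 0.5-s triangular ramps of 5 intensity units hitting all
channels).  An optional frame renderer expands the trace into a
(T, H, W, 3) stack with a rectangular skin patch plus per-pixel noise;
`roi_mean_rgb` inverts it.

What the generator does *not* emulate: face/head motion and tracking
error, illumination spectra, video compression, skin-tone diversity,
autonomic rate drift within a recording, and any coupling between
rhythm and pulse morphology beyond the VPC amplitude deficit.  Passing
tests therefore validate the pipeline's mechanics and its
discriminative mechanism, not clinical performance.

## 3. Pulse extraction and filtering

`chrominance_project` implements CHROM (default): within 1.6-s windows
(50 % overlap, Hann overlap-add), channels are normalized by their
window means, combined as X = 3R̂ − 2Ĝ and Y = 1.5R̂ + Ĝ − 1.5B̂
(both mean-centered), and output as X − (σ_X/σ_Y)Y, which cancels
common intensity modulation to first order.  POS and a mean-centered
GREEN channel are provided for comparison.  A zero-variance Y window
falls back to X alone.

Filtering is a Chebyshev type-II band-pass designed with prototype
order 4 and 40 dB stopband attenuation at edges 0.5/3 Hz, applied
forward–backward (zero phase).  Note the type-II convention: 0.5 and
3 Hz are *stopband* edges, so the flat (−1 dB) passband is about
0.81–1.87 Hz and response at 2.5 Hz is already ≈ −19 dB.  This is what
the standard `cheby2(4, 40, [0.5 3])` design produces and is kept
deliberately; its practical consequence — fast rhythms such as 2:1
flutter (2.5 Hz) emerge strongly attenuated and noise-like — is
visible in the error analysis below.

`estimate_hr` takes 60× the argmax of a Welch-averaged periodogram
(40-s windows) over 0.5–3 Hz; averaging is needed because the raw
periodogram of an irregular rhythm is too erratic for its largest
single bin to track the mean rate.  `quality_check` scores the power
within ±0.1 Hz of the dominant in-band peak and its first harmonic
against the remaining in-band power (pass ≥ 2 dB).  This statistic
measures *periodicity*: genuinely irregular rhythms score low even
when perfectly recorded, so the pipeline does not gate subjects on it
by default (`ExtractConfig.quality_gate = False`); it is intended for
flagging, or for gating cohorts of near-periodic rhythms.

## 4. Segmentation and tasks

Recordings are cut into non-overlapping 30-s clips anchored at sample
0; the trailing remainder is discarded (600 s → 20 clips, 484 s → 16).
Each clip is z-scored (pulse amplitude units are arbitrary); a
constant clip becomes zeros and is flagged.  Clips inherit the
subject's group as a binary label under three tasks: AF vs NSR, AF vs
Others, AF vs non-AF; AF maps to 1 in all three.

## 5. The classifier

A sample-level 1-D CNN with 12 weight layers: 11 convolutions
(channel widths 16, 16, 32, 32, 64, 64, 64, 128, 128, 128, 256, each
with batch normalization and ReLU), max pools of size 3 after layers
1, 2, 3, 5 and 7, a global max pool, dropout 0.5, and a single
fully-connected sigmoid unit.  Two departures from the audio-style
original are deliberate and were driven by the 84-Hz input rate:

- **Stride-4 first convolution.** The pulse band (≤ 3 Hz) is ~14×
  oversampled at 84 Hz; the strided front end (standard in
  sample-level audio networks) decimates to 21 Hz, cutting compute
  ~4× and letting deeper layers span beats sooner.
- **Kernel 7 and pools spread over layers 1–7.** With kernel 3 and a
  pool after every early layer, the temporal axis falls below the
  pulse frequency (84/3⁴ ≈ 1 Hz by layer 4) while the receptive field
  is still shorter than one beat — beat-interval irregularity, the
  discriminative signal, is then invisible.  Measured on
  subject-grouped CV, the kernel-3/pool-1..7 schedule plateaus near
  segment AUC 0.68; the kernel-7 spread schedule reaches ≈ 0.93–0.95.

Training: Adam (lr 10⁻³, batch 32, binary cross-entropy), weighted by
inverse class frequency for the imbalanced pooled task; fully
deterministic under a seed (initialization, shuffling, dropout,
augmentation).  Two training-time augmentations encode invariances of
the rhythm label: a random circular time shift, and a random ±25 %
time warp, which removes the shortcut of memorizing a training
subject's heart rate.  (Channel dropout inside conv blocks is
implemented but defaults to 0 — at rate 0.1 it stalled training on
this task; noise-injection augmentation likewise defaults off after
measuring that it blurs rather than helps class separation.)  An
optional validation split with early stopping exists, but the
cross-validation protocol uses a fixed epoch budget.  Per fold, an
ensemble of 2 models trained from different seeds is averaged
(`TrainConfig.ensemble`); seed averaging stabilizes the small-sample
fit and is worth ≈ +0.02 segment AUC.

## 6. Evaluation protocol

Stratified folds are dealt round-robin with a rolling pointer, so fold
sizes differ by at most one unit.  The default grouping is
**subject-level** (all clips of a subject share a fold): partitioning
clips instead — as the flow-chart description of the emulated protocol
suggests — lets clips of one subject appear in both train and test and
inflates segment metrics; `SEGMENT_LEVEL` is available as a fidelity
mode and all reports name the mode used.  Every clip receives exactly
one out-of-fold probability; clips are called AF above 0.5; a subject
is called AF when the fraction of AF-called clips strictly exceeds 0.5
(an exact 50/50 tie is non-AF).  Sensitivity, specificity, PPV and
accuracy are exact ratios of confusion counts (undefined ratios are
flagged, not zeroed); ROC/AUC uses all distinct thresholds with the
tie-aware rank convention, so AUC equals the Mann-Whitney concordance
probability.  Subject-level metrics pool out-of-fold votes; fold-wise
mean ± sample SD (n−1) is reported for segment-level metrics.

The segment-length sensitivity sweep re-segments, re-trains and
re-votes at each length (15–300 s); a length exceeding the shortest
recording is flagged rather than dropped.  Because longer segments
mean proportionally fewer training clips, the sweep equalizes the
optimization budget across lengths (epochs scaled by
`seg_len / min_len`, keeping sample-passes constant); without this the
long-segment rows are confounded by undertraining at small cohort
sizes.  Under that design, subject accuracy at 120-s segments is at or
above the 15-s accuracy in the median over seeds, consistent with
voting over windows that each span more beats.

## 7. Problem sizes and observed behavior

The validation experiments run on one CPU at desk scale: 60 subjects
(20 AF / 20 NSR / 20 mixed other-abnormality), 5-minute recordings,
600 clips, subject-grouped tenfold CV with 50 epochs and 2-seed
ensembles (~13 minutes); the sweep property uses 12-subject AF/NSR
cohorts at 360 s over 10 seeds.  Under these conditions subject-level
accuracy for AF vs non-AF lands around 0.92–0.98 and out-of-fold
segment AUC around 0.95, varying with the cohort seed; the AF-vs-NSR
subset is essentially solved (subject accuracy ~1.0, segment AUC
≈ 0.99).  Residual errors concentrate exactly where the physics
says they should: flutter and sinus-tachycardia subjects, whose
2–2.5 Hz pulse lies outside the filter's flat passband, emerge
noise-like and are occasionally voted AF.  A linear oracle on spectral
entropy separates the same clips at AUC ≈ 0.997, so the remaining gap
is attributable to the small training cohort, not to inseparable data.

## 8. Known limitations

- The synthetic cohort is far cleaner and smaller than a clinical one;
  none of the reported numbers transfer to real recordings.
- The quality gate conflates irregularity with poor quality (§3) and is
  therefore off by default, unlike the emulated protocol's manual
  exclusion of unreadable recordings.
- The type-II band semantics shrink the usable passband (§3); fast
  rhythms are under-served by design fidelity.
- The CNN is NumPy-based and single-threaded; it is sized for
  hundreds, not tens of thousands, of training clips.
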