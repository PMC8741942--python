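# rppg-afib

Contactless atrial-fibrillation (AF) screening from facial video works
because the skin's color is modulated a fraction of a percent by the
cardiac blood-volume pulse: a camera pointed at a face yields, after
averaging a skin region and projecting the RGB channels onto a
chrominance axis, a remote photoplethysmogram (rPPG) whose beat-to-beat
timing carries the rhythm.  AF is "irregularly irregular" — heavy
interval variability with no serial correlation — and that signature
survives all the way to the rPPG waveform.

`rppg_afib` is a tested, reusable implementation of that screening
pipeline for people who study camera-based vital-sign monitoring and
arrhythmia classifiers:

1. **Rhythm & camera simulation** (`simulate`) — RR-interval processes
   for AF, normal sinus rhythm (NSR) and six "other abnormality"
   subtypes (ectopy, sinus arrhythmia, rate abnormalities, flutter);
   pulse-wave rendering; an RGB skin-color observation model with
   illumination drift, sensor noise and motion artifacts at 84
   samples/s; optional synthetic frame stacks.  No clinical recordings
   are distributed with the emulated protocol, so the simulator is a
   first-class, tested component, not a fixture.
2. **Pulse extraction** (`rppg`) — CHROM/POS/GREEN projections; a
   4th-order Chebyshev type-II band-pass (0.5–3 Hz) applied zero-phase;
   heart-rate estimation; a spectral-SNR quality score.
3. **Segmentation** (`segment`) — non-overlapping 30-s clips, z-scored,
   assembled into three binary tasks: AF vs NSR, AF vs Others,
   AF vs non-AF (AF ↦ 1 in all).
4. **Classifier** (`net`) — a sample-level, 12-weight-layer 1-D CNN
   (11 convolutions + fully-connected head, batch norm, ReLU, max
   pooling, dropout) implemented directly in NumPy with Adam and full
   seed determinism.
5. **Evaluation** (`evaluate`) — stratified, subject-grouped tenfold
   cross-validation; segment voting (a subject is AF iff strictly more
   than half of their clips are called AF); confusion-matrix rates,
   ROC/AUC, fold mean ± SD; a segment-length sensitivity sweep.
6. **I/O, config and CLI** (`io`, `config`, `cli`, `pipeline`) —
   delimited-text trace/signal formats, YAML configs with strict key
   checking, and an `rppg-afib` command with `simulate / extract /
   segment / train / evaluate / sweep / run` subcommands.

## Worked example

```python
import rppg_afib as ra

# one AF and one NSR subject, 5-minute recordings at 84 Hz
af  = ra.simulate_subject(ra.RhythmLabel(ra.RhythmGroup.AF),  300, seed=2)
nsr = ra.simulate_subject(ra.RhythmLabel(ra.RhythmGroup.NSR), 300, seed=1)

for rec in (nsr, af):
    sig = ra.extract_rppg(rec.trace)         # CHROM + Chebyshev-II band-pass
    hr  = ra.estimate_hr(sig)
    cv  = rec.rr.intervals.std() / rec.rr.intervals.mean()
    n   = len(ra.segment_signal(sig, 30.0))
    print(f"{rec.label.group.value}: {rec.rr.n_beats} beats, "
          f"interval CV {cv:.3f}, estimated HR {hr:.1f} bpm "
          f"(true {rec.rr.mean_rate_bpm:.1f}), {n} clips of 30 s")
```

prints

```
NSR: 278 beats, interval CV 0.028, estimated HR 55.5 bpm (true 55.7), 10 clips of 30 s
AF: 387 beats, interval CV 0.240, estimated HR 69.0 bpm (true 77.5), 10 clips of 30 s
```

The interval coefficient of variation is the ground-truth discriminant
(~0.03 for NSR, ~0.24 for AF); note also that the spectral rate
estimate is tight for the periodic rhythm and biased for AF, whose
power is spread — the pipeline's job is to recover the regularity
difference from the camera trace alone.  The full study flow — cohort,
extraction, segmentation, grouped tenfold CV of the CNN, voting,
reports — runs from one config:

```bash
rppg-afib run --config examples/small.yaml --out runs/demo
```

and writes `metrics_<task>.json` (confusion counts, rates, AUC, fold
mean ± SD, per-subject votes), ROC curves as CSV, the resolved config
and a stage-tagged log.  Rerunning the same config reproduces every
metrics file byte for byte.

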