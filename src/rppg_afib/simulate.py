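"""Synthetic cardiac rhythms and camera-facing RGB traces.

This module generates the ground truth the rest of the pipeline tries to
recover: beat-to-beat (RR) interval series with a known rhythm class, a
pulse waveform rendered from those beats, and a noisy three-channel RGB
trace emulating the mean skin color of a facial region filmed at 84
frames per second.  Optionally the trace can be expanded into a stack of
synthetic frames with a rectangular skin patch.

The rhythm taxonomy follows the clinical three-way grouping used for
camera-based AF screening: AF (irregularly irregular intervals with no
serial correlation), NSR (regular intervals with mild respiratory
modulation), and a heterogeneous "other abnormality" class covering
premature complexes, sinus arrhythmia, rate abnormalities and flutter.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "RhythmGroup",
    "RhythmSubtype",
    "RhythmLabel",
    "RRParams",
    "RRIntervalSeries",
    "PulseWave",
    "RGBTrace",
    "NoiseParams",
    "CohortSpec",
    "SubjectRecord",
    "simulate_rr",
    "render_pulse",
    "render_rgb_trace",
    "render_frames",
    "simulate_subject",
    "simulate_cohort",
    "default_cohort_spec",
]

#: Hard physiological bounds on a single RR interval, seconds.
RR_BOUNDS = (0.25, 3.0)

DEFAULT_FS = 84.0


class RhythmGroup(str, enum.Enum):
    AF = "AF"
    NSR = "NSR"
    OTHER = "OTHER"


class RhythmSubtype(str, enum.Enum):
    NONE = "NONE"
    APC = "APC"
    VPC = "VPC"
    SINUS_ARRHYTHMIA = "SINUS_ARRHYTHMIA"
    SINUS_TACHY = "SINUS_TACHY"
    SINUS_BRADY = "SINUS_BRADY"
    FLUTTER = "FLUTTER"


@dataclass(frozen=True)
class RhythmLabel:
    """Rhythm class of a subject: coarse group plus an OTHER subtype."""

    group: RhythmGroup
    subtype: RhythmSubtype = RhythmSubtype.NONE

    def __post_init__(self) -> None:
        group = RhythmGroup(self.group)
        subtype = RhythmSubtype(self.subtype)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "subtype", subtype)
        if subtype is not RhythmSubtype.NONE and group is not RhythmGroup.OTHER:
            raise ValueError(
                f"subtype {subtype.value} only valid with group OTHER, got {group.value}"
            )
        if group is RhythmGroup.OTHER and subtype is RhythmSubtype.NONE:
            raise ValueError("group OTHER requires a concrete subtype")

    @property
    def key(self) -> str:
        """Short class key used in cohort specs and manifests."""
        if self.group is RhythmGroup.OTHER:
            return self.subtype.value
        return self.group.value

    @staticmethod
    def from_key(key: str) -> "RhythmLabel":
        if key in (RhythmGroup.AF.value, RhythmGroup.NSR.value):
            return RhythmLabel(RhythmGroup(key))
        return RhythmLabel(RhythmGroup.OTHER, RhythmSubtype(key))


@dataclass(frozen=True)
class RRParams:
    """Tunable parameters of the RR-interval processes.

    All are surfaced here rather than hard-coded because no clinical RR
    statistics are available for the population being emulated; the
    defaults are minimal models that reproduce the discriminating
    feature of each rhythm (chiefly, irregular irregularity in AF).
    """

    resp_amp: float = 0.03          # NSR respiratory sinus arrhythmia depth
    resp_freq_hz: float = 0.25      # respiratory frequency
    jitter_cv: float = 0.02         # NSR multiplicative Gaussian jitter
    af_cv: float = 0.24             # AF i.i.d. Gamma coefficient of variation
    af_clip: tuple[float, float] = (0.3, 2.0)
    ectopy_prob: float = 0.1        # per-beat premature-complex probability
    apc_early: float = 0.6          # APC coupling interval, fraction of base
    apc_pause: float = 1.4          # post-APC compensatory pause factor
    vpc_early: float = 0.5
    vpc_pause: float = 1.5
    sa_resp_amp: float = 0.15       # sinus arrhythmia: exaggerated modulation
    tachy_hr: float = 110.0
    brady_hr: float = 50.0
    flutter_hr: float = 150.0       # ventricular rate under 2:1 block
    flutter_switch_s: float = 30.0  # mean time between block-ratio switches


@dataclass(frozen=True)
class RRIntervalSeries:
    """Beat-to-beat intervals (seconds) with their generating label."""

    intervals: np.ndarray
    label: RhythmLabel
    seed: int
    target_duration: float

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.size and (iv.min() < RR_BOUNDS[0] - 1e-12 or iv.max() > RR_BOUNDS[1] + 1e-12):
            raise ValueError(f"RR intervals outside {RR_BOUNDS} s")
        if iv.size and iv.sum() > self.target_duration + 1e-9:
            raise ValueError("RR intervals overrun the target duration")

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def mean_rate_bpm(self) -> float:
        if self.intervals.size == 0:
            return float("nan")
        return 60.0 / float(self.intervals.mean())

    def onset_times(self) -> np.ndarray:
        """Beat onset times in seconds; beat 0 starts at t = 0."""
        return np.concatenate([[0.0], np.cumsum(self.intervals)[:-1]])


@dataclass(frozen=True)
class PulseWave:
    samples: np.ndarray
    fs: float
    beat_onsets: np.ndarray  # sample index of each beat onset

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class RGBTrace:
    """Mean-pixel-intensity series of the three color channels (0-255)."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    fs: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.r) == len(self.g) == len(self.b)):
            raise ValueError("channel lengths differ")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for ch in (self.r, self.g, self.b):
            if not np.all(np.isfinite(ch)):
                raise ValueError("non-finite channel values")

    def __len__(self) -> int:
        return len(self.r)

    @property
    def channels(self) -> np.ndarray:
        """(3, n) array in R, G, B order."""
        return np.vstack([self.r, self.g, self.b])


@dataclass(frozen=True)
class NoiseParams:
    """Additive disturbances of the rendered RGB trace.

    illum_drift_amp is a fraction of the channel baseline (shared
    illumination drift, band-limited below ``drift_cutoff_hz``);
    white_noise_sd and artifact_amp are in 0-255 intensity units.
    """

    illum_drift_amp: float = 0.01
    white_noise_sd: float = 0.2
    artifact_rate: float = 1.0 / 60.0  # motion transients per second
    artifact_amp: float = 5.0
    artifact_len_s: float = 0.5
    drift_cutoff_hz: float = 0.1

    def __post_init__(self) -> None:
        for name in ("illum_drift_amp", "white_noise_sd", "artifact_rate",
                     "artifact_amp", "artifact_len_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise parameter {name} must be non-negative")

    @staticmethod
    def silent() -> "NoiseParams":
        return NoiseParams(0.0, 0.0, 0.0, 0.0, 0.0)


# Mean heart-rate sampling ranges (bpm) per class key; rate ranges of the
# free-rate classes overlap so that rate alone cannot separate them.
HR_RANGES: dict[str, tuple[float, float]] = {
    "AF": (60.0, 120.0),
    "NSR": (55.0, 95.0),
    "APC": (55.0, 95.0),
    "VPC": (55.0, 95.0),
    "SINUS_ARRHYTHMIA": (55.0, 95.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Composition and generation parameters of a synthetic cohort."""

    n_per_class: dict[str, int]
    duration_range: tuple[float, float] = (300.0, 600.0)
    fs: float = DEFAULT_FS
    noise: NoiseParams = field(default_factory=NoiseParams)
    rr_params: RRParams = field(default_factory=RRParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        for key, n in self.n_per_class.items():
            RhythmLabel.from_key(key)  # validates the key
            if n < 0:
                raise ValueError(f"negative count for class {key}")
        lo, hi = self.duration_range
        if not (30.0 <= lo <= hi <= 600.0):
            raise ValueError("duration_range must lie within [30, 600] s")

    @property
    def total(self) -> int:
        return sum(self.n_per_class.values())


@dataclass(frozen=True)
class SubjectRecord:
    """One simulated participant: ground truth plus the raw RGB trace."""

    subject_id: str
    label: RhythmLabel
    mean_hr: float
    duration: float
    rr: RRIntervalSeries
    trace: RGBTrace
    seed: int


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """Cohort template matching the emulated screening study's
    composition — 105 AF, 116 NSR and 232 other-abnormality
    participants — with the other-abnormality count split across the
    six modeled subtypes."""
    return CohortSpec(
        n_per_class={
            "AF": 105,
            "NSR": 116,
            "APC": 58,
            "VPC": 35,
            "SINUS_ARRHYTHMIA": 58,
            "SINUS_TACHY": 35,
            "SINUS_BRADY": 23,
            "FLUTTER": 23,
        },
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# RR interval simulation
# ---------------------------------------------------------------------------

def _clip_rr(iv: float) -> float:
    return float(min(max(iv, RR_BOUNDS[0]), RR_BOUNDS[1]))


def simulate_rr(
    label: RhythmLabel,
    mean_hr: float,
    duration: float,
    seed: int,
    params: RRParams | None = None,
) -> RRIntervalSeries:
    """Draw an RR-interval series for one subject.

    Parameters
    ----------
    label
        Rhythm class; determines the generating process.
    mean_hr
        Target mean heart rate in bpm (30-220).  Ignored for the
        fixed-rate subtypes (sinus tachy/brady, flutter), whose rates
        come from ``params``.
    duration
        Recording length in seconds; intervals are emitted while their
        cumulative sum still fits within it.
    seed
        Seeds the interval process; the series is reproducible from
        (label, mean_hr, duration, seed, params).

    Notes
    -----
    NSR is a slightly jittered regular rhythm with sinusoidal
    respiratory modulation; AF is an i.i.d. Gamma renewal process with a
    heavy coefficient of variation and no serial correlation — the
    "irregularly irregular" signature that the downstream classifier
    must pick up.  Premature-complex subtypes interleave early beats
    with compensatory pauses into an NSR backbone; flutter alternates
    between 2:1 and 4:1 atrioventricular block at a regular atrial rate.
    """
    p = params or RRParams()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (30.0 <= mean_hr <= 220.0):
        raise ValueError("mean_hr must lie in [30, 220] bpm")
    label = RhythmLabel(label.group, label.subtype)
    rng = np.random.default_rng(seed)

    sub = label.subtype
    if sub is RhythmSubtype.SINUS_TACHY:
        mean_hr = p.tachy_hr
    elif sub is RhythmSubtype.SINUS_BRADY:
        mean_hr = p.brady_hr
    base = 60.0 / mean_hr

    intervals: list[float] = []
    t = 0.0

    if label.group is RhythmGroup.AF:
        shape = 1.0 / p.af_cv**2
        scale = base / shape
        while True:
            iv = float(rng.gamma(shape, scale))
            iv = min(max(iv, p.af_clip[0]), p.af_clip[1])
            iv = _clip_rr(iv)
            if t + iv > duration:
                break
            intervals.append(iv)
            t += iv
    elif sub is RhythmSubtype.FLUTTER:
        atrial_cycle = 60.0 / p.flutter_hr / 2.0  # 2:1 block gives flutter_hr
        block = 2
        next_switch = float(rng.uniform(0.5, 1.5) * p.flutter_switch_s)
        while True:
            iv = _clip_rr(block * atrial_cycle * (1.0 + 0.01 * rng.standard_normal()))
            if t + iv > duration:
                break
            intervals.append(iv)
            t += iv
            if t >= next_switch:
                block = 4 if block == 2 else 2
                next_switch = t + float(rng.uniform(0.5, 1.5) * p.flutter_switch_s)
    else:
        # NSR backbone, possibly with ectopy or exaggerated modulation.
        amp = p.sa_resp_amp if sub is RhythmSubtype.SINUS_ARRHYTHMIA else p.resp_amp
        is_ectopic = sub in (RhythmSubtype.APC, RhythmSubtype.VPC)
        early = p.apc_early if sub is RhythmSubtype.APC else p.vpc_early
        pause = p.apc_pause if sub is RhythmSubtype.APC else p.vpc_pause
        pending_pause = False
        while True:
            iv = base * (1.0 + amp * np.sin(2.0 * np.pi * p.resp_freq_hz * t))
            iv *= 1.0 + p.jitter_cv * rng.standard_normal()
            if is_ectopic:
                if pending_pause:
                    iv *= pause
                    pending_pause = False
                elif rng.random() < p.ectopy_prob:
                    iv *= early
                    pending_pause = True
            iv = _clip_rr(iv)
            if t + iv > duration:
                break
            intervals.append(iv)
            t += iv

    return RRIntervalSeries(
        intervals=np.asarray(intervals, dtype=float),
        label=label,
        seed=seed,
        target_duration=float(duration),
    )


# ---------------------------------------------------------------------------
# Pulse wave rendering
# ---------------------------------------------------------------------------

# Pulse template: systolic peak + dicrotic wave, as fractions of the RR
# interval; widths in seconds.
_SYSTOLIC_FRAC, _SYSTOLIC_W, _SYSTOLIC_AMP = 0.30, 0.08, 1.00
_DICROTIC_FRAC, _DICROTIC_W, _DICROTIC_AMP = 0.55, 0.10, 0.35


def render_pulse(rr: RRIntervalSeries, fs: float = DEFAULT_FS,
                 amplitude_scale: np.ndarray | None = None) -> PulseWave:
    """Render the blood-volume pulse waveform from an RR series.

    Each beat contributes a two-Gaussian template (systolic upstroke
    plus dicrotic wave) positioned within its own RR interval; the
    waveform is normalized to unit peak amplitude.  An empty RR series
    renders to an all-zero wave of the requested duration.

    ``amplitude_scale`` optionally scales individual beats (used to give
    ventricular ectopic beats a pulse deficit).
    """
    n = int(round(rr.target_duration * fs))
    samples = np.zeros(n)
    onsets_t = rr.onset_times()
    onsets_idx = np.round(onsets_t * fs).astype(int)
    if rr.n_beats:
        max_hf = fs / 2.0
        if 1.0 / float(rr.intervals.min()) >= max_hf:
            raise ValueError("sampling rate too low for the implied beat rate")
    for i, (t0, dt) in enumerate(zip(onsets_t, rr.intervals)):
        amp = 1.0 if amplitude_scale is None else float(amplitude_scale[i])
        for frac, width, a in (
            (_SYSTOLIC_FRAC, _SYSTOLIC_W, _SYSTOLIC_AMP),
            (_DICROTIC_FRAC, _DICROTIC_W, _DICROTIC_AMP),
        ):
            center = t0 + frac * dt
            lo = max(0, int((center - 4 * width) * fs))
            hi = min(n, int((center + 4 * width) * fs) + 1)
            if lo >= hi:
                continue
            tt = np.arange(lo, hi) / fs
            samples[lo:hi] += amp * a * np.exp(-0.5 * ((tt - center) / width) ** 2)
    peak = np.abs(samples).max()
    if peak > 0:
        samples /= peak
    return PulseWave(samples=samples, fs=float(fs),
                     beat_onsets=onsets_idx[onsets_idx < n])


def _vpc_amplitude_scale(rr: RRIntervalSeries, params: RRParams) -> np.ndarray | None:
    """Pulse-amplitude deficit for ventricular ectopic beats: a beat much
    earlier than its neighbors ejects against incomplete filling."""
    if rr.label.subtype is not RhythmSubtype.VPC or rr.n_beats < 3:
        return None
    iv = rr.intervals
    med = float(np.median(iv))
    scale = np.ones(rr.n_beats)
    scale[iv < 0.75 * med] = 0.4
    return scale


# ---------------------------------------------------------------------------
# RGB trace and frame rendering
# ---------------------------------------------------------------------------

#: Relative pulsatile strength of the R, G, B channels for skin
#: reflection (hemoglobin absorption peaks under green light).
CHANNEL_SIGNATURE = (0.33, 0.77, 0.53)
DEFAULT_BASELINE = (140.0, 110.0, 95.0)
DEFAULT_PULSE_STRENGTH = 0.005  # peak fractional color modulation


def render_rgb_trace(
    pulse: PulseWave,
    baseline: tuple[float, float, float] = DEFAULT_BASELINE,
    noise: NoiseParams | None = None,
    seed: int = 0,
    pulse_strength: float = DEFAULT_PULSE_STRENGTH,
    signature: tuple[float, float, float] = CHANNEL_SIGNATURE,
    subject_id: str = "",
) -> RGBTrace:
    """Turn a pulse wave into the mean skin-ROI color trace a camera sees.

    Channel model: ``c(t) = baseline_c * (1 + k_c * strength * pulse(t)
    + drift(t)) + white_noise + artifacts``, where ``drift`` is a shared
    band-limited illumination drift and artifacts are sparse 0.5-s
    motion transients hitting all channels equally.
    """
    noise = noise or NoiseParams()
    for b0 in baseline:
        if not (0.0 < b0 < 255.0):
            raise ValueError("baseline intensities must lie in (0, 255)")
    n = pulse.samples.size
    fs = pulse.fs
    rng = np.random.default_rng(seed)

    drift = np.zeros(n)
    if noise.illum_drift_amp > 0 and n > 24:
        white = rng.standard_normal(n)
        sos = scipy.signal.butter(2, noise.drift_cutoff_hz, fs=fs, output="sos")
        drift = scipy.signal.sosfiltfilt(sos, white)
        sd = drift.std()
        if sd > 0:
            drift = drift / sd * noise.illum_drift_amp

    artifact = np.zeros(n)
    if noise.artifact_rate > 0 and noise.artifact_len_s > 0:
        n_events = rng.poisson(noise.artifact_rate * n / fs)
        ramp_len = max(2, int(round(noise.artifact_len_s * fs)))
        half = ramp_len // 2
        shape = np.concatenate([np.linspace(0, 1, half), np.linspace(1, 0, ramp_len - half)])
        for _ in range(n_events):
            start = int(rng.integers(0, max(1, n - ramp_len)))
            seg = shape[: n - start]
            artifact[start:start + seg.size] += noise.artifact_amp * seg

    channels = []
    for b0, k in zip(baseline, signature):
        ch = b0 * (1.0 + k * pulse_strength * pulse.samples + drift)
        if noise.white_noise_sd > 0:
            ch = ch + rng.normal(0.0, noise.white_noise_sd, n)
        ch = ch + artifact
        channels.append(ch)
    return RGBTrace(r=channels[0], g=channels[1], b=channels[2], fs=fs,
                    subject_id=subject_id)


def render_frames(
    trace: RGBTrace,
    frame_size: tuple[int, int] = (48, 64),
    skin_rect: tuple[int, int, int, int] = (8, 40, 16, 48),
    pixel_noise_sd: float = 2.0,
    background: tuple[float, float, float] = (60.0, 60.0, 60.0),
    seed: int = 0,
) -> np.ndarray:
    """Expand a trace into a (T, H, W, 3) synthetic frame stack.

    Pixels inside ``skin_rect`` (row0, row1, col0, col1; half-open)
    carry the trace value of their frame plus independent per-pixel
    noise; the rest is a constant background.
    """
    h, w = frame_size
    r0, r1, c0, c1 = skin_rect
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("skin_rect empty or outside frame bounds")
    n = len(trace)
    rng = np.random.default_rng(seed)
    frames = np.empty((n, h, w, 3), dtype=np.float32)
    frames[:] = np.asarray(background, dtype=np.float32)
    patch = np.stack([trace.r, trace.g, trace.b], axis=-1)[:, None, None, :]
    block = np.broadcast_to(patch, (n, r1 - r0, c1 - c0, 3)).astype(np.float32)
    if pixel_noise_sd > 0:
        block = block + rng.normal(0.0, pixel_noise_sd,
                                   block.shape).astype(np.float32)
    frames[:, r0:r1, c0:c1, :] = block
    return frames


# ---------------------------------------------------------------------------
# Subject and cohort composition
# ---------------------------------------------------------------------------

def _draw_mean_hr(label: RhythmLabel, rng: np.random.Generator,
                  params: RRParams) -> float:
    key = label.key
    if key in HR_RANGES:
        lo, hi = HR_RANGES[key]
        return float(rng.uniform(lo, hi))
    if label.subtype is RhythmSubtype.SINUS_TACHY:
        return params.tachy_hr
    if label.subtype is RhythmSubtype.SINUS_BRADY:
        return params.brady_hr
    return params.flutter_hr


def simulate_subject(
    label: RhythmLabel,
    duration: float,
    noise: NoiseParams | None = None,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    mean_hr: float | None = None,
    rr_params: RRParams | None = None,
    subject_id: str = "",
) -> SubjectRecord:
    """Simulate one participant end to end: rhythm -> pulse -> RGB trace."""
    if not (30.0 <= duration <= 600.0):
        raise ValueError("duration must lie in [30, 600] s")
    p = rr_params or RRParams()
    ss = np.random.SeedSequence([int(seed)])
    hr_seed, rr_seed, trace_seed = (int(s.generate_state(1)[0] % 2**31)
                                    for s in ss.spawn(3))
    if mean_hr is None:
        mean_hr = _draw_mean_hr(label, np.random.default_rng(hr_seed), p)
    rr = simulate_rr(label, mean_hr, duration, rr_seed, p)
    pulse = render_pulse(rr, fs, amplitude_scale=_vpc_amplitude_scale(rr, p))
    trace = render_rgb_trace(pulse, noise=noise or NoiseParams(),
                             seed=trace_seed, subject_id=subject_id)
    return SubjectRecord(subject_id=subject_id, label=label,
                         mean_hr=float(mean_hr), duration=float(duration),
                         rr=rr, trace=trace, seed=int(seed))


def subject_seed(master_seed: int, index: int) -> int:
    """Stable per-subject seed derived from the cohort master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0] % 2**31)


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort described by ``spec``.

    Subjects are enumerated class by class in the spec's key order;
    each gets a seed deterministically derived from (master_seed,
    index) and a duration drawn uniformly from ``duration_range``, so
    an identical spec always regenerates an identical cohort.
    """
    if spec.total < 1:
        raise ValueError("cohort spec has no subjects")
    records: list[SubjectRecord] = []
    index = 0
    for key, count in spec.n_per_class.items():
        label = RhythmLabel.from_key(key)
        for _ in range(count):
            seed = subject_seed(spec.master_seed, index)
            dur_rng = np.random.default_rng(
                np.random.SeedSequence([spec.master_seed, index, 1]))
            lo, hi = spec.duration_range
            duration = float(dur_rng.uniform(lo, hi)) if hi > lo else float(lo)
            sid = f"S{index:04d}"
            records.append(
                simulate_subject(label, duration, spec.noise, seed,
                                 fs=spec.fs, rr_params=spec.rr_params,
                                 subject_id=sid))
            index += 1
    return records
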