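"""Pulse extraction from RGB traces: chrominance projection, band-pass
filtering, heart-rate estimation and signal-quality control.

The observation model is the usual one for camera-based pulse
measurement: the mean skin color of a facial region is modulated a
fraction of a percent by the cardiac blood-volume pulse, on top of much
larger illumination and motion components.  The chrominance projection
(CHROM) combines the normalized color channels with fixed coefficients
chosen so that intensity (motion) variations cancel while the pulsatile
component survives; POS and a plain green-channel baseline are provided
as alternatives.  A fourth-order Chebyshev type-II band-pass (0.5-3 Hz,
the plausible heart-rate band) then suppresses drift and high-frequency
noise.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .simulate import RGBTrace

__all__ = [
    "Stage",
    "RPPGSignal",
    "FilterSpec",
    "ProjectionMethod",
    "roi_mean_rgb",
    "chrominance_project",
    "design_bandpass",
    "apply_bandpass",
    "estimate_hr",
    "quality_check",
    "QualityResult",
    "extract_rppg",
]

log = logging.getLogger(__name__)

HR_BAND = (0.5, 3.0)  # plausible heart-rate band, Hz


class Stage(str, enum.Enum):
    RAW = "RAW"
    FILTERED = "FILTERED"


class ProjectionMethod(str, enum.Enum):
    CHROM = "CHROM"
    POS = "POS"
    GREEN = "GREEN"


@dataclass(frozen=True)
class RPPGSignal:
    samples: np.ndarray
    fs: float
    stage: Stage = Stage.RAW
    subject_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "stage", Stage(self.stage))
        if not np.all(np.isfinite(samples)):
            raise ValueError("non-finite rPPG samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """A designed Chebyshev type-II band-pass filter.

    ``order`` is the analog prototype order (the band-pass transfer
    function has twice as many poles).  Coefficients are stored both as
    second-order sections (used for application, numerically robust)
    and as a single transfer function (b, a) for inspection.
    """

    fs: float
    f_lo: float = HR_BAND[0]
    f_hi: float = HR_BAND[1]
    order: int = 4
    stopband_attenuation_db: float = 40.0
    sos: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    b: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    a: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def poles(self) -> np.ndarray:
        return np.roots(self.a)

    def frequency_response(self, n_points: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """(frequencies_hz, complex_response) on an n-point grid to Nyquist."""
        w, h = scipy.signal.sosfreqz(self.sos, worN=n_points, fs=self.fs)
        return w, h


def design_bandpass(
    fs: float,
    f_lo: float = HR_BAND[0],
    f_hi: float = HR_BAND[1],
    order: int = 4,
    stopband_attenuation_db: float = 40.0,
) -> FilterSpec:
    """Design the heart-band Chebyshev-II band-pass and verify stability."""
    if not (0.0 < f_lo < f_hi < fs / 2.0):
        raise ValueError(
            f"band [{f_lo}, {f_hi}] Hz invalid for fs={fs} (need 0 < lo < hi < Nyquist)")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = scipy.signal.cheby2(order, stopband_attenuation_db, [f_lo, f_hi],
                              btype="bandpass", fs=fs, output="sos")
    b, a = scipy.signal.cheby2(order, stopband_attenuation_db, [f_lo, f_hi],
                               btype="bandpass", fs=fs)
    poles = np.roots(a)
    if poles.size and np.abs(poles).max() >= 1.0:
        raise ValueError("designed filter is unstable")
    return FilterSpec(fs=float(fs), f_lo=float(f_lo), f_hi=float(f_hi),
                      order=int(order),
                      stopband_attenuation_db=float(stopband_attenuation_db),
                      sos=sos, b=b, a=a)


def apply_bandpass(sig: RPPGSignal, spec: FilterSpec) -> RPPGSignal:
    """Zero-phase (forward-backward) band-pass; preserves beat timing.

    Offline processing permits the non-causal forward-backward pass, so
    the effective magnitude response is squared and the net phase is
    zero; output length equals input length.
    """
    if sig.fs != spec.fs:
        raise ValueError(f"signal fs {sig.fs} != filter fs {spec.fs}")
    out = scipy.signal.sosfiltfilt(spec.sos, sig.samples)
    return RPPGSignal(samples=out, fs=sig.fs, stage=Stage.FILTERED,
                      subject_id=sig.subject_id)


# ---------------------------------------------------------------------------
# ROI averaging and chrominance projection
# ---------------------------------------------------------------------------

def roi_mean_rgb(frames: np.ndarray, roi: tuple[int, int, int, int],
                 fs: float, subject_id: str = "") -> RGBTrace:
    """Average each color channel over a rectangular ROI, per frame.

    ``frames`` is (T, H, W, 3); ``roi`` is (row0, row1, col0, col1),
    half-open, and must be non-empty and inside the frame.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3:
        raise ValueError("frames must have shape (T, H, W, 3)")
    _, h, w, _ = frames.shape
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("roi empty or outside frame bounds")
    means = frames[:, r0:r1, c0:c1, :].mean(axis=(1, 2))
    return RGBTrace(r=means[:, 0].astype(float), g=means[:, 1].astype(float),
                    b=means[:, 2].astype(float), fs=fs, subject_id=subject_id)


DEFAULT_WINDOW_S = 1.6  # analysis window for windowed projections


def _overlap_add_project(trace: RGBTrace, window_s: float, project) -> np.ndarray:
    """Run a per-window projection with 50% overlap-add and a Hann taper.

    ``project(rgb_win)`` maps a (3, L) window of raw channel values to a
    length-L pulse estimate; windows are mean-centered by the projection
    itself.  The taper squares to a constant under 50% overlap, so the
    reconstruction is exact up to the edges.
    """
    n = len(trace)
    win_len = int(round(window_s * trace.fs))
    if n < win_len:
        raise ValueError(
            f"trace of {n} samples shorter than one {window_s}-s analysis window")
    hop = max(1, win_len // 2)
    taper = scipy.signal.windows.hann(win_len, sym=False)
    rgb = trace.channels
    out = np.zeros(n)
    norm = np.zeros(n)
    starts = list(range(0, n - win_len + 1, hop))
    if starts[-1] + win_len < n:  # cover the tail
        starts.append(n - win_len)
    for s in starts:
        seg = project(rgb[:, s:s + win_len])
        out[s:s + win_len] += taper * seg
        norm[s:s + win_len] += taper
    nz = norm > 1e-12
    out[nz] /= norm[nz]
    return out


def _chrom_window(rgb_win: np.ndarray) -> np.ndarray:
    means = rgb_win.mean(axis=1, keepdims=True)
    if np.any(means == 0):
        return np.zeros(rgb_win.shape[1])
    rn, gn, bn = rgb_win / means
    x = 3.0 * rn - 2.0 * gn
    y = 1.5 * rn + gn - 1.5 * bn
    x = x - x.mean()
    y = y - y.mean()
    sy = y.std()
    if sy < 1e-12:
        log.debug("zero-variance Y chrominance window; using X alone")
        return x
    return x - (x.std() / sy) * y


def _pos_window(rgb_win: np.ndarray) -> np.ndarray:
    means = rgb_win.mean(axis=1, keepdims=True)
    if np.any(means == 0):
        return np.zeros(rgb_win.shape[1])
    cn = rgb_win / means
    s1 = cn[1] - cn[2]               # G - B
    s2 = -2.0 * cn[0] + cn[1] + cn[2]  # -2R + G + B
    s1 = s1 - s1.mean()
    s2 = s2 - s2.mean()
    sd2 = s2.std()
    if sd2 < 1e-12:
        return s1
    return s1 + (s1.std() / sd2) * s2


def chrominance_project(
    trace: RGBTrace,
    method: ProjectionMethod | str = ProjectionMethod.CHROM,
    window_s: float = DEFAULT_WINDOW_S,
) -> RPPGSignal:
    """Project an RGB trace onto a single raw pulse channel.

    CHROM (default) and POS are windowed projections of the
    mean-normalized channels, combined by 50%-overlap-add with a Hann
    taper; both cancel common intensity modulation to first order.
    GREEN simply mean-centers the green channel and serves as the
    motion-sensitive baseline.
    """
    method = ProjectionMethod(method)
    if method is ProjectionMethod.GREEN:
        g = np.asarray(trace.g, dtype=float)
        return RPPGSignal(samples=g - g.mean(), fs=trace.fs,
                          stage=Stage.RAW, subject_id=trace.subject_id)
    project = _chrom_window if method is ProjectionMethod.CHROM else _pos_window
    out = _overlap_add_project(trace, window_s, project)
    return RPPGSignal(samples=out, fs=trace.fs, stage=Stage.RAW,
                      subject_id=trace.subject_id)


# ---------------------------------------------------------------------------
# Heart-rate estimate and quality control
# ---------------------------------------------------------------------------

def _band_periodogram(sig: RPPGSignal) -> tuple[np.ndarray, np.ndarray]:
    freqs, power = scipy.signal.periodogram(sig.samples, fs=sig.fs)
    mask = (freqs >= HR_BAND[0]) & (freqs <= HR_BAND[1])
    return freqs[mask], power[mask]


def estimate_hr(sig: RPPGSignal) -> float:
    """Heart rate in bpm: 60 x the periodogram argmax over 0.5-3 Hz.

    The periodogram is Welch-averaged (40-s windows, 50% overlap): the
    raw periodogram of an irregular rhythm is too erratic for its single
    largest bin to track the mean rate, while averaging concentrates the
    spectral mass around it.
    """
    if sig.stage is not Stage.FILTERED:
        raise ValueError("estimate_hr expects a FILTERED signal")
    if sig.duration < 10.0:
        raise ValueError("need at least 10 s of signal to estimate heart rate")
    nperseg = min(sig.samples.size, int(40.0 * sig.fs))
    freqs, power = scipy.signal.welch(sig.samples, fs=sig.fs, nperseg=nperseg)
    mask = (freqs >= HR_BAND[0]) & (freqs <= HR_BAND[1])
    return 60.0 * float(freqs[mask][np.argmax(power[mask])])


@dataclass(frozen=True)
class QualityResult:
    passed: bool
    snr_db: float | None  # None when undefined (e.g. all-zero signal)


DEFAULT_SNR_THRESHOLD_DB = 2.0


def quality_check(sig: RPPGSignal,
                  snr_threshold_db: float = DEFAULT_SNR_THRESHOLD_DB) -> QualityResult:
    """Spectral SNR gate mimicking the exclusion of unreadable recordings.

    SNR is the power within +/-0.1 Hz of the dominant in-band peak and
    its first harmonic, over the remaining in-band power, in dB.  A
    periodic pulse concentrates power at its rate and passes easily;
    broadband noise spreads power across the 2.5-Hz band and fails.
    """
    if sig.stage is not Stage.FILTERED:
        raise ValueError("quality_check expects a FILTERED signal")
    if sig.duration < 30.0:
        raise ValueError("need at least 30 s of signal for quality check")
    freqs, power = _band_periodogram(sig)
    total = float(power.sum())
    if total <= 0.0:
        return QualityResult(passed=False, snr_db=None)
    f0 = float(freqs[np.argmax(power)])
    near = np.zeros(freqs.size, dtype=bool)
    for fc in (f0, 2.0 * f0):
        near |= np.abs(freqs - fc) <= 0.1
    signal_p = float(power[near].sum())
    noise_p = total - signal_p
    if noise_p <= 0.0:
        return QualityResult(passed=True, snr_db=float("inf"))
    snr = 10.0 * np.log10(signal_p / noise_p)
    return QualityResult(passed=bool(snr >= snr_threshold_db), snr_db=float(snr))


def extract_rppg(
    trace: RGBTrace,
    method: ProjectionMethod | str = ProjectionMethod.CHROM,
    spec: FilterSpec | None = None,
) -> RPPGSignal:
    """Convenience path: chrominance projection followed by the band-pass."""
    raw = chrominance_project(trace, method)
    spec = spec or design_bandpass(trace.fs)
    return apply_bandpass(raw, spec)
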