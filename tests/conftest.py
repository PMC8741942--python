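import numpy as np
import pytest

import rppg_afib as ra


@pytest.fixture(scope="session")
def nsr_label():
    return ra.RhythmLabel(ra.RhythmGroup.NSR)


@pytest.fixture(scope="session")
def af_label():
    return ra.RhythmLabel(ra.RhythmGroup.AF)


@pytest.fixture(scope="session")
def default_filter():
    return ra.design_bandpass(84.0)


@pytest.fixture(scope="session")
def small_cohort_segments():
    """12 subjects (4 AF / 4 NSR / 4 OTHER), 2-min recordings, segmented;
    shared across tests that need a ready-made dataset."""
    spec = ra.CohortSpec(
        n_per_class={"AF": 4, "NSR": 4, "APC": 2, "SINUS_ARRHYTHMIA": 2},
        duration_range=(120.0, 120.0), master_seed=42)
    records = ra.simulate_cohort(spec)
    bp = ra.design_bandpass(84.0)
    subjects = []
    for rec in records:
        filtered = ra.apply_bandpass(ra.chrominance_project(rec.trace), bp)
        subjects.append((rec.subject_id, rec.label,
                         ra.segment_signal(filtered, 30.0)))
    return records, subjects


def make_filtered_tone(freq_hz: float, duration_s: float = 60.0,
                       fs: float = 84.0) -> ra.RPPGSignal:
    t = np.arange(int(duration_s * fs)) / fs
    return ra.RPPGSignal(samples=np.sin(2 * np.pi * freq_hz * t), fs=fs,
                         stage=ra.Stage.FILTERED)
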