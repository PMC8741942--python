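"""Fixed-length segmentation of filtered rPPG and binary task assembly.

A recording is cut into consecutive non-overlapping clips of
``seg_len`` seconds (default 30 s); the trailing remainder is
discarded, so a 10-min recording yields exactly 20 clips.  Each clip is
z-scored (pulse amplitude is in arbitrary units, so the classifier must
be scale-invariant) and inherits its subject's rhythm group as a binary
label under one of three tasks: AF vs NSR, AF vs other abnormalities,
or AF vs everything non-AF.  AF always maps to 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .rppg import RPPGSignal, Stage
from .simulate import RhythmGroup, RhythmLabel

__all__ = [
    "Segment",
    "Task",
    "TaskDataset",
    "segment_signal",
    "normalize_segment",
    "assemble_dataset",
    "task_label",
]

DEFAULT_SEG_LEN_S = 30.0


class Task(str, enum.Enum):
    AF_vs_NSR = "AF_vs_NSR"
    AF_vs_Others = "AF_vs_Others"
    AF_vs_NonAF = "AF_vs_NonAF"


@dataclass(frozen=True)
class Segment:
    """One fixed-length clip of a subject's filtered rPPG."""

    samples: np.ndarray
    subject_id: str
    segment_index: int
    fs: float
    seg_len: float = DEFAULT_SEG_LEN_S
    label01: int | None = None
    normalized: bool = False
    degenerate: bool = False  # constant input; z-scoring emitted zeros

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float32)
        object.__setattr__(self, "samples", samples)
        expected = int(round(self.seg_len * self.fs))
        if samples.size != expected:
            raise ValueError(
                f"segment length {samples.size} != seg_len*fs = {expected}")

    def __len__(self) -> int:
        return self.samples.size


def segment_signal(sig: RPPGSignal, seg_len: float = DEFAULT_SEG_LEN_S) -> list[Segment]:
    """Cut a filtered signal into floor(duration/seg_len) clips.

    Windows are anchored at sample 0 and non-overlapping; a signal
    shorter than one window yields an empty list.
    """
    if seg_len <= 0:
        raise ValueError("seg_len must be positive")
    if sig.stage is not Stage.FILTERED:
        raise ValueError("segment_signal expects a FILTERED signal")
    win = int(round(seg_len * sig.fs))
    n_seg = sig.samples.size // win
    return [
        Segment(samples=sig.samples[i * win:(i + 1) * win],
                subject_id=sig.subject_id, segment_index=i,
                fs=sig.fs, seg_len=float(seg_len))
        for i in range(n_seg)
    ]


def normalize_segment(seg: Segment) -> Segment:
    """Z-score one segment; a constant segment becomes all zeros and is
    flagged degenerate.  Idempotent to numerical precision."""
    x = seg.samples.astype(np.float64)
    sd = x.std()
    if sd < 1e-12:
        return replace(seg, samples=np.zeros_like(seg.samples),
                       normalized=True, degenerate=True)
    z = (x - x.mean()) / sd
    return replace(seg, samples=z.astype(np.float32), normalized=True,
                   degenerate=False)


def task_label(group: RhythmGroup | RhythmLabel, task: Task) -> int | None:
    """Binary label of a rhythm group under a task, or None if the group
    is excluded from that task.  AF maps to 1 in every task."""
    if isinstance(group, RhythmLabel):
        group = group.group
    group = RhythmGroup(group)
    task = Task(task)
    if group is RhythmGroup.AF:
        return 1
    if task is Task.AF_vs_NSR:
        return 0 if group is RhythmGroup.NSR else None
    if task is Task.AF_vs_Others:
        return 0 if group is RhythmGroup.OTHER else None
    return 0


@dataclass(frozen=True)
class TaskDataset:
    """All segments of one binary task, with a per-subject index."""

    task: Task
    segments: list[Segment]
    subject_index: dict[str, list[int]]       # subject_id -> segment positions
    subject_groups: dict[str, RhythmGroup]    # subject_id -> rhythm group

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_index)

    def labels(self) -> np.ndarray:
        return np.asarray([s.label01 for s in self.segments], dtype=int)

    def matrix(self) -> np.ndarray:
        """(n_segments, L) float32 design matrix of normalized clips."""
        return np.stack([s.samples for s in self.segments]).astype(np.float32)

    def subject_label(self, subject_id: str) -> int:
        return task_label(self.subject_groups[subject_id], self.task)  # type: ignore[return-value]


def assemble_dataset(
    subjects: list[tuple[str, RhythmLabel, list[Segment]]],
    task: Task | str,
    normalize: bool = True,
) -> TaskDataset:
    """Filter subjects by task, label their segments, and build the dataset.

    Every segment of a subject carries the subject's group-derived
    binary label (segment truth is inherited from the ECG-style subject
    diagnosis, not re-derived per clip).  Subjects whose group does not
    participate in the task are dropped; an empty class is an error.
    """
    task = Task(task)
    segments: list[Segment] = []
    subject_index: dict[str, list[int]] = {}
    subject_groups: dict[str, RhythmGroup] = {}
    for subject_id, label, segs in subjects:
        y = task_label(label, task)
        if y is None:
            continue
        if not segs:
            raise ValueError(f"subject {subject_id} has no segments")
        subject_index[subject_id] = []
        subject_groups[subject_id] = label.group
        for seg in segs:
            seg = normalize_segment(seg) if normalize and not seg.normalized else seg
            seg = replace(seg, label01=y, subject_id=subject_id)
            subject_index[subject_id].append(len(segments))
            segments.append(seg)
    labels = {s.label01 for s in segments}
    if labels != {0, 1}:
        raise ValueError(
            f"task {task.value} needs both classes after filtering, got labels {sorted(labels)}")
    return TaskDataset(task=task, segments=segments,
                       subject_index=subject_index,
                       subject_groups=subject_groups)
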