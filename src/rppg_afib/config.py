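"""Run configuration: one structured object covering every stage.

Defaults follow the emulated recording protocol wherever it fixes a
value: 84 Hz sampling, a 4th-order Chebyshev-II band-pass at 0.5-3 Hz,
30-s segments, 10 folds, a strict 0.5 voting threshold and a 15-300 s
sweep range.  Configs load from YAML; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluate import Grouping
from .net import TrainConfig
from .rppg import ProjectionMethod
from .segment import Task
from .simulate import NoiseParams, RRParams

__all__ = ["CohortConfig", "ExtractConfig", "CVConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass(frozen=True)
class CohortConfig:
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"AF": 6, "NSR": 6})
    duration_min_s: float = 300.0
    duration_max_s: float = 600.0
    fs: float = 84.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    rr_params: RRParams = field(default_factory=RRParams)


@dataclass(frozen=True)
class ExtractConfig:
    method: str = ProjectionMethod.CHROM.value
    f_lo_hz: float = 0.5
    f_hi_hz: float = 3.0
    filter_order: int = 4
    stopband_attenuation_db: float = 40.0
    # The spectral-SNR gate scores periodicity, so it penalizes genuinely
    # irregular rhythms (AF) as if they were poor recordings; it is off by
    # default and intended for cohorts of near-periodic rhythms or for
    # flagging rather than excluding.
    quality_gate: bool = False
    snr_threshold_db: float = 2.0


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    grouping: str = Grouping.SUBJECT_LEVEL.value
    call_threshold: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    seg_len_s: float = 30.0
    tasks: tuple[str, ...] = (Task.AF_vs_NonAF.value,)
    cv: CVConfig = field(default_factory=CVConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sweep_lengths_s: tuple[float, ...] = ()
    sweep_k: int = 4
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.seg_len_s <= 0:
            raise ValueError("seg_len_s must be positive")
        for t in self.tasks:
            Task(t)
        Grouping(self.cv.grouping)
        ProjectionMethod(self.extract.method)
        if not (0 < self.extract.f_lo_hz < self.extract.f_hi_hz
                < self.cohort.fs / 2):
            raise ValueError("band edges must satisfy 0 < lo < hi < Nyquist")
        for length in self.sweep_lengths_s:
            if not (15.0 <= length <= 300.0):
                raise ValueError("sweep lengths must lie in [15, 300] s")


_NESTED = {"cohort": CohortConfig, "extract": ExtractConfig, "cv": CVConfig,
           "train": TrainConfig, "noise": NoiseParams, "rr_params": RRParams}


def _build(cls, data: dict, context: str = ""):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in {context or cls.__name__}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, context=f"{context}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path_or_dict) -> RunConfig:
    """Load a RunConfig from a YAML file or an already-parsed mapping."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    return _build(RunConfig, data, context="run config")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))
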