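"""File formats: RGB traces, rPPG signals, cohort manifests, segment
containers and metrics reports.

All tabular formats are delimited text with headers; the segment
container is a single ``.npz`` per dataset (clips are runtime artifacts,
regenerated from config rather than archived).  Metrics reports are
JSON, written with sorted keys so a deterministic pipeline rerun
produces bit-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import CVResult, Grouping, MetricsReport
from .rppg import RPPGSignal, Stage
from .segment import Segment, Task
from .simulate import RGBTrace, RhythmLabel, SubjectRecord

__all__ = [
    "save_trace", "load_trace",
    "save_rppg", "load_rppg",
    "write_cohort_manifest", "read_cohort_manifest",
    "save_segments", "load_segments", "write_dataset_manifest",
    "write_metrics_report", "read_metrics_report",
    "write_roc", "write_sweep",
]

TRACE_HEADER = ["time_s", "r", "g", "b"]
TIME_JITTER_TOL_S = 1e-9


def save_trace(trace: RGBTrace, path) -> None:
    """Write a trace as ``time_s,r,g,b`` delimited text, full precision."""
    n = len(trace)
    time_s = np.arange(n) / trace.fs
    df = pd.DataFrame({"time_s": time_s, "r": trace.r, "g": trace.g,
                       "b": trace.b})
    df.to_csv(path, index=False, float_format="%.17g")


def load_trace(path, subject_id: str = "") -> RGBTrace:
    """Read a ``time_s,r,g,b`` trace; the sampling rate is inferred from
    the time column, which must be strictly increasing and constant-step
    to within 1 ns."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != TRACE_HEADER:
        raise ValueError(
            f"trace header must be {','.join(TRACE_HEADER)}, got "
            f"{','.join(map(str, df.columns))}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace needs at least two samples to infer fs")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time_s column must be strictly increasing")
    if np.abs(dt - dt.mean()).max() > TIME_JITTER_TOL_S:
        raise ValueError(
            f"sampling interval varies by more than {TIME_JITTER_TOL_S} s")
    fs = 1.0 / dt.mean()
    return RGBTrace(r=df["r"].to_numpy(float), g=df["g"].to_numpy(float),
                    b=df["b"].to_numpy(float), fs=float(fs),
                    subject_id=subject_id)


def save_rppg(sig: RPPGSignal, path, meta: dict | None = None) -> None:
    """Write ``time_s,value`` plus a ``.meta.json`` sidecar (stage, fs,
    extraction parameters)."""
    path = Path(path)
    n = sig.samples.size
    pd.DataFrame({"time_s": np.arange(n) / sig.fs,
                  "value": sig.samples}).to_csv(path, index=False,
                                                float_format="%.17g")
    sidecar = {"fs": sig.fs, "stage": sig.stage.value,
               "subject_id": sig.subject_id}
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=1))


def load_rppg(path) -> RPPGSignal:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "value"]:
        raise ValueError("rPPG file header must be time_s,value")
    sidecar = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    return RPPGSignal(samples=df["value"].to_numpy(float), fs=sidecar["fs"],
                      stage=Stage(sidecar["stage"]),
                      subject_id=sidecar.get("subject_id", ""))


MANIFEST_HEADER = ["subject_id", "group", "subtype", "duration_s",
                   "trace_path", "seed"]


def write_cohort_manifest(records: list[SubjectRecord], trace_paths: dict[str, str],
                          path) -> None:
    rows = [{"subject_id": r.subject_id, "group": r.label.group.value,
             "subtype": r.label.subtype.value, "duration_s": r.duration,
             "trace_path": trace_paths[r.subject_id], "seed": r.seed}
            for r in records]
    pd.DataFrame(rows, columns=MANIFEST_HEADER).to_csv(path, index=False)


def read_cohort_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != MANIFEST_HEADER:
        raise ValueError(f"manifest header must be {','.join(MANIFEST_HEADER)}")
    return df


# ---------------------------------------------------------------------------
# Segment container
# ---------------------------------------------------------------------------

def save_segments(subjects: list[tuple[str, RhythmLabel, list[Segment]]],
                  path) -> None:
    """Single-file container for the clips of many subjects: a ``.npz``
    holding the stacked clip matrix plus per-clip subject/group/index
    columns."""
    rows_x, sid, group, subtype, seg_idx = [], [], [], [], []
    fs = seg_len = None
    for subject_id, label, segs in subjects:
        for seg in segs:
            rows_x.append(seg.samples)
            sid.append(subject_id)
            group.append(label.group.value)
            subtype.append(label.subtype.value)
            seg_idx.append(seg.segment_index)
            fs, seg_len = seg.fs, seg.seg_len
    if not rows_x:
        raise ValueError("no segments to save")
    np.savez(path, x=np.stack(rows_x).astype(np.float32),
             subject_id=np.asarray(sid), group=np.asarray(group),
             subtype=np.asarray(subtype),
             segment_index=np.asarray(seg_idx, dtype=int),
             fs=np.asarray([fs]), seg_len=np.asarray([seg_len]))


def load_segments(path) -> list[tuple[str, RhythmLabel, list[Segment]]]:
    with np.load(path, allow_pickle=False) as data:
        x = data["x"]
        sid = data["subject_id"]
        group = data["group"]
        subtype = data["subtype"]
        seg_idx = data["segment_index"]
        fs = float(data["fs"][0])
        seg_len = float(data["seg_len"][0])
    subjects: dict[str, tuple[RhythmLabel, list[Segment]]] = {}
    for i in range(x.shape[0]):
        key = str(sid[i])
        if key not in subjects:
            sub = str(subtype[i])
            label = (RhythmLabel.from_key(str(group[i])) if sub == "NONE"
                     else RhythmLabel.from_key(sub))
            subjects[key] = (label, [])
        subjects[key][1].append(Segment(
            samples=x[i], subject_id=key, segment_index=int(seg_idx[i]),
            fs=fs, seg_len=seg_len, normalized=True))
    return [(k, v[0], v[1]) for k, v in subjects.items()]


# ---------------------------------------------------------------------------
# Metrics report
# ---------------------------------------------------------------------------

def write_dataset_manifest(ds, container_path, path) -> None:
    """Per-segment index of a task dataset:
    ``subject_id,segment_index,label01,task,path`` (one row per clip,
    ``path`` pointing at the segment container holding the payload)."""
    rows = [{"subject_id": seg.subject_id, "segment_index": seg.segment_index,
             "label01": seg.label01, "task": ds.task.value,
             "path": str(container_path)}
            for seg in ds.segments]
    pd.DataFrame(rows, columns=["subject_id", "segment_index", "label01",
                                "task", "path"]).to_csv(path, index=False)


REPORT_METRICS = ("sensitivity", "specificity", "ppv", "accuracy")


def _report_block(report: MetricsReport) -> dict:
    d = report.as_dict()
    d["undefined"] = sorted(m for m in REPORT_METRICS if d[m] is None)
    return d


def write_metrics_report(result: CVResult, path) -> None:
    """Serialize a cross-validation result: confusion counts and rates at
    segment and subject level, per-fold values with mean +/- sample SD,
    and the fold-grouping mode.  Undefined rates are written as null and
    listed under ``undefined`` rather than zeroed."""
    if result.segment_report is None or result.subject_report is None:
        raise ValueError("incomplete CV result: missing pooled reports")
    fold_stats = {}
    for metric in REPORT_METRICS + ("auc",):
        mean, sd = result.fold_mean_sd(metric)
        fold_stats[metric] = {"mean": mean, "sd": sd}
    payload = {
        "task": result.task.value,
        "grouping": result.grouping.value,
        "k": result.folds.k,
        "fold_seed": result.folds.seed,
        "segment": _report_block(result.segment_report),
        "subject": _report_block(result.subject_report),
        "folds_segment_level": [_report_block(r) for r in result.fold_reports],
        "fold_mean_sd": fold_stats,
        "subject_predictions": [
            {"subject_id": p.subject_id, "af_score": p.af_score,
             "predicted_af": p.predicted_af, "n_segments": p.n_segments}
            for p in result.subject_preds],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_metrics_report(path) -> dict:
    """Load a report; the segment/subject blocks are rebuilt as
    MetricsReport objects under ``segment_report``/``subject_report``."""
    payload = json.loads(Path(path).read_text())
    for key in ("segment", "subject"):
        block = payload[key]
        payload[key + "_report"] = MetricsReport(
            tp=block["tp"], fp=block["fp"], tn=block["tn"], fn=block["fn"],
            auc=block["auc"])
    payload["task"] = Task(payload["task"])
    payload["grouping"] = Grouping(payload["grouping"])
    return payload


def write_roc(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, index=False, float_format="%.17g")


def write_sweep(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")
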