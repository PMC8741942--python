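"""Cross-validation, segment voting, and diagnostic metrics.

The evaluation protocol mirrors the screening study design: segments
are partitioned into ten stratified folds, each fold serves once as the
hold-out set, every segment receives exactly one out-of-fold AF
probability, and a subject is called AF when strictly more than half of
their segment calls are AF.  Sensitivity, specificity, positive
predictive value and accuracy come from the confusion matrix against
the ground-truth rhythm group; ROC curves and AUC are computed both at
segment level (raw probabilities) and subject level (vote scores).

Fold grouping deserves a note: partitioning *segments* lets one
subject's clips appear in both train and test of a fold, which inflates
performance.  The default here is subject-grouped folds
(``Grouping.SUBJECT_LEVEL``); segment-level partitioning is available
as a fidelity mode and the reports name the mode used.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
import sklearn.metrics

from .net import ArchConfig, TrainConfig, default_arch, predict_proba, train_model
from .segment import Task, TaskDataset, assemble_dataset, segment_signal
from .simulate import SubjectRecord

__all__ = [
    "Grouping",
    "FoldAssignment",
    "SubjectPrediction",
    "MetricsReport",
    "CVResult",
    "make_folds",
    "cross_validate",
    "vote_subject",
    "subject_predictions",
    "confusion_metrics",
    "roc_auc",
    "segment_length_sweep",
]

DEFAULT_K = 10
SEGMENT_CALL_THRESHOLD = 0.5
VOTE_THRESHOLD = 0.5


class Grouping(str, enum.Enum):
    SEGMENT_LEVEL = "SEGMENT_LEVEL"
    SUBJECT_LEVEL = "SUBJECT_LEVEL"


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of_segment: np.ndarray  # fold id in 1..k per dataset segment
    grouping: Grouping
    seed: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fold_of_segment, dtype=int)
        object.__setattr__(self, "fold_of_segment", f)
        if f.size and (f.min() < 1 or f.max() > self.k):
            raise ValueError("fold ids must lie in 1..k")


@dataclass(frozen=True)
class SubjectPrediction:
    subject_id: str
    af_score: float          # fraction of segments called AF
    predicted_af: bool       # af_score strictly greater than 0.5
    n_segments: int


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus the four diagnostic rates and AUC.

    Rates are exact ratios of the integer counts; an undefined ratio
    (e.g. PPV with no positive predictions) is None, never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    def _rate(self, num: int, den: int) -> float | None:
        return float(Fraction(num, den)) if den else None

    @property
    def sensitivity(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float | None:
        total = self.tp + self.fp + self.tn + self.fn
        return self._rate(self.tp + self.tn, total)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "accuracy": self.accuracy, "auc": self.auc}


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def make_folds(ds: TaskDataset, k: int = DEFAULT_K,
               grouping: Grouping | str = Grouping.SUBJECT_LEVEL,
               seed: int = 0) -> FoldAssignment:
    """Stratified k-fold partition of the dataset.

    Units (segments, or whole subjects under SUBJECT_LEVEL) are
    shuffled within each class and dealt round-robin with a rolling
    fold pointer, so fold sizes differ by at most one unit overall and
    each class is spread evenly.  Under SUBJECT_LEVEL all segments of a
    subject land in one fold.
    """
    grouping = Grouping(grouping)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold_of_segment = np.zeros(ds.n_segments, dtype=int)

    if grouping is Grouping.SUBJECT_LEVEL:
        subjects = sorted(ds.subject_index)
        if k > len(subjects):
            raise ValueError(f"k={k} exceeds {len(subjects)} subjects")
        by_class: dict[int, list[str]] = {}
        for sid in subjects:
            by_class.setdefault(ds.subject_label(sid), []).append(sid)
        pointer = 0
        for cls in sorted(by_class):
            members = list(by_class[cls])
            rng.shuffle(members)
            for sid in members:
                fold = pointer % k + 1
                fold_of_segment[ds.subject_index[sid]] = fold
                pointer += 1
    else:
        labels = ds.labels()
        if k > labels.size:
            raise ValueError(f"k={k} exceeds {labels.size} segments")
        pointer = 0
        for cls in sorted(np.unique(labels)):
            members = np.flatnonzero(labels == cls)
            rng.shuffle(members)
            for idx in members:
                fold_of_segment[idx] = pointer % k + 1
                pointer += 1
    return FoldAssignment(k=int(k), fold_of_segment=fold_of_segment,
                          grouping=grouping, seed=int(seed))


# ---------------------------------------------------------------------------
# Voting and metrics
# ---------------------------------------------------------------------------

def vote_subject(segment_calls, subject_id: str = "") -> SubjectPrediction:
    """Aggregate per-segment AF calls into a subject decision.

    The AF score is the fraction of segments called AF; the subject is
    predicted AF only when the score strictly exceeds 0.5, so an exact
    50/50 split is a non-AF call.
    """
    calls = np.asarray(segment_calls, dtype=bool)
    if calls.size == 0:
        raise ValueError("cannot vote with zero segments")
    score = float(calls.sum()) / calls.size
    return SubjectPrediction(subject_id=subject_id, af_score=score,
                             predicted_af=bool(score > VOTE_THRESHOLD),
                             n_segments=int(calls.size))


def confusion_metrics(pred, truth, auc: float | None = None) -> MetricsReport:
    """Exact confusion-matrix rates from boolean predictions and truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be equal-length, non-empty")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc)


def roc_auc(scores, truth) -> tuple[pd.DataFrame, float]:
    """ROC curve over all distinct score thresholds plus trapezoidal AUC.

    Ties are handled by the rank convention, so the AUC equals the
    concordance probability P(score_pos > score_neg) + 0.5 P(equal).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("ROC requires both classes in truth")
    fpr, tpr, thresholds = sklearn.metrics.roc_curve(
        truth.astype(int), scores, drop_intermediate=False)
    auc = float(sklearn.metrics.roc_auc_score(truth.astype(int), scores))
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return curve, auc


def subject_predictions(ds: TaskDataset, segment_probs: np.ndarray,
                        call_threshold: float = SEGMENT_CALL_THRESHOLD
                        ) -> list[SubjectPrediction]:
    """Vote every subject of the dataset from per-segment probabilities."""
    preds = []
    for sid in sorted(ds.subject_index):
        calls = segment_probs[ds.subject_index[sid]] > call_threshold
        preds.append(vote_subject(calls, subject_id=sid))
    return preds


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    task: Task
    grouping: Grouping
    fold_reports: list[MetricsReport]               # segment-level, per fold
    oof_probs: np.ndarray                           # one out-of-fold prob/segment
    folds: FoldAssignment
    subject_preds: list[SubjectPrediction] = field(default_factory=list)
    subject_report: MetricsReport | None = None     # pooled out-of-fold votes
    segment_report: MetricsReport | None = None     # pooled segment calls
    subject_roc: pd.DataFrame | None = None
    segment_roc: pd.DataFrame | None = None

    def fold_mean_sd(self, metric: str) -> tuple[float, float]:
        """Mean and sample SD (n-1) of a rate across folds, skipping
        folds where it is undefined."""
        values = [getattr(r, metric) for r in self.fold_reports]
        values = np.asarray([v for v in values if v is not None], dtype=float)
        if values.size == 0:
            return float("nan"), 0.0
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        return float(values.mean()), sd


def cross_validate(ds: TaskDataset, folds: FoldAssignment,
                   cfg: TrainConfig, arch: ArchConfig | None = None,
                   call_threshold: float = SEGMENT_CALL_THRESHOLD) -> CVResult:
    """Train on k-1 folds, evaluate on the hold-out, k times.

    Every segment receives exactly one out-of-fold probability.  When
    ``cfg.ensemble > 1``, that probability is the average over models
    trained from different seeds on the same fold (seed averaging
    stabilizes the small-sample CNN fit at the cost of proportional
    training time).  The result carries per-fold segment-level reports
    (mean +/- SD across folds), pooled segment- and subject-level
    reports, and both ROC curves.  Subject metrics pool the out-of-fold
    votes of all subjects; per-fold averaging of subject metrics can be
    derived from ``folds`` if wanted.
    """
    if folds.fold_of_segment.size != ds.n_segments:
        raise ValueError("fold assignment does not match dataset size")
    labels = ds.labels()
    if arch is None:
        arch = default_arch(len(ds.segments[0]))
    oof = np.full(ds.n_segments, np.nan)
    fold_reports: list[MetricsReport] = []
    x = ds.matrix()
    for fold in range(1, folds.k + 1):
        test_mask = folds.fold_of_segment == fold
        train_mask = ~test_mask
        y_train = labels[train_mask]
        if np.unique(y_train).size < 2:
            raise ValueError(f"fold {fold}: training split lost a class")
        member_probs = []
        length = x.shape[1]
        n_shift = max(1, cfg.tta_shifts)
        shifts = [round(i * length / n_shift) for i in range(n_shift)]
        for member in range(max(1, cfg.ensemble)):
            fold_cfg = replace(cfg, seed=int(np.random.SeedSequence(
                [cfg.seed, fold, member]).generate_state(1)[0] % 2**31))
            model = train_model((x[train_mask], y_train), fold_cfg, arch)
            # clip labels are invariant to circular shifts, so predictions
            # are averaged over a few shifted views (test-time augmentation)
            member_probs.append(np.mean(
                [predict_proba(model, np.roll(x[test_mask], s, axis=1))
                 for s in shifts], axis=0))
        probs = np.mean(member_probs, axis=0)
        oof[test_mask] = probs
        y_test = labels[test_mask]
        if np.unique(y_test).size == 2:
            _, fold_auc = roc_auc(probs, y_test.astype(bool))
        else:
            fold_auc = None
        fold_reports.append(confusion_metrics(probs > call_threshold,
                                              y_test.astype(bool), auc=fold_auc))
    assert not np.isnan(oof).any(), "some segment missed its out-of-fold pass"

    seg_truth = labels.astype(bool)
    seg_roc, seg_auc = roc_auc(oof, seg_truth)
    segment_report = confusion_metrics(oof > call_threshold, seg_truth,
                                       auc=seg_auc)
    preds = subject_predictions(ds, oof, call_threshold)
    subj_truth = np.asarray([ds.subject_label(p.subject_id) == 1 for p in preds])
    subj_scores = np.asarray([p.af_score for p in preds])
    subj_called = np.asarray([p.predicted_af for p in preds])
    if subj_truth.any() and not subj_truth.all():
        subj_roc, subj_auc = roc_auc(subj_scores, subj_truth)
    else:
        subj_roc, subj_auc = None, None
    subject_report = confusion_metrics(subj_called, subj_truth, auc=subj_auc)
    return CVResult(task=ds.task, grouping=folds.grouping,
                    fold_reports=fold_reports, oof_probs=oof, folds=folds,
                    subject_preds=preds, subject_report=subject_report,
                    segment_report=segment_report, subject_roc=subj_roc,
                    segment_roc=seg_roc)


# ---------------------------------------------------------------------------
# Segment-length sensitivity sweep
# ---------------------------------------------------------------------------

def segment_length_sweep(
    records: list[SubjectRecord],
    signals: dict[str, "np.ndarray | object"],
    lengths: list[float],
    task: Task = Task.AF_vs_NonAF,
    k: int = 4,
    cfg: TrainConfig | None = None,
    grouping: Grouping | str = Grouping.SUBJECT_LEVEL,
    seed: int = 0,
    equalize_steps: bool = True,
) -> pd.DataFrame:
    """Subject-level accuracy as a function of segment length.

    For each length the filtered signals are re-segmented, the
    classifier re-trained under ``k``-fold grouped CV, subjects re-voted,
    and one row emitted.  A length exceeding the shortest recording is
    flagged (``feasible = False``) and reported with NaN accuracy, not
    silently dropped.  ``signals`` maps subject_id to the FILTERED
    RPPGSignal of that subject.

    Longer segments mean fewer training examples, so a fixed epoch
    count would hand the long-segment models far fewer gradient steps
    and confound the comparison; with ``equalize_steps`` (default) the
    epoch count of each row is scaled so every length receives the same
    optimization budget as the shortest one.
    """
    cfg = cfg or TrainConfig(epochs=10, patience=None)
    rows = []
    min_dur = min(r.duration for r in records)
    feasible_lengths = [l for l in lengths if l <= min_dur]
    base_len = min(feasible_lengths) if feasible_lengths else None
    for seg_len in lengths:
        if not (15.0 <= seg_len <= 300.0):
            raise ValueError("sweep lengths must lie in [15, 300] s")
        if seg_len > min_dur:
            rows.append({"seg_len_s": seg_len, "subject_accuracy": np.nan,
                         "n_subjects": 0, "feasible": False})
            continue
        subjects = []
        for rec in records:
            segs = segment_signal(signals[rec.subject_id], seg_len)
            if segs:
                subjects.append((rec.subject_id, rec.label, segs))
        ds = assemble_dataset(subjects, task)
        folds = make_folds(ds, k=k, grouping=grouping, seed=seed)
        row_cfg = cfg
        if equalize_steps and base_len is not None and seg_len > base_len:
            row_cfg = replace(cfg, epochs=int(round(
                cfg.epochs * seg_len / base_len)))
        result = cross_validate(ds, folds, row_cfg)
        rows.append({"seg_len_s": seg_len,
                     "subject_accuracy": result.subject_report.accuracy,
                     "n_subjects": ds.n_subjects, "feasible": True})
    return pd.DataFrame(rows)
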