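"""Folds, voting, confusion metrics, ROC/AUC and the CV contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rppg_afib as ra


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_vote(calls):
    n_af = sum(1 for c in calls if c)
    score = n_af / len(calls)
    return score, score > 0.5


def brute_confusion(pred, truth):
    tp = fp = tn = fn = 0
    for p, t in zip(pred, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def mann_whitney_auc(scores, truth):
    """Pairwise concordance probability, ties counted half."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def make_dataset(n_af=5, n_nsr=5, segs_per_subject=4, length=243):
    rng = np.random.default_rng(0)
    subjects = []
    for i in range(n_af + n_nsr):
        key = "AF" if i < n_af else "NSR"
        sid = f"s{i}"
        segs = [ra.Segment(samples=rng.standard_normal(length).astype(np.float32),
                           subject_id=sid, segment_index=j, fs=81.0,
                           seg_len=3.0)
                for j in range(segs_per_subject)]
        subjects.append((sid, ra.RhythmLabel.from_key(key), segs))
    return ra.assemble_dataset(subjects, ra.Task.AF_vs_NSR)


class TestMakeFolds:
    def test_segment_level_partition_balanced(self):
        ds = make_dataset(5, 5, 10)  # 100 segments
        folds = ra.make_folds(ds, 10, ra.Grouping.SEGMENT_LEVEL, seed=0)
        sizes = [int((folds.fold_of_segment == f).sum()) for f in range(1, 11)]
        assert sizes == [10] * 10

    def test_subject_level_keeps_subjects_whole(self):
        ds = make_dataset(6, 6, 5)
        folds = ra.make_folds(ds, 4, ra.Grouping.SUBJECT_LEVEL, seed=1)
        for sid, idxs in ds.subject_index.items():
            assert len(set(folds.fold_of_segment[idxs])) == 1

    def test_subject_level_stratified_and_balanced(self):
        ds = make_dataset(10, 10, 3)
        folds = ra.make_folds(ds, 5, ra.Grouping.SUBJECT_LEVEL, seed=2)
        per_fold = {f: set() for f in range(1, 6)}
        for sid, idxs in ds.subject_index.items():
            per_fold[folds.fold_of_segment[idxs[0]]].add(sid)
        sizes = sorted(len(v) for v in per_fold.values())
        assert max(sizes) - min(sizes) <= 1
        for members in per_fold.values():
            labels = {ds.subject_label(s) for s in members}
            assert labels == {0, 1}

    def test_too_many_folds_rejected(self):
        ds = make_dataset(3, 2, 4)
        with pytest.raises(ValueError):
            ra.make_folds(ds, 10, ra.Grouping.SUBJECT_LEVEL, seed=0)

    def test_deterministic_under_seed(self):
        ds = make_dataset(5, 5, 4)
        a = ra.make_folds(ds, 5, ra.Grouping.SUBJECT_LEVEL, seed=7)
        b = ra.make_folds(ds, 5, ra.Grouping.SUBJECT_LEVEL, seed=7)
        np.testing.assert_array_equal(a.fold_of_segment, b.fold_of_segment)


# ---------------------------------------------------------------------------
# Voting
# ---------------------------------------------------------------------------

class TestVoteSubject:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            calls = rng.random(rng.integers(1, 40)) > rng.random()
            pred = ra.vote_subject(calls)
            score, is_af = brute_vote(calls.tolist())
            assert pred.af_score == score
            assert pred.predicted_af == is_af

    def test_majority_strictness(self):
        p = ra.vote_subject([True] * 11 + [False] * 9)
        assert p.af_score == pytest.approx(0.55) and p.predicted_af
        tie = ra.vote_subject([True] * 10 + [False] * 10)
        assert tie.af_score == pytest.approx(0.5) and not tie.predicted_af

    def test_zero_segments_rejected(self):
        with pytest.raises(ValueError):
            ra.vote_subject([])


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

class TestConfusionMetrics:
    def test_worked_example(self):
        pred = [True] * 19 + [False] * 1 + [True] * 5 + [False] * 55
        truth = [True] * 20 + [False] * 60
        rep = ra.confusion_metrics(pred, truth)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (19, 1, 5, 55)
        assert rep.sensitivity == pytest.approx(0.95)
        assert rep.specificity == pytest.approx(55 / 60)
        assert rep.ppv == pytest.approx(19 / 24)
        assert rep.accuracy == pytest.approx(74 / 80)

    def test_all_correct(self):
        rep = ra.confusion_metrics([True, False], [True, False])
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.accuracy) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_undefined_ppv_flagged_not_zeroed(self):
        rep = ra.confusion_metrics([False, False], [True, False])
        assert rep.ppv is None

    def test_matches_naive_recount_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(1, 50))
            pred = rng.random(n) > 0.5
            truth = rng.random(n) > 0.5
            rep = ra.confusion_metrics(pred, truth)
            assert (rep.tp, rep.fp, rep.tn, rep.fn) == \
                tuple(np.array(brute_confusion(pred, truth))[[0, 1, 2, 3]])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ra.confusion_metrics([True], [True, False])


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = ra.roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = ra.roc_auc([0.5] * 6, [True, False] * 3)
        assert auc == 0.5

    def test_interleaved_example(self):
        _, auc = ra.roc_auc([0.9, 0.7, 0.8, 0.6],
                            [True, True, False, False])
        assert auc == pytest.approx(0.75)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_mann_whitney_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = rng.choice([0.1, 0.25, 0.5, 0.5, 0.75, 0.9], size=n)
        truth = rng.random(n) > 0.5
        if truth.all() or not truth.any():
            truth[0] = not truth[0]
        _, auc = ra.roc_auc(scores, truth)
        assert auc == pytest.approx(mann_whitney_auc(scores, truth), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ra.roc_auc([0.1, 0.9], [True, True])


# ---------------------------------------------------------------------------
# Cross-validation contract (tiny architecture for speed)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cv_result():
    ds = make_dataset(6, 6, 4, length=243)
    folds = ra.make_folds(ds, 3, ra.Grouping.SUBJECT_LEVEL, seed=0)
    arch = ra.default_arch(243, channel_widths=(4, 8))
    cfg = ra.TrainConfig(epochs=2, batch_size=16, seed=0, patience=None)
    return ds, folds, ra.cross_validate(ds, folds, cfg, arch)


class TestCrossValidate:

    def test_every_segment_scored_once_out_of_fold(self, cv_result):
        ds, folds, res = cv_result
        assert res.oof_probs.shape == (ds.n_segments,)
        assert np.isfinite(res.oof_probs).all()
        assert len(res.fold_reports) == folds.k

    def test_no_subject_spans_train_and_test(self, cv_result):
        ds, folds, _ = cv_result
        for fold in range(1, folds.k + 1):
            test_subjects = {ds.segments[i].subject_id
                             for i in np.flatnonzero(folds.fold_of_segment == fold)}
            train_subjects = {ds.segments[i].subject_id
                              for i in np.flatnonzero(folds.fold_of_segment != fold)}
            assert not (test_subjects & train_subjects)

    def test_subject_predictions_cover_all_subjects(self, cv_result):
        ds, _, res = cv_result
        assert {p.subject_id for p in res.subject_preds} == set(ds.subject_index)

    def test_vote_operating_point_lies_on_subject_roc(self, cv_result):
        """The fixed 0.5 vote threshold corresponds to a point on the
        subject-level ROC built from af_score thresholds."""
        ds, _, res = cv_result
        rep = res.subject_report
        fpr0 = rep.fp / (rep.fp + rep.tn)
        tpr0 = rep.tp / (rep.tp + rep.fn)
        curve = res.subject_roc
        found = ((np.isclose(curve["fpr"], fpr0, atol=1e-12))
                 & (np.isclose(curve["tpr"], tpr0, atol=1e-12))).any()
        assert found

    def test_identical_fold_accuracies_give_zero_sd(self):
        reports = [ra.confusion_metrics([True, False], [True, False])] * 4
        res = ra.CVResult(task=ra.Task.AF_vs_NSR,
                          grouping=ra.Grouping.SUBJECT_LEVEL,
                          fold_reports=reports, oof_probs=np.zeros(8),
                          folds=ra.FoldAssignment(4, np.ones(8, dtype=int),
                                                  ra.Grouping.SUBJECT_LEVEL, 0))
        mean, sd = res.fold_mean_sd("accuracy")
        assert mean == 1.0 and sd == 0.0


class TestSweepShape:
    def test_infeasible_length_flagged_not_dropped(self):
        spec = ra.CohortSpec(n_per_class={"AF": 3, "NSR": 3},
                             duration_range=(60.0, 60.0), master_seed=0)
        records = ra.simulate_cohort(spec)
        bp = ra.design_bandpass(84.0)
        signals = {r.subject_id: ra.apply_bandpass(
            ra.chrominance_project(r.trace), bp) for r in records}
        cfg = ra.TrainConfig(epochs=1, batch_size=8, seed=0, patience=None)
        table = ra.segment_length_sweep(records, signals, [20.0, 120.0],
                                        k=2, cfg=cfg, seed=0)
        assert len(table) == 2
        feasible = table[table.seg_len_s == 20.0].iloc[0]
        flagged = table[table.seg_len_s == 120.0].iloc[0]
        assert feasible["feasible"] and not flagged["feasible"]
        assert np.isnan(flagged["subject_accuracy"])
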