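"""Fold construction, metrics and the training contract."""

import numpy as np
import pytest

from forceskill.evaluation import (
    ConfusionCounts, FoldAssignment, MetricReport, TrainConfig,
    compute_metrics, default_louo_merges, evaluate_fold, louo_split,
    random_split, train_one_fold,
)
from forceskill.force_data import Cohort, ForceTrace, TrialRecord
from forceskill.models import ModelSpec
from forceskill.synthetic import CohortSpec, generate_cohort

from conftest import make_separable_trials


def brute_force_metrics(labels, preds):
    """Independent oracle: recount the four metrics from raw pairs."""
    labels, preds = np.asarray(labels), np.asarray(preds)
    tp = int(np.sum((labels == 1) & (preds == 1)))
    tn = int(np.sum((labels == 0) & (preds == 0)))
    fp = int(np.sum((labels == 0) & (preds == 1)))
    fn = int(np.sum((labels == 1) & (preds == 0)))
    out = {"accuracy": (tp + tn) / labels.size}
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["recall"] = tp / (tp + fn) if tp + fn else None
    out["f1"] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    return ConfusionCounts(tp, tn, fp, fn), out


class TestComputeMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(TP=2, TN=6, FP=1, FN=1))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_perfect_positive_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=7, TN=0, FP=0, FN=0))
        assert all(m[k] == 1.0 for k in ("accuracy", "precision", "recall", "f1"))

    def test_matches_brute_force_recount_on_random_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = int(rng.integers(1, 40))
            labels = rng.integers(0, 2, size=n)
            preds = rng.integers(0, 2, size=n)
            counts, oracle = brute_force_metrics(labels, preds)
            m = compute_metrics(counts)
            for k in m:
                if oracle[k] is None:
                    assert m[k] is None
                else:
                    assert m[k] == pytest.approx(oracle[k])

    def test_f1_is_harmonic_mean_of_precision_recall(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 30, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            p, r = m["precision"], m["recall"]
            if p is None or r is None or p + r == 0:
                continue
            assert m["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_undefined_metrics_reported_as_none_not_zero(self):
        m = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert m["precision"] is None and m["recall"] is None and m["f1"] is None
        assert m["accuracy"] == 1.0

    def test_report_mean_skips_undefined_with_warning(self):
        folds = [
            {"accuracy": 1.0, "precision": None, "recall": None, "f1": None},
            {"accuracy": 0.5, "precision": 0.5, "recall": 1.0, "f1": 2 / 3},
        ]
        with pytest.warns(UserWarning, match="undefined"):
            rep = MetricReport(per_fold=folds)
        assert rep.mean["accuracy"] == pytest.approx(0.75)
        assert rep.mean["precision"] == pytest.approx(0.5)


class TestRandomSplit:
    def test_18_trials_deal_3_per_fold(self):
        recs = [TrialRecord(ForceTrace(np.ones(30) * (k + 1)), "S1", "Expert", k + 1)
                for k in range(18)]
        cohort = Cohort(records=recs)
        folds = random_split(cohort, n_folds=6, seed=0)
        counts = np.bincount(list(folds.fold_of_trial.values()), minlength=6)
        np.testing.assert_array_equal(counts, 3)

    def test_folds_partition_all_trials(self):
        cohort = generate_cohort(CohortSpec(seed=4))
        folds = random_split(cohort, n_folds=6, seed=1)
        keys = {(r.surgeon_id, r.trial_index) for r in cohort.records}
        assert set(folds.fold_of_trial) == keys
        assert set(folds.fold_of_trial.values()) <= set(range(6))

    @pytest.mark.parametrize("n_trials", list(range(1, 21)))
    def test_per_surgeon_fold_counts_differ_by_at_most_one(self, n_trials):
        recs = [TrialRecord(ForceTrace(np.ones(10)), "S1", "Expert", k + 1)
                for k in range(n_trials)]
        folds = random_split(Cohort(records=recs), n_folds=6, seed=n_trials)
        counts = np.bincount([folds.fold_of_trial[("S1", k + 1)]
                              for k in range(n_trials)], minlength=6)
        assert counts.max() - counts.min() <= 1


class TestLouoSplit:
    @staticmethod
    def cohort_with(n_experts, n_novices, trials=3):
        recs = []
        for i in range(n_experts):
            for k in range(trials + (i % 2)):  # uneven counts
                recs.append(TrialRecord(ForceTrace(np.ones(20)), f"E{i+1}",
                                        "Expert", k + 1))
        for j in range(n_novices):
            for k in range(trials):
                recs.append(TrialRecord(ForceTrace(np.ones(20)), f"N{j+1}",
                                        "Novice", k + 1))
        return Cohort(records=recs)

    def test_seven_experts_six_novices_with_merge_gives_six_folds(self):
        cohort = self.cohort_with(7, 6)
        folds = louo_split(cohort, merges=[["E2", "E7"]])
        assert folds.n_folds == 6
        # merged experts travel together
        assert (folds.fold_of_trial[("E2", 1)] == folds.fold_of_trial[("E7", 1)])

    def test_unpairable_roster_suggests_merges(self):
        with pytest.raises(ValueError, match="merges"):
            louo_split(self.cohort_with(7, 6))

    def test_balanced_roster_needs_no_merge(self):
        folds = louo_split(self.cohort_with(6, 6))
        assert folds.n_folds == 6
        for k in range(6):
            surgeons = {sid for (sid, _), f in folds.fold_of_trial.items() if f == k}
            assert len(surgeons) == 2

    def test_no_surgeon_spans_folds(self):
        folds = louo_split(self.cohort_with(6, 6))
        fold_of_surgeon = {}
        for (sid, _), f in folds.fold_of_trial.items():
            assert fold_of_surgeon.setdefault(sid, f) == f

    def test_default_merges_pick_fewest_trial_experts(self):
        cohort = generate_cohort(CohortSpec(seed=3))
        merges = default_louo_merges(cohort)
        assert merges is not None and len(merges) == 1 and len(merges[0]) == 2
        expert_counts = {s.surgeon_id: s.n_trials for s in cohort.roster
                         if s.skill == "Expert"}
        merged_counts = sorted(expert_counts[sid] for sid in merges[0])
        assert merged_counts == sorted(expert_counts.values())[:2]
        folds = louo_split(cohort, merges=merges)
        assert folds.n_folds == 6


class TestEvaluateFold:
    class _Stub:
        """Fixed-prediction stand-in for a fitted model."""

        def __init__(self, prob_by_surgeon):
            self.prob_by_surgeon = prob_by_surgeon
            self.scaler = None
            self.input_transform = None
            self._queue = []

        def forward(self, inputs, **kw):
            return np.array([self._queue.pop(0)])

        def queue(self, records):
            self._queue = [self.prob_by_surgeon[r.surgeon_id] for r in records]
            return self

    @staticmethod
    def records():
        ramp = np.linspace(0, 1, 30)
        recs = [TrialRecord(ForceTrace(1.0 + ramp), "E1", "Expert", k + 1)
                for k in range(5)]
        recs += [TrialRecord(ForceTrace(5.0 + ramp), "N1", "Novice", k + 1)
                 for k in range(5)]
        return recs

    def test_all_correct(self):
        recs = self.records()
        model = self._Stub({"E1": 0.9, "N1": 0.1}).queue(recs)
        counts = evaluate_fold(model, recs)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (5, 5, 0, 0)

    def test_counts_sum_to_trials(self):
        recs = self.records()
        model = self._Stub({"E1": 0.4, "N1": 0.6}).queue(recs)
        assert evaluate_fold(model, recs).total == 10

    def test_flipping_predictions_swaps_counts(self):
        recs = self.records()
        a = evaluate_fold(self._Stub({"E1": 0.9, "N1": 0.6}).queue(recs), recs)
        b = evaluate_fold(self._Stub({"E1": 0.1, "N1": 0.4}).queue(recs), recs)
        assert (a.TP, a.FN) == (b.FN, b.TP)
        assert (a.TN, a.FP) == (b.FP, b.TN)


class TestTraining:
    @staticmethod
    def fold_last_trial_out(records):
        """Folds: trial_index == max goes to fold 0, rest to fold 1."""
        last = max(r.trial_index for r in records)
        fold_of = {(r.surgeon_id, r.trial_index): 0 if r.trial_index == last else 1
                   for r in records}
        return FoldAssignment(n_folds=2, fold_of_trial=fold_of, scheme="random")

    def test_memorizes_separable_set(self):
        recs = make_separable_trials(9, 9)
        cohort = Cohort(records=recs)
        folds = self.fold_last_trial_out(recs)
        cfg = TrainConfig(epochs=25, learning_rate=1e-3, batch_size=16, seed=0)
        model = train_one_fold(cohort, folds, 0, ModelSpec(arch="tcn", init_seed=0), cfg)
        train_recs = folds.trials_not_in_fold(cohort, 0)
        counts = evaluate_fold(model, train_recs)
        assert (counts.TP + counts.TN) / counts.total == 1.0

    def test_single_class_training_rejected(self):
        recs = [TrialRecord(ForceTrace(np.random.default_rng(k).uniform(1, 2, 50)),
                            "E1", "Expert", k + 1) for k in range(6)]
        cohort = Cohort(records=recs)
        folds = self.fold_last_trial_out(recs)
        with pytest.raises(ValueError, match="single class"):
            train_one_fold(cohort, folds, 0, ModelSpec(arch="tcn", init_seed=0),
                           TrainConfig(epochs=1, seed=0))

    def test_training_is_deterministic(self):
        recs = make_separable_trials(5, 5, length=80)
        cohort = Cohort(records=recs)
        folds = self.fold_last_trial_out(recs)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=3)
        outs = []
        for _ in range(2):
            model = train_one_fold(cohort, folds, 0,
                                   ModelSpec(arch="tcn", init_seed=3), cfg)
            outs.append(model.forward([np.ones((1, 80), dtype=np.float32)])[0])
        assert outs[0] == outs[1]

    def test_scaler_fitted_without_test_fold(self):
        recs = make_separable_trials(5, 5, length=60)
        cohort = Cohort(records=recs)
        folds = self.fold_last_trial_out(recs)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0)
        model = train_one_fold(cohort, folds, 0, ModelSpec(arch="tcn", init_seed=0), cfg)
        from forceskill.force_data import clip_negatives, fit_scaler
        expected = fit_scaler([clip_negatives(r.trace)
                               for r in folds.trials_not_in_fold(cohort, 0)])
        assert model.scaler == expected
        # and it differs from the scaler that would include the test fold
        tainted = fit_scaler([clip_negatives(r.trace) for r in cohort.records])
        assert model.scaler != tainted
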