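import numpy as np
import pandas as pd
import pytest

from oracles import recount_confusion
from pulseicp.evaluate import (EvalCounts, accuracy, classify_prediction,
                               crossvalidate, make_cv_plan, summarize_cv)
from pulseicp.recognize import make_recognizer
from pulseicp.types import PeakAssignment


class TestClassifyPrediction:
    @pytest.mark.parametrize("yhat, y, want", [
        (None, None, "TN"),
        (180.0, 180.0, "TP"),
        (180.0, 200.0, "FN"),
        (None, 200.0, "FN"),
        (180.0, None, "FP"),
    ])
    def test_confusion_branches(self, yhat, y, want):
        assert classify_prediction(yhat, y) == want


class TestAccuracy:
    def test_hand_enumerated_table(self):
        truths = [PeakAssignment(100.0, None, None)] * 3 \
            + [PeakAssignment(None, None, None),
               PeakAssignment(None, None, None),
               PeakAssignment(110.0, None, None)]
        preds = [PeakAssignment(100.0, None, None)] * 3 \
            + [PeakAssignment(None, None, None),
               PeakAssignment(90.0, None, None),
               PeakAssignment(None, None, None)]
        counts = EvalCounts.from_assignments(truths, preds)
        c = counts.counts["p1"]
        assert (c["TP"], c["TN"], c["FP"], c["FN"]) == (3, 1, 1, 1)

    def test_all_tn_is_perfect(self):
        truths = preds = [PeakAssignment(None, None, None)] * 4
        per_peak, overall = accuracy(EvalCounts.from_assignments(truths, preds))
        assert np.all(per_peak == 1.0) and overall == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            accuracy(EvalCounts())

    def test_matches_recount_oracle(self, rng):
        def random_assignment():
            vals = sorted(rng.uniform(0, 500, 3))
            lat = [v if rng.random() > 0.3 else None for v in vals]
            return PeakAssignment(*lat)

        truths = [random_assignment() for _ in range(300)]
        preds = [t if rng.random() > 0.5 else random_assignment()
                 for t in truths]
        counts = EvalCounts.from_assignments(truths, preds)
        want = recount_confusion([t.latencies for t in truths],
                                 [p.latencies for p in preds])
        for peak in ("p1", "p2", "p3"):
            assert dict(counts.counts[peak]) == want[peak]

    def test_order_invariance(self, rng):
        truths = [PeakAssignment(100.0 + i, 200.0 + i, None) for i in range(50)]
        preds = [PeakAssignment(100.0 + i, None, None) for i in range(50)]
        a = accuracy(EvalCounts.from_assignments(truths, preds))[1]
        order = rng.permutation(50)
        b = accuracy(EvalCounts.from_assignments(
            [truths[i] for i in order], [preds[i] for i in order]))[1]
        assert a == b


class TestCvPlan:
    def test_five_singleton_patients(self):
        plan = make_cv_plan(["a", "b", "c", "d", "e"], n_folds=5)
        assert sorted(plan.fold_of_patient.values()) == [0, 1, 2, 3, 4]

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_cv_plan(["a", "b"], n_folds=5)

    def test_balances_pulse_counts(self):
        patients = ["big"] * 50 + ["m1"] * 20 + ["m2"] * 20 + ["s1"] * 5 \
            + ["s2"] * 5 + ["s3"] * 4
        plan = make_cv_plan(patients, n_folds=3, rng_seed=1)
        loads = [0, 0, 0]
        from collections import Counter
        counts = Counter(patients)
        for p, f in plan.fold_of_patient.items():
            loads[f] += counts[p]
        assert max(loads) == 50  # the big patient sits alone in its fold


class TestCrossvalidate:
    def test_no_patient_leaks_between_train_and_test(self, small_annotated):
        plan = make_cv_plan([ap.patient_id for ap in small_annotated],
                            n_folds=3, rng_seed=0)

        seen = {}

        class SpyRecognizer:
            def fit(self, training):
                self.train_patients = {ap.patient_id for ap in training}
                return self

            def predict(self, pulse, candidates):
                seen.setdefault(id(self), set()).add(
                    frozenset(self.train_patients))
                return PeakAssignment(None, None, None)

        df = crossvalidate(small_annotated, SpyRecognizer, plan, rng_seed=0)
        by_fold = {ap.patient_id: plan.fold_of(ap.patient_id)
                   for ap in small_annotated}
        for fold in df["fold"]:
            test_patients = {p for p, f in by_fold.items() if f == fold}
            train_patients = {p for p, f in by_fold.items() if f != fold}
            assert test_patients.isdisjoint(train_patients)

    def test_deterministic_under_seed(self, small_annotated):
        plan = make_cv_plan([ap.patient_id for ap in small_annotated],
                            n_folds=3, rng_seed=4)
        factory = lambda: make_recognizer("gaussian")
        a = crossvalidate(small_annotated, factory, plan, rng_seed=4)
        b = crossvalidate(small_annotated, factory, plan, rng_seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_training_request_skipped(self, small_annotated):
        plan = make_cv_plan([ap.patient_id for ap in small_annotated],
                            n_folds=3, rng_seed=0)
        with pytest.warns(UserWarning, match="exceeds"):
            df = crossvalidate(small_annotated, lambda: make_recognizer("gaussian"),
                               plan, train_sizes=[10, 10_000], rng_seed=0)
        assert set(df["n_train"]) == {10}

    def test_summary_shape(self, small_annotated):
        plan = make_cv_plan([ap.patient_id for ap in small_annotated],
                            n_folds=3, rng_seed=0)
        df = crossvalidate(small_annotated, lambda: make_recognizer("gaussian"),
                           plan, train_sizes=[20, 40], rng_seed=0)
        s = summarize_cv(df)
        assert list(s["n_train"]) == [20, 40]
        assert {"A_mean", "A_sd", "n_folds"} <= set(s.columns)


class TestSanityCeiling:
    def test_all_recognizers_ace_a_separable_corpus(self):
        """On noise-free, always-triphasic, patient-homogeneous data every
        recognizer family should be nearly perfect with 500 training pulses."""
        from pulseicp.benchmark import cv_accuracy
        from pulseicp.evaluate import annotate_corpus
        from pulseicp.simulate import MorphologyProfile, make_corpus

        def clean_easy(rng):
            return MorphologyProfile((110.0, 210.0, 320.0), (5.0, 6.0, 7.0),
                                     (3.0, 2.4, 1.7), (0.25, 0.25, 0.2),
                                     (0.0, 0.0, 0.0), 0.02, 0.2, 0.05)

        corpus = make_corpus(8, 4, 25, 0.0, 7, easy_profile_fn=clean_easy)
        ann = annotate_corpus(corpus)
        for method in ("gaussian", "gmm", "sr", "ksr"):
            assert cv_accuracy(ann, method, train_size=500, seed=7) > 0.95
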