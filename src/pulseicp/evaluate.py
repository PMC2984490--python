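"""Scoring and patient-grouped cross-validation of peak recognizers.

Predictions are scored per peak against the ground-truth designation with
missing-aware confusion categories:

* TP — prediction equals the truth and both are present;
* FP — a peak is predicted where the truth is missing;
* TN — both missing;
* FN — the truth is present and the prediction is missing or different.

Per-peak accuracy is (TP + TN) / (TP + FP + TN + FN) and the overall
accuracy is the unweighted mean over the three peaks.  Cross-validation
groups all pulses of a patient into the same fold so no patient appears in
both train and test.
"""
from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .features import DEFAULT_SIGMA, candidates_from_pulse
from .simulate import SyntheticCorpus, ground_truth_designation
from .types import AnnotatedPulse, PeakAssignment, PEAK_NAMES

LABELS = ("TP", "FP", "TN", "FN")


def classify_prediction(yhat: Optional[float], y: Optional[float]) -> str:
    """Confusion category of one peak's prediction (exact-latency equality)."""
    if y is None:
        return "TN" if yhat is None else "FP"
    if yhat is not None and float(yhat) == float(y):
        return "TP"
    return "FN"


@dataclass
class EvalCounts:
    """Per-peak confusion tallies."""

    counts: dict = field(default_factory=lambda: {
        p: Counter({l: 0 for l in LABELS}) for p in PEAK_NAMES})

    @classmethod
    def from_assignments(cls, truths: Sequence[PeakAssignment],
                         predictions: Sequence[PeakAssignment]) -> "EvalCounts":
        if len(truths) != len(predictions):
            raise ValueError("truths and predictions differ in length")
        ec = cls()
        for t, p in zip(truths, predictions):
            for i, name in enumerate(PEAK_NAMES):
                ec.counts[name][classify_prediction(p.latencies[i],
                                                    t.latencies[i])] += 1
        return ec

    def n_evaluated(self, peak: str) -> int:
        return sum(self.counts[peak].values())


def accuracy(counts: EvalCounts) -> tuple:
    """(per-peak accuracies A_p as an array of 3, overall accuracy A)."""
    per_peak = np.empty(3)
    for i, name in enumerate(PEAK_NAMES):
        c = counts.counts[name]
        denom = sum(c[l] for l in LABELS)
        if denom == 0:
            raise ValueError(f"no evaluated pulses for peak {name}")
        per_peak[i] = (c["TP"] + c["TN"]) / denom
    return per_peak, float(per_peak.mean())


@dataclass(frozen=True)
class CvPlan:
    """Patient -> fold assignment for grouped cross-validation."""

    fold_of_patient: dict
    n_folds: int
    rng_seed: int

    def fold_of(self, patient_id) -> int:
        return self.fold_of_patient[patient_id]


def make_cv_plan(patient_of_pulse: Sequence, n_folds: int = 5,
                 rng_seed: int = 0) -> CvPlan:
    """Assign patients to folds, balancing pulse counts.

    Patients are shuffled (seeded), ordered by decreasing pulse count, and
    greedily placed into the currently lightest fold.
    """
    counts = Counter(patient_of_pulse)
    patients = sorted(counts)
    if len(patients) < n_folds:
        raise ValueError(f"{len(patients)} patients cannot fill {n_folds} folds")
    rng = np.random.default_rng(rng_seed)
    order = [patients[i] for i in rng.permutation(len(patients))]
    order.sort(key=lambda p: -counts[p])  # stable: seeded order breaks ties
    load = np.zeros(n_folds)
    assignment = {}
    for p in order:
        f = int(np.argmin(load))
        assignment[p] = f
        load[f] += counts[p]
    return CvPlan(fold_of_patient=assignment, n_folds=n_folds, rng_seed=rng_seed)


def annotate_corpus(corpus: SyntheticCorpus, sigma: float = DEFAULT_SIGMA,
                    gt_tol_ms: float = 10.0) -> list:
    """Detect candidates and derive ground-truth designations for a corpus."""
    out = []
    for sp in corpus.iter_pulses():
        cands = candidates_from_pulse(sp.waveform, sigma=sigma)
        truth = ground_truth_designation(sp.apexes, cands, tol_ms=gt_tol_ms)
        out.append(AnnotatedPulse(pulse=sp.waveform, candidates=cands,
                                  truth=truth, pulse_id=sp.pulse_id,
                                  file_id=sp.file_id, patient_id=sp.patient_id,
                                  is_hard=sp.is_hard))
    return out


def evaluate_recognizer(recognizer, test: Sequence[AnnotatedPulse]) -> EvalCounts:
    preds = [recognizer.predict(ap.pulse, ap.candidates) for ap in test]
    return EvalCounts.from_assignments([ap.truth for ap in test], preds)


def crossvalidate(annotated: Sequence[AnnotatedPulse],
                  recognizer_factory: Callable[[], object],
                  plan: CvPlan,
                  train_sizes: Optional[Sequence[int]] = None,
                  rng_seed: int = 0) -> pd.DataFrame:
    """Patient-grouped k-fold cross-validation with optional learning curve.

    For every fold and every requested training size ``n``, a fresh
    recognizer is trained on ``n`` pulses drawn (seeded) from the other
    folds and evaluated on the held-out fold.  ``train_sizes=None`` trains
    on all available pulses.  Returns one row per (fold, n) with per-peak
    and overall accuracies.
    """
    by_fold: dict[int, list] = defaultdict(list)
    for ap in annotated:
        by_fold[plan.fold_of(ap.patient_id)].append(ap)

    rows = []
    for fold in range(plan.n_folds):
        test = by_fold.get(fold, [])
        if not test:
            warnings.warn(f"fold {fold} holds no pulses; skipped")
            continue
        pool = [ap for f, aps in by_fold.items() if f != fold for ap in aps]
        sizes = list(train_sizes) if train_sizes is not None else [len(pool)]
        for n in sizes:
            if n > len(pool):
                warnings.warn(f"training size {n} exceeds the {len(pool)} "
                              f"pulses available outside fold {fold}; skipped")
                continue
            rng = np.random.default_rng([rng_seed, fold, n])
            train = [pool[i] for i in rng.choice(len(pool), size=n,
                                                 replace=False)]
            rec = recognizer_factory()
            rec.fit(train)
            counts = evaluate_recognizer(rec, test)
            per_peak, overall = accuracy(counts)
            rows.append({"fold": fold, "n_train": n,
                         "A_p1": per_peak[0], "A_p2": per_peak[1],
                         "A_p3": per_peak[2], "A": overall,
                         "n_test": len(test)})
    return pd.DataFrame(rows)


def summarize_cv(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and fold-SD of the overall accuracy per training size."""
    g = results.groupby("n_train")["A"]
    out = pd.DataFrame({"A_mean": g.mean(), "A_sd": g.std(ddof=1),
                        "n_folds": g.count()})
    return out.reset_index()


def plot_learning_curves(results_by_method: dict, path=None, ax=None):
    """Learning-curve figure: mean accuracy vs training size per method."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for method, df in results_by_method.items():
        s = summarize_cv(df)
        ax.errorbar(s["n_train"], 100 * s["A_mean"], yerr=100 * s["A_sd"],
                    marker="o", capsize=3, label=method)
    ax.set_xlabel("training pulses")
    ax.set_ylabel("overall accuracy A (%)")
    ax.legend()
    ax.grid(alpha=0.3)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
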