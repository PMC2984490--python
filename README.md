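# pulseicp

Peak recognition for intracranial-pressure (ICP) pulse waveforms.

Continuous ICP monitoring is standard care after traumatic brain injury,
and the *morphology* of the per-beat pressure pulse — which normally shows
three sub-peaks P1 (percussion), P2 (tidal) and P3 (dicrotic) — carries
information about intracranial compliance and patient state.  Turning raw
pressure traces into that morphology requires designating, on every beat,
which detected landmark is p1, p2 and p3, where any of the three may be
absent.  On common beats this is easy; on *challenging* beats (merged
peaks, unusual amplitude ordering, drift) simple latency priors fail, and
those are exactly the beats most likely to matter clinically.

`pulseicp` is a Python library for this task.  It provides:

* **Synthetic corpora** (`pulseicp.simulate`) — triphasic beats built from
  Gaussian components on a decaying baseline, organised as patients →
  files → pulses, with patient-specific morphology profiles, missing
  peaks, drift, residual noise and a continuous "challenge" axis that
  merges components into shoulders.  Everything downstream is testable
  without clinical recordings.
* **Preprocessing** (`pulseicp.preprocess`) — beat segmentation at
  supplied ECG-QRS onset times and a dominant (representative) pulse per
  3-minute segment via average-linkage clustering on correlation distance.
* **Differential features and candidates** (`pulseicp.features`) — the
  Gaussian-smoothed pulse `L`, backward differences `Lx = L(x) − L(x+1)`
  and `Lxx`, curvature `K = Lxx / (1 + Lx²)^{3/2}`, and peak candidates
  `a1..aN` at strict local maxima plus concave/convex intersections
  (merged-peak shoulders).  All channels are invariant to elevation shifts.
* **Three recognizer families** (`pulseicp.recognize`):
  * *Gaussian priors* — per-peak latency priors; the assignment
    maximises `J = P(X1=ax) + P(X2=ay) + P(X3=az)` over ordered candidate
    picks, with a density threshold ρ and an empty designation a0 for
    missing peaks;
  * *Gaussian mixture* — a full-covariance mixture over the joint
    latency triple fitted by EM with BIC component selection, recognised
    hierarchically (3-peak, then 2-dim marginals, then 1-dim) with
    thresholds τ3, τ2;
  * *Spectral regression (SR/KSR)* — graph-eigenvector embedding of the
    training pulses, ridge projection, affine readout to the three
    latencies, and nearest-candidate snapping; the kernel variant uses RBF
    features against the stored training set.
* **Error-weighted hard-example sampling** (`pulseicp.sampling`) — per-file
  weights `w_i = (E_p1+E_p2+E_p3)/(N_p1+N_p2+N_p3)` from a baseline's
  mistakes, two-stage sampling with `v_i = w_i / Σ w`, and the T1/T2
  training-library construction (uniform vs 50/50 uniform+weighted).
* **Evaluation** (`pulseicp.evaluate`) — missing-aware per-peak confusion
  (TP/FP/TN/FN), accuracy `A_p = (TP+TN)/(TP+FP+TN+FN)`, overall
  `A = (A_p1+A_p2+A_p3)/3`, and five-fold cross-validation grouped by
  patient so no patient leaks between train and test.

## Worked example

```python
import numpy as np
from pulseicp import (accuracy, annotate_corpus, make_corpus,
                      make_recognizer)
from pulseicp.evaluate import evaluate_recognizer

corpus = make_corpus(20, 4, 25, challenge_mix=0.5, rng_seed=7)
annotated = annotate_corpus(corpus)          # candidates + ground truth

patients = sorted({ap.patient_id for ap in annotated})
test_ids = set(patients[::5])
test = [ap for ap in annotated if ap.patient_id in test_ids]
pool = [ap for ap in annotated if ap.patient_id not in test_ids]
rng = np.random.default_rng(0)
train = [pool[i] for i in rng.choice(len(pool), 600, replace=False)]

rec = make_recognizer("sr", channels=("raw",), d=15, assign_delta=40.0)
per_peak, overall = accuracy(evaluate_recognizer(rec.fit(train), test))
print(f"A = {100*overall:.1f} %")
```

Running the full comparison in `examples/03_train_and_recognize.py` on
this corpus prints:

```
gaussian priors      A =  69.7 %   (p1 81.8, p2 65.0, p3 62.3)
joint GMM            A =  68.8 %   (p1 77.8, p2 67.5, p3 61.3)
spectral regression  A =  73.5 %   (p1 82.2, p2 70.5, p3 67.8)
kernel SR            A =  72.0 %   (p1 82.8, p2 68.0, p3 65.2)
```

Half of the test patients carry challenging morphology, so the global
latency priors trail the shape-based regressors; per-peak accuracies show
the familiar pattern that p1 (often legitimately absent, hence many easy
true negatives) scores higher than p2/p3.  The `examples/` directory holds
one short script per capability: corpus simulation, candidate detection,
recognizer training, weighted sampling, and learning curves.

There is also a thin CLI (`pulseicp simulate | extract | features | train |
recognize | sample | evaluate | pipeline`) over the same functions, with a
YAML-configured end-to-end pipeline.

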