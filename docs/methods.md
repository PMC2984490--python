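# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the open design decisions behind `pulseicp`.  Conventions used
throughout: latencies in milliseconds measured from the beat onset (ECG QRS
time), pressures in mmHg, 0-based sample indices, half-open beat intervals.
An absent peak is the value `None` (the empty designation a0).

## Problem

An ICP beat typically shows three sub-peaks (P1 percussion, P2 tidal, P3
dicrotic), any of which may be absent.  Given a beat and a set of detected
peak candidates, a recognizer must output the triple (p1, p2, p3), each
entry either one of the candidate latencies or "missing".  A prediction is
scored per peak: true positive when it equals the annotated candidate,
true negative when both sides agree the peak is absent, false
positive/negative otherwise; per-peak accuracy is (TP+TN)/(TP+FP+TN+FN)
and the overall accuracy the unweighted mean over the three peaks.

## Feature channels and candidate detection

The pulse is smoothed by Gaussian convolution (`sigma` = 3 samples by
default, edge replication).  Derivatives use the backward difference

    Lx(x)  = L(x) − L(x+1),      Lxx(x) = Lx(x) − Lx(x+1),

with the last element replicated to preserve length.  Note the
orientation: `Lx` is the *negated* slope (rising pressure ⇔ `Lx < 0`),
while `Lxx` double-negates and so carries the usual curvature sign.
Curvature is `K = Lxx / (1 + Lx²)^{3/2}`; its denominator is ≥ 1, so it is
finite everywhere.  All of `Lx`, `Lxx`, `K` are exactly invariant to a
constant elevation shift of the input.

Candidates are placed at

1. every strict local maximum of `L` (a fully formed peak), and
2. sign changes of `Lxx` that open a concave dome on a monotone stretch —
   `+→−` where `Lx > 0` (a shoulder on the descending side) and `−→+`
   where `Lx < 0` (a shoulder on the rising side).  These mark merged
   peaks that never become local maxima.

A run of exact zeros in `Lxx` places the change at the last index of the
run; candidates closer than one sample are merged (earlier kept).  A
deadband of `64·eps·max|L|` treats floating-point residue in `Lxx` as
zero, so affine stretches produce no spurious inflections.  With this rule
a noiseless unimodal bump yields exactly one candidate (its apex): the
bump's own inflections at ±1 SD fall on the wrong side of the slope test
by construction, which keeps the candidate list short and meaningful.
Whether detection should run on the raw or the smoothed second derivative
was an open choice; the smoothed channel is used.

## Recognizers

**Gaussian priors (baseline).**  Each peak has a Gaussian latency prior
(sample mean/SD of its non-missing training latencies; SD floored at 1 ms).
Recognition maximises the sum of per-peak densities over all assignments
of (p1, p2, p3) to candidates or a0, with strictly increasing latencies
among the non-empty picks.  A candidate scoring below the threshold ρ
contributes 0; a0 contributes exactly ρ, so "no candidate above threshold"
makes missing the argmax, and raising ρ can only increase the number of
missing outputs.  ρ defaults to the prior density at 3 SDs from the mean
(per peak).  Densities are unnormalised pdfs — the objective sums, not
multiplies, so no joint normalisation is implied.  Ties break toward
earlier latencies, then toward fewer missing entries.  The search prunes
exactly: when ρ > 0, a zero-scoring candidate is strictly dominated by a0.

**Joint-latency Gaussian mixture.**  Complete training triples are fitted
by EM (scikit-learn `GaussianMixture`, full covariance, k-means
initialisation with fixed seed, tolerance 1e-6, ≤ 500 iterations, ridge
jitter 1e-6 on covariances) for every component count C in 1..10; the C
minimising BIC wins.  Although the component density is printed
univariate in some treatments, the model here is explicitly 3-dimensional
with full covariances — the object being modelled is the *joint* latency
of the three peaks.  Recognition is hierarchical: the best strictly
increasing candidate triple under the full mixture is accepted if its
density reaches τ3; otherwise the three 2-dimensional marginal mixtures
(closed-form: sub-vectors of means, sub-blocks of covariances) are
evaluated over strictly increasing pairs against τ2; otherwise the single
best (peak, candidate) under the 1-dimensional marginals is designated.
τ3 and τ2 default to the 5th percentile of the training-set densities (of
the full triples and of their pooled pairwise marginals respectively) —
a data-adaptive calibration, since no canonical values exist.  Pairs are
required to be strictly increasing in latency, consistent with the
ordering constraint of the 3-peak stage.  The recognizer wrapper caps the
candidate C range at n/2 so small training draws stay fittable.

**Spectral regression (SR) and its kernel variant (KSR).**  Each training
pulse is vectorised: the first 500 ms resampled to s = 500 points (1
sample/ms) by linear interpolation and min-max normalised to [0, 1];
optional feature channels (`Lx`, `Lxx`, `K`) are resampled identically and
standardised with one mean/SD per channel block over the training set,
then rescaled to the raw block's overall spread.  Per-dimension
standardisation was rejected because it inflates the flat diastolic-tail
dimensions to unit variance and drowns the informative ones; block
rescaling keeps the concatenated modalities balanced in the neighbour
graph and the regression.  The graph W is a symmetrised binary k-nearest-
neighbour affinity (k = 5, ties by index; an edge when either endpoint
selects the other), a stand-in for the class-membership affinity that is
undefined for continuous latency targets.  The generalized eigenproblem
`W e = λ D e` (D = diagonal of column sums) is solved through the
symmetrically normalised adjacency; the trivial constant eigenvector is
identified by cosine similarity with √D and discarded, and each kept
eigenvector is scale-fixed to norm √n with its largest-magnitude entry
positive, making the embedding deterministic and stable under sample
duplication.  Each eigenvector is then expressed as a function of the
inputs: for SR by ridge least squares (SVD solve, λ = 1e-3·n by default);
for KSR by the kernel-ridge system `(K + λI) β = e` with
`K_ij = exp(−γ‖x_i−x_j‖²)` — the kernel trick applied to the regression
step only, with the graph still built on the input vectors.  The KSR
model necessarily retains its training inputs.  A final affine readout
maps the d-dimensional projection to the three latencies by ordinary
least squares.

Predictions are snapped to candidates greedily by increasing
|prediction − candidate|, each candidate used at most once; processing
pairs in distance order yields the matching whose sorted distance sequence
is lexicographically smallest.  A peak whose best remaining candidate is
farther than `assign_delta` stays missing; if the survivors violate
p1 < p2 < p3 the later-assigned offender is dropped.  The snapping radius
is the package's own device — the regression itself cannot produce a
missing peak, but the evaluation requires it.  Its default is 100 ms
(permissive); the benchmark experiments use 40 ms, roughly half the
typical inter-peak gap, because pilot runs showed the 100 ms radius makes
missing outputs almost unreachable and wastes the true-negative mass of
challenging data.

**Benchmark hyperparameters.**  The experiment configurations
(`pulseicp.benchmark.METHOD_CONFIGS`) fix the open spectral knobs once,
from a pilot run on a separate synthetic corpus (seed 999, never reused in
tests): embedding dimension d = 15 for linear SR, d = 25 and RBF bandwidth
γ = 3e-3 for KSR, snapping radius 40 ms, ridge default 1e-3·n.  Library
defaults are more conservative (d = 3, radius 100 ms) and all knobs are
exposed.

## Synthetic-data generator

The generator emulates *dominant* pulses — the cluster-averaged
representative beats that annotated pulse libraries consist of — not raw
bedside traces.  One beat (800 ms at 400 Hz by default, covering both
240 Hz and 400 Hz acquisition and the 500 ms analysis window) is

    pulse_pressure·exp(−t/450 ms) + 8 mmHg        (decaying baseline)
  + Σ present components  a_i · exp(−(t−l_i)²/2w_i²)   (Gaussian bumps)
  + drift_amplitude · sin(2π f t/T + φ)            (slow drift)
  + low-pass residual noise (white noise smoothed over 6 samples,
    rescaled to noise_sd)

with per-pulse draws of latencies (resampled up to 25 times until strictly
increasing, then a degenerate-profile error), amplitudes (floored at
0.3 mmHg), pulse pressure U(2.5, 6) mmHg, drift frequency and phase.
Component widths start at (16, 20, 24) ms and scale by (1 + 1.2·challenge),
so components merge into shoulders as the challenge level rises.
Smooth (low-pass) residual noise is deliberate: white noise at realistic
amplitude would cover the nearly flat diastolic tail with spurious local
maxima that an averaged beat does not have.

A component's *true apex* is where it observably manifests on the
deterministic waveform, located with the same curve geometry an annotator
works with — the nearest maximum-or-inflection landmark within 2.5
component SDs of the sampled latency, falling back to the generative
latency when components merge beyond recognition.  Ground truth for
recognition is then the nearest detected candidate within 10 ms of the
apex, else missing — mirroring annotation practice, where the annotator
picks the correct peak among automatically detected candidates.

**Patient profiles.**  Easy patients draw latency means around
(110, 210, 320) ms with 8 ms patient-level spread, P1-dominant amplitudes
(3.0, 2.3, 1.6) mmHg, missing probabilities (8, 4, 5) %, noise 0.05 mmHg,
drift 0.4 mmHg.  Challenging patients are assigned one of four recurring
morphology archetypes (merged early peaks with P2 dominance; elevated
dicrotic wave; delayed low-amplitude pulses with frequently absent P1;
widened triphasic) with patient-level jitter, wider latency SDs, noise
0.12 mmHg, drift 1.0 mmHg, challenge level U(0.6, 1.0), and a raised P1
missing rate (~26 %, matching the imbalance reported for hard clinical
files).  The archetype structure is essential and deliberate: challenging
clinical files are not idiosyncratic one-offs — the same uncommon patterns
recur across patients, which is precisely why training on sampled
challenging pulses transfers to new patients and why peak identity is
ambiguous for a single global latency prior (one archetype's p2 sits where
another's p1 or p3 does).

**What the generator does not model.**  No cardiovascular physiology (the
waveform is a geometric stand-in), no beat-to-beat correlation within a
file beyond the shared profile, no artifacts (coughing, probe drift), no
coupling between mean ICP elevation and morphology, and no ECG synthesis
(beat onsets are emitted directly).  Consequently, passing tests show the
pipeline's machinery is correct and that the qualitative method orderings
emerge under the modelled traits; they do not certify accuracy levels on
clinical recordings.

## Preprocessing

Beats are half-open windows between consecutive supplied onsets (QRS
detection is out of scope; onsets are trusted inputs).  Within each
3-minute segment, beats are resampled to a common length (500 samples,
or their shared native length when equal), clustered by average-linkage
agglomeration on distance 1 − Pearson correlation with the tree cut at
0.15, and the pointwise mean of the largest cluster is the dominant pulse,
reported at the median beat length of that cluster.  Size ties go to the
cluster whose centroid is closest to its members on average; flat
(zero-variance) beats are excluded with a warning because correlation
distance is undefined for them.  The linkage, distance and cut were open
choices; the recipe above is deterministic and standard.

## Error-weighted sampling and training libraries

Each file's weight is the fraction of wrongly designated peaks under a
baseline recognizer, `w = ΣE_p / ΣN_p`, where a designation is wrong
whenever it differs from the annotated one — missing mismatches count in
both directions — and `N_p` counts one designation slot per evaluated
pulse per peak, so `w = 1` means every peak in the file was designated
incorrectly.  Challenging pulses are drawn file-first with probability
`v_i = w_i/Σw`, then uniformly among the file's not-yet-taken pulses; an
exhausted file is removed and the probabilities renormalised (the
at-most-once rule makes some resolution necessary; renormalisation is the
documented one).  The two training libraries are T1, a uniform draw from
the easy reference pool, and T2, half uniform reference and half
error-weighted challenging pulses, equal total size.  The library
comparison trains both on the same recognizer and scores every corpus
pulse outside both libraries — a pulse-level holdout that mirrors the
original protocol, where the libraries are sampled from the corpus and
accuracy is reported on the corpus itself (patients are deliberately
shared between library and evaluation; the patient-grouped protocol is
used for the cross-validation experiments, not this one).

## Evaluation protocol

Fold assignment is by patient: patients are seeded-shuffled, ordered by
decreasing pulse count, and greedily placed into the lightest fold.  For
each fold and training size n, a fresh recognizer is trained on n pulses
drawn (seeded) from the other folds and scored on the held-out fold;
reported uncertainty is the SD of the overall accuracy across folds.
Equality of a prediction with the truth means the identical candidate
latency — no tolerance window — which is well-defined because ground truth
is itself chosen among the detected candidates.  The standard study corpus
is 20 patients × 4 files × 25 pulses = 2000 beats with a 50 % challenge
mix; learning curves use an all-challenging corpus of the same size with
training sizes (100, 250, 500, 1500).  These sizes keep a full study in
the low minutes on one CPU while leaving every method's learning curve
flat beyond ~500 training pulses.

## Numerical choices and degenerate inputs

* Prior SDs floored at 1 ms; GMM covariances regularised at 1e-6.
* Graph embedding via `eigsh` on the normalised adjacency with a fixed
  deterministic start vector; dense fallback for small n; a disconnected
  affinity graph draws a warning and a 1e-8 diagonal regulariser.
* Ridge solves use one thin SVD for all targets (SR) or a single
  symmetric solve (KSR).
* Flat pulses cannot be min-max normalised and raise; flat beats are
  excluded from clustering.
* The spectral embedding dimension is capped at n − 2 with a warning when
  complete-triple training data is scarce.
* CSV floats are written with 17 significant digits and parsed in
  round-trip mode, so corpus write/read is bitwise exact.
* All stochastic steps take explicit seeds; identical seeds give
  bitwise-identical corpora, models and result tables.

## Known limitations

* The challenge parametrisation is a stand-in for clinical hard pulses;
  absolute accuracies on synthetic corpora do not transfer to patients.
* The first-derivative input channel helps the spectral recognizer only
  mildly here: the generator's min-max-normalised raw input is already
  elevation-invariant and nearly noise-free, so much of the derivative's
  clinical advantage (robustness to elevation and acquisition noise) has
  little to bite on.
* Greedy snapping is lexicographic-optimal but not minimum-total-distance;
  the difference only matters when predictions are badly misplaced.
* The dominant-pulse step assumes a single morphology per 3-minute
  segment; segments spanning a morphology transition yield a centroid of
  the majority cluster only.
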