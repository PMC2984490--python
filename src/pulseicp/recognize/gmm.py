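"""Joint-latency Gaussian-mixture recognizer with hierarchical fallback.

The joint distribution of the three peak latencies is modelled as a
full-covariance Gaussian mixture in 3-dimensional latency space, fitted by
EM with the component count selected by BIC.  Recognition is hierarchical:
first the best ordered candidate triple is scored on the full mixture; if
its response falls below tau3, the three 2-dimensional marginal mixtures
are tried (threshold tau2); finally the 1-dimensional marginals designate a
single peak.  Marginalisation of a Gaussian mixture is closed form —
sub-vectors of the means and sub-blocks of the covariances.

EM fitting itself is delegated to scikit-learn's ``GaussianMixture``; this
module owns the model selection, the thresholds, and the recognition logic.
"""
from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import multivariate_normal
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from ..types import MISSING, AnnotatedPulse, CandidateSet, PeakAssignment

DEFAULT_C_RANGE = tuple(range(1, 11))
DEFAULT_TAU_PERCENTILE = 5.0
EM_TOL = 1e-6
EM_MAX_ITER = 500
_PAIR_DIMS = ((0, 1), (0, 2), (1, 2))


@dataclass
class GmmModel:
    """Mixture parameters over the joint latency triple, plus thresholds."""

    weights: np.ndarray      # (C,)
    means: np.ndarray        # (C, 3) ms
    covariances: np.ndarray  # (C, 3, 3)
    tau3: float
    tau2: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        self.means = np.asarray(self.means, dtype=float).reshape(-1, 3)
        self.covariances = np.asarray(self.covariances, dtype=float).reshape(-1, 3, 3)
        if not (1 <= self.n_components <= 10):
            raise ValueError("component count must lie in 1..10")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must be non-negative and sum to 1")

    @property
    def n_components(self) -> int:
        return int(self.weights.size)

    def pdf(self, points: np.ndarray, dims: Sequence[int] = (0, 1, 2)) -> np.ndarray:
        """Mixture density of the marginal over ``dims`` at ``points``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dims = tuple(dims)
        out = np.zeros(pts.shape[0])
        for w, mu, cov in zip(self.weights, self.means, self.covariances):
            sub_mu = mu[list(dims)]
            sub_cov = cov[np.ix_(dims, dims)]
            out += w * multivariate_normal.pdf(pts, mean=sub_mu, cov=sub_cov,
                                               allow_singular=True)
        return out

    def to_json(self) -> str:
        return json.dumps({
            "kind": "gmm", "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "tau3": self.tau3, "tau2": self.tau2,
        })

    @classmethod
    def from_json(cls, text: str) -> "GmmModel":
        d = json.loads(text)
        return cls(weights=np.array(d["weights"]), means=np.array(d["means"]),
                   covariances=np.array(d["covariances"]),
                   tau3=float(d["tau3"]), tau2=float(d["tau2"]))


def _complete_triples(training: Iterable) -> np.ndarray:
    rows = []
    for item in training:
        t = item.truth.latencies if isinstance(item, AnnotatedPulse) else (
            item.latencies if isinstance(item, PeakAssignment) else tuple(item))
        if len(t) != 3:
            raise ValueError("training entries must be (p1, p2, p3) triples")
        if all(v is not None for v in t):
            rows.append([float(v) for v in t])
    return np.asarray(rows, dtype=float)


def fit_gmm(training: Iterable,
            c_range: Sequence[int] = DEFAULT_C_RANGE,
            random_state: int = 0,
            tau_percentile: float = DEFAULT_TAU_PERCENTILE) -> GmmModel:
    """Fit the mixture by EM, selecting the component count by BIC.

    Only complete latency triples are used (the model's sample space is the
    full triple).  For every C in ``c_range`` EM runs to convergence from a
    k-means initialisation with a fixed seed; the C minimising BIC wins.
    The recognition thresholds default to the ``tau_percentile``-th
    percentile of the training densities (tau3 on the full mixture, tau2 on
    the pooled 2-dim marginals).
    """
    X = _complete_triples(training)
    c_range = sorted(int(c) for c in c_range)
    if not c_range or c_range[0] < 1:
        raise ValueError("c_range must contain positive integers")
    n = X.shape[0]
    if n < 2 * max(c_range):
        raise ValueError(
            f"need at least {2 * max(c_range)} complete triples to consider "
            f"C up to {max(c_range)}; got {n}")

    best_gm, best_bic = None, np.inf
    for C in c_range:
        gm = GaussianMixture(n_components=C, covariance_type="full",
                             tol=EM_TOL, max_iter=EM_MAX_ITER, n_init=1,
                             init_params="kmeans", reg_covar=1e-6,
                             random_state=random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic:
            best_gm, best_bic = gm, bic

    model = GmmModel(weights=best_gm.weights_, means=best_gm.means_,
                     covariances=best_gm.covariances_, tau3=0.0, tau2=0.0)
    model.tau3 = float(np.percentile(model.pdf(X), tau_percentile))
    marg = np.concatenate([model.pdf(X[:, list(d)], dims=d) for d in _PAIR_DIMS])
    model.tau2 = float(np.percentile(marg, tau_percentile))
    return model


def em_loglik_trace(X: np.ndarray, n_components: int, random_state: int = 0,
                    max_iter: int = 200) -> np.ndarray:
    """Total log-likelihood after each EM iteration (for monotonicity checks).

    Steps a warm-started EM one iteration at a time and records the total
    training log-likelihood after every step.
    """
    X = np.asarray(X, dtype=float)
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         tol=0.0, max_iter=1, n_init=1, warm_start=True,
                         init_params="kmeans", reg_covar=1e-6,
                         random_state=random_state)
    trace = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(X)
            total = float(gm.lower_bound_) * X.shape[0]
            if trace and abs(total - trace[-1]) < 1e-10 * max(1.0, abs(total)):
                trace.append(total)
                break
            trace.append(total)
    return np.asarray(trace)


def recognize_gmm(model: GmmModel, candidates: CandidateSet) -> PeakAssignment:
    """Hierarchical 3 -> 2 -> 1 peak recognition on the mixture.

    Stage 1 scores every strictly increasing candidate triple on the full
    mixture and accepts the best if its response reaches tau3.  Stage 2
    scores strictly increasing pairs on the three 2-dim marginals and
    accepts at tau2, leaving the third peak MISSING.  Stage 3 designates the
    single (peak, candidate) with the highest 1-dim marginal response.  A
    stage that needs more candidates than are available is skipped; an empty
    candidate set yields all MISSING.  Ties keep the earliest enumeration
    (earlier latencies, lower peak numbers first).
    """
    lat = candidates.latencies_ms
    n = lat.size

    if n >= 3:
        idx = np.array(list(itertools.combinations(range(n), 3)))
        dens = model.pdf(lat[idx])
        j = int(np.argmax(dens))
        if dens[j] >= model.tau3:
            a, b, c = (int(v) for v in idx[j])
            return PeakAssignment(float(lat[a]), float(lat[b]), float(lat[c]),
                                  source_indices=(a, b, c))

    if n >= 2:
        best = None  # (response, dims, (i, j)) — first max wins
        pair_idx = np.array(list(itertools.combinations(range(n), 2)))
        for dims in _PAIR_DIMS:
            dens = model.pdf(lat[pair_idx], dims=dims)
            j = int(np.argmax(dens))
            if best is None or dens[j] > best[0]:
                best = (float(dens[j]), dims, tuple(int(v) for v in pair_idx[j]))
        resp, dims, (i, j) = best
        if resp >= model.tau2:
            lats = [MISSING, MISSING, MISSING]
            srcs = [None, None, None]
            lats[dims[0]], srcs[dims[0]] = float(lat[i]), i
            lats[dims[1]], srcs[dims[1]] = float(lat[j]), j
            return PeakAssignment(lats[0], lats[1], lats[2],
                                  source_indices=tuple(srcs))

    if n >= 1:
        best = None  # (response, peak, cand)
        for peak in range(3):
            dens = model.pdf(lat[:, None], dims=(peak,))
            j = int(np.argmax(dens))
            if best is None or dens[j] > best[0]:
                best = (float(dens[j]), peak, j)
        _, peak, j = best
        lats = [MISSING, MISSING, MISSING]
        srcs = [None, None, None]
        lats[peak], srcs[peak] = float(lat[j]), j
        return PeakAssignment(lats[0], lats[1], lats[2], source_indices=tuple(srcs))

    return PeakAssignment.all_missing()


class GmmRecognizer:
    """Recognizer wrapper around the joint-latency mixture model.

    The candidate component range is capped at ``n_complete // 2`` at fit
    time so that small training draws remain fittable.
    """

    def __init__(self, c_range: Sequence[int] = DEFAULT_C_RANGE,
                 random_state: int = 0,
                 tau_percentile: float = DEFAULT_TAU_PERCENTILE):
        self.c_range = tuple(c_range)
        self.random_state = random_state
        self.tau_percentile = tau_percentile
        self.model: GmmModel | None = None

    def fit(self, training: Sequence[AnnotatedPulse]) -> "GmmRecognizer":
        X = _complete_triples(training)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 complete latency triples")
        cap = max(1, X.shape[0] // 2)
        c_range = [c for c in self.c_range if c <= cap] or [1]
        self.model = fit_gmm(X, c_range=c_range, random_state=self.random_state,
                             tau_percentile=self.tau_percentile)
        return self

    def predict(self, pulse, candidates: CandidateSet) -> PeakAssignment:
        if self.model is None:
            raise RuntimeError("recognizer is not fitted")
        return recognize_gmm(self.model, candidates)
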