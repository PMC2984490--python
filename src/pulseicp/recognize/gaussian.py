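"""Baseline recognizer: independent Gaussian latency priors.

Each peak has a Gaussian prior over its latency.  Recognition maximises the
sum of the three per-peak densities over ordered assignments of candidates,
with a density threshold rho guarding against false designations: a
candidate whose density falls below rho scores 0 for that peak, while the
empty designation a0 scores exactly rho.  With that convention "no candidate
above threshold" makes MISSING the argmax, and raising rho can only increase
the number of MISSING outputs.
"""
from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ..types import (MISSING, AnnotatedPulse, CandidateSet, PeakAssignment,
                     PEAK_NAMES)

SD_FLOOR_MS = 1.0
_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class GaussianPriorModel:
    """Per-peak Gaussian latency priors plus the density threshold rho."""

    mu: np.ndarray   # (3,) ms
    sd: np.ndarray   # (3,) ms
    rho: np.ndarray  # (3,) density threshold per peak

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        self.sd = np.asarray(self.sd, dtype=float).reshape(3)
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim == 0:
            rho = np.full(3, float(rho))
        self.rho = rho.reshape(3)
        if np.any(self.sd <= 0):
            raise ValueError("prior SDs must be positive")
        if np.any(self.rho < 0):
            raise ValueError("rho must be non-negative")

    def density(self, peak: int, latency_ms: np.ndarray) -> np.ndarray:
        """Unnormalised-joint Gaussian pdf of one peak's prior."""
        z = (np.asarray(latency_ms, dtype=float) - self.mu[peak]) / self.sd[peak]
        return np.exp(-0.5 * z * z) / (self.sd[peak] * _SQRT_2PI)

    def to_json(self) -> str:
        return json.dumps({"kind": "gaussian", "mu": self.mu.tolist(),
                           "sd": self.sd.tolist(), "rho": self.rho.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "GaussianPriorModel":
        d = json.loads(text)
        return cls(mu=np.array(d["mu"]), sd=np.array(d["sd"]),
                   rho=np.array(d["rho"]))


def _triples_from(training: Iterable) -> list:
    triples = []
    for item in training:
        if isinstance(item, AnnotatedPulse):
            triples.append(item.truth.latencies)
        elif isinstance(item, PeakAssignment):
            triples.append(item.latencies)
        else:
            t = tuple(item)
            if len(t) != 3:
                raise ValueError("training entries must be (p1, p2, p3) triples")
            triples.append(t)
    return triples


def fit_gaussian(training: Iterable, rho=None) -> GaussianPriorModel:
    """Fit per-peak latency priors from annotated training examples.

    ``training`` is an iterable of (p1, p2, p3) latency triples (``None``
    marks a missing peak), of :class:`PeakAssignment`, or of
    :class:`AnnotatedPulse`.  Each peak needs at least 2 non-missing
    observations.  SDs are floored at 1 ms to avoid degenerate priors.
    ``rho`` defaults to the prior density at 3 SDs from each mean.
    """
    triples = _triples_from(training)
    mu = np.empty(3)
    sd = np.empty(3)
    for i, name in enumerate(PEAK_NAMES):
        obs = np.array([t[i] for t in triples if t[i] is not None], dtype=float)
        if obs.size < 2:
            raise ValueError(
                f"peak {name} has {obs.size} non-missing training latencies; "
                f"need at least 2")
        mu[i] = obs.mean()
        sd[i] = max(obs.std(ddof=1), SD_FLOOR_MS)
    if rho is None:
        rho = np.exp(-4.5) / (sd * _SQRT_2PI)
    return GaussianPriorModel(mu=mu, sd=sd, rho=rho)


def recognize_gaussian(model: GaussianPriorModel,
                       candidates: CandidateSet) -> PeakAssignment:
    """Exhaustive maximisation of the summed prior densities.

    Every assignment of (p1, p2, p3) to candidates or the empty designation
    is scored; non-empty picks must be strictly increasing in latency.  A
    candidate scores its prior density (zeroed below rho); the empty
    designation scores rho.  Ties are broken toward earlier latencies, then
    toward fewer MISSING entries.
    """
    lat = candidates.latencies_ms
    n = lat.size
    scores = np.zeros((3, n))
    for i in range(3):
        d = model.density(i, lat)
        scores[i] = np.where(d >= model.rho[i], d, 0.0)

    # Exact pruning: when rho_i > 0, a zero-scoring candidate is strictly
    # dominated by a0 (same J minus rho_i, plus an ordering constraint), so
    # each peak only needs its above-threshold candidates plus a0.
    per_peak_options = []
    for i in range(3):
        if model.rho[i] > 0:
            opts = [j for j in range(n) if scores[i, j] > 0.0]
        else:
            opts = list(range(n))
        per_peak_options.append(opts + [-1])  # -1 encodes a0

    best = None  # (neg_J, lex latencies, n_missing, assignment triple)
    for x, y, z in itertools.product(*per_peak_options):
        picks = [(0, x), (1, y), (2, z)]
        lats = [lat[j] if j >= 0 else None for _, j in picks]
        present = [v for v in lats if v is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            continue
        J = sum(scores[i, j] if j >= 0 else model.rho[i] for i, j in picks)
        lex = tuple(v if v is not None else math.inf for v in lats)
        n_miss = sum(v is None for v in lats)
        key = (-J, lex, n_miss)
        if best is None or key < best[0]:
            best = (key, lats, (x if x >= 0 else None,
                                y if y >= 0 else None,
                                z if z >= 0 else None))
    _, lats, idx = best
    return PeakAssignment(lats[0], lats[1], lats[2], source_indices=idx)


class GaussianRecognizer:
    """Recognizer wrapper around the independent-Gaussian prior model."""

    def __init__(self, rho=None):
        self.rho = rho
        self.model: GaussianPriorModel | None = None

    def fit(self, training: Sequence[AnnotatedPulse]) -> "GaussianRecognizer":
        self.model = fit_gaussian(training, rho=self.rho)
        return self

    def predict(self, pulse, candidates: CandidateSet) -> PeakAssignment:
        if self.model is None:
            raise RuntimeError("recognizer is not fitted")
        return recognize_gaussian(self.model, candidates)
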