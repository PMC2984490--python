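"""Spectral-regression recognizers (SR and the RBF-kernel variant KSR).

SR learns a map from (optionally feature-augmented) pulse vectors to the
three peak latencies in three steps: (1) a k-nearest-neighbour affinity
graph W over the training vectors, (2) the top generalized eigenvectors of
W e = lambda D e (D = diagonal of column sums), which embed the training
pulses so that graph neighbours receive similar coordinates, and (3)
ridge-regularised least squares that expresses each nontrivial eigenvector
as a linear function of the inputs, followed by an affine readout from the
d-dimensional projection to the latency triple.  KSR replaces the input
vectors in the regression step by RBF kernel features against the training
set (the graph is still built on the raw input vectors), which makes the
predictor nonlinear at the price of keeping the training inputs inside the
model.

Predicted latencies are snapped to detected candidates greedily by
increasing |prediction - candidate|; a peak whose best remaining candidate
is farther than ``assign_delta`` is MISSING.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix, identity
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from ..features import compute_features
from ..types import (MISSING, AnnotatedPulse, CandidateSet, PeakAssignment,
                     PulseWaveform)

CHANNEL_ORDER = ("raw", "Lx", "Lxx", "K")
DEFAULT_S = 500
DEFAULT_WINDOW_MS = 500.0
DEFAULT_D = 3
DEFAULT_GRAPH_K = 5
DEFAULT_ASSIGN_DELTA_MS = 100.0
_EPS_DIAG = 1e-8


@dataclass(frozen=True)
class InputSpec:
    """How pulses are turned into input vectors."""

    s: int = DEFAULT_S
    window_ms: float = DEFAULT_WINDOW_MS
    channels: tuple = ("raw",)
    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.s < 2:
            raise ValueError("s must be >= 2")
        bad = [c for c in self.channels if c not in CHANNEL_ORDER]
        if bad:
            raise ValueError(f"unknown channels {bad}; allowed: {CHANNEL_ORDER}")
        ordered = tuple(c for c in CHANNEL_ORDER if c in self.channels)
        object.__setattr__(self, "channels", ordered)

    @property
    def n_feature_channels(self) -> int:
        return sum(1 for c in self.channels if c != "raw")

    @property
    def dim(self) -> int:
        return self.s * len(self.channels)


def _blocks(pulse: PulseWaveform, spec: InputSpec) -> np.ndarray:
    """Resample the analysis window of every enabled channel to s points.

    The raw block is min-max normalised to [0, 1] per pulse; feature-channel
    blocks are returned unscaled (training-set standardisation is applied by
    the fitted model).
    """
    grid = np.arange(spec.s) * (spec.window_ms / spec.s)
    t = pulse.times_ms
    out = []
    need_features = any(c != "raw" for c in spec.channels)
    channels = compute_features(pulse, spec.sigma) if need_features else None
    for name in spec.channels:
        if name == "raw":
            block = np.interp(grid, t, pulse.samples)
            lo, hi = block.min(), block.max()
            if hi <= lo:
                raise ValueError("cannot min-max normalise a flat pulse")
            block = (block - lo) / (hi - lo)
        else:
            block = np.interp(grid, t, channels.channel(name))
        out.append(block)
    return np.concatenate(out)


def vectorize(pulse: PulseWaveform, channels: Sequence[str] = ("raw",),
              s: int = DEFAULT_S, sigma: float = 3.0,
              window_ms: float = DEFAULT_WINDOW_MS) -> np.ndarray:
    """Input vector of one pulse (without training-set standardisation)."""
    return _blocks(pulse, InputSpec(s=s, window_ms=window_ms,
                                    channels=tuple(channels), sigma=sigma))


def _knn_affinity(X: np.ndarray, k: int) -> coo_matrix:
    """Symmetrised binary k-NN affinity (an edge if either end picks it).

    Neighbour ties are broken by index (stable argsort on squared
    distances).
    """
    n = X.shape[0]
    if k >= n:
        k = n - 1
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    W = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)
    W.data[:] = 1.0
    return W


def _graph_embedding(W, d: int) -> np.ndarray:
    """Top d nontrivial generalized eigenvectors of W e = lambda D e.

    Solved through the symmetrically normalised adjacency; the trivial
    constant eigenvector (lambda = 1) is identified by its cosine similarity
    with sqrt(D) and discarded.  Each eigenvector is scale- and sign-fixed
    (norm sqrt(n), largest-magnitude entry positive) so the embedding is
    deterministic and invariant to sample duplication.
    """
    n = W.shape[0]
    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        warnings.warn(f"affinity graph has {n_comp} connected components; "
                      "adding a diagonal regulariser", stacklevel=3)
        W = W + _EPS_DIAG * identity(n, format="csr")
    deg = np.asarray(W.sum(axis=0)).ravel()
    deg = np.maximum(deg, _EPS_DIAG)
    inv_sqrt = 1.0 / np.sqrt(deg)
    S = W.multiply(inv_sqrt[:, None]).multiply(inv_sqrt[None, :]).tocsr()

    k = min(d + 1, n - 1)
    if n <= max(2 * (d + 1), 12):
        vals, vecs = np.linalg.eigh(S.toarray())
        sel = np.argsort(vals)[::-1][:k]
        vals, vecs = vals[sel], vecs[:, sel]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = eigsh(S, k=k, which="LA", v0=v0)
        sel = np.argsort(vals)[::-1]
        vals, vecs = vals[sel], vecs[:, sel]

    sqrt_d = np.sqrt(deg)
    sqrt_d /= np.linalg.norm(sqrt_d)
    cos = np.abs(vecs.T @ sqrt_d)  # unit-norm columns
    trivial = int(np.argmax(cos))
    keep = [j for j in range(vecs.shape[1]) if j != trivial][:d]

    E = vecs[:, keep] * inv_sqrt[:, None]  # back to generalized eigenvectors
    for j in range(E.shape[1]):
        col = E[:, j]
        norm = np.linalg.norm(col)
        if norm > 0:
            col = col * (np.sqrt(n) / norm)
        if col[int(np.argmax(np.abs(col)))] < 0:
            col = -col
        E[:, j] = col
    return E


def _ridge_solve(X: np.ndarray, targets: np.ndarray, lam: float) -> np.ndarray:
    """Ridge least squares via the thin SVD (one factorisation, many targets)."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    shrink = s / (s * s + lam)
    return Vt.T @ (shrink[:, None] * (U.T @ targets))


@dataclass
class SrModel:
    """A fitted (kernel) spectral-regression latency predictor."""

    input_spec: InputSpec
    betas: np.ndarray            # (p, d) projection vectors
    readout_coef: np.ndarray     # (d, 3)
    readout_intercept: np.ndarray  # (3,)
    feat_mean: Optional[np.ndarray]  # standardisation of non-raw columns
    feat_sd: Optional[np.ndarray]
    ridge: float
    assign_delta: float = DEFAULT_ASSIGN_DELTA_MS
    graph_k: int = DEFAULT_GRAPH_K
    kernel_gamma: Optional[float] = None
    X_train: Optional[np.ndarray] = None  # kept only for the kernel variant

    @property
    def d(self) -> int:
        return int(self.betas.shape[1])

    @property
    def is_kernel(self) -> bool:
        return self.kernel_gamma is not None

    def transform(self, pulse: PulseWaveform) -> np.ndarray:
        """Standardised input vector of one pulse."""
        v = _blocks(pulse, self.input_spec)
        return self._standardize(v[None, :])[0]

    def _standardize(self, V: np.ndarray) -> np.ndarray:
        raw_dim = self.input_spec.s if "raw" in self.input_spec.channels else 0
        if self.feat_mean is not None and V.shape[1] > raw_dim:
            V = V.copy()
            V[:, raw_dim:] = (V[:, raw_dim:] - self.feat_mean) / self.feat_sd
        return V

    def predict_from_vectors(self, V: np.ndarray) -> np.ndarray:
        """Latency predictions (n, 3) from already-standardised vectors."""
        V = np.atleast_2d(V)
        if self.is_kernel:
            F = _rbf(V, self.X_train, self.kernel_gamma)
        else:
            F = V
        Z = F @ self.betas
        return Z @ self.readout_coef + self.readout_intercept

    def predict_latencies(self, pulse: PulseWaveform) -> np.ndarray:
        return self.predict_from_vectors(self.transform(pulse)[None, :])[0]

    def to_json(self) -> str:
        return json.dumps({
            "kind": "ksr" if self.is_kernel else "sr",
            "input_spec": {"s": self.input_spec.s,
                           "window_ms": self.input_spec.window_ms,
                           "channels": list(self.input_spec.channels),
                           "sigma": self.input_spec.sigma},
            "betas": self.betas.tolist(),
            "readout_coef": self.readout_coef.tolist(),
            "readout_intercept": self.readout_intercept.tolist(),
            "feat_mean": None if self.feat_mean is None else self.feat_mean.tolist(),
            "feat_sd": None if self.feat_sd is None else self.feat_sd.tolist(),
            "ridge": self.ridge, "assign_delta": self.assign_delta,
            "graph_k": self.graph_k, "kernel_gamma": self.kernel_gamma,
            "X_train": None if self.X_train is None else self.X_train.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "SrModel":
        d = json.loads(text)
        spec = InputSpec(s=d["input_spec"]["s"],
                         window_ms=d["input_spec"]["window_ms"],
                         channels=tuple(d["input_spec"]["channels"]),
                         sigma=d["input_spec"]["sigma"])
        opt = lambda v: None if v is None else np.array(v, dtype=float)
        return cls(input_spec=spec, betas=np.array(d["betas"]),
                   readout_coef=np.array(d["readout_coef"]),
                   readout_intercept=np.array(d["readout_intercept"]),
                   feat_mean=opt(d["feat_mean"]), feat_sd=opt(d["feat_sd"]),
                   ridge=float(d["ridge"]), assign_delta=float(d["assign_delta"]),
                   graph_k=int(d["graph_k"]),
                   kernel_gamma=d["kernel_gamma"], X_train=opt(d["X_train"]))


def _rbf(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    sq = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
          - 2.0 * (A @ B.T))
    np.clip(sq, 0.0, None, out=sq)
    return np.exp(-gamma * sq)


def _prepare_training(pulses, latencies, spec):
    Y = np.asarray(latencies, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 3 or not np.isfinite(Y).all():
        raise ValueError("latency targets must be an (n, 3) array of "
                         "complete triples")
    V = np.vstack([_blocks(p, spec) for p in pulses])
    raw_dim = spec.s if "raw" in spec.channels else 0
    feat_mean = feat_sd = None
    if V.shape[1] > raw_dim:
        # One mean/SD per channel block (not per dimension): per-dimension
        # scaling would inflate the flat-tail dimensions to unit variance
        # and drown the informative ones.  Each feature block is then scaled
        # to the raw block's overall spread so that no modality dominates
        # the neighbour graph or the regression.
        target = float(V[:, :raw_dim].std()) if raw_dim else 1.0
        target = max(target, 1e-8)
        feat_mean = np.empty(V.shape[1] - raw_dim)
        feat_sd = np.empty(V.shape[1] - raw_dim)
        for b in range((V.shape[1] - raw_dim) // spec.s):
            sl = slice(b * spec.s, (b + 1) * spec.s)
            block = V[:, raw_dim:][:, sl]
            feat_mean[sl] = block.mean()
            feat_sd[sl] = max(float(block.std()), 1e-8) / target
        V[:, raw_dim:] = (V[:, raw_dim:] - feat_mean) / feat_sd
    return V, Y, feat_mean, feat_sd


def _fit_common(V, Y, feat_mean, feat_sd, spec, d, graph_k, ridge,
                assign_delta, gamma):
    n = V.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 complete training pulses, got {n}")
    if n < d + 2:
        warnings.warn(f"embedding dimension capped at {n - 2} "
                      f"(only {n} complete training pulses)", stacklevel=3)
        d = n - 2
    lam = 1e-3 * n if ridge is None else float(ridge)
    if lam <= 0:
        raise ValueError("ridge must be positive")

    W = _knn_affinity(V, graph_k)
    E = _graph_embedding(W, d)

    if gamma is None:
        F = V
        betas = _ridge_solve(F, E, lam)
    else:
        # kernel trick on the regression step: (K + lam I) beta = e
        F = _rbf(V, V, gamma)
        betas = np.linalg.solve(F + lam * np.eye(n), E)

    Z = F @ betas
    design = np.column_stack([Z, np.ones(n)])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return SrModel(input_spec=spec, betas=betas, readout_coef=coef[:-1],
                   readout_intercept=coef[-1], feat_mean=feat_mean,
                   feat_sd=feat_sd, ridge=lam, assign_delta=assign_delta,
                   graph_k=graph_k, kernel_gamma=gamma,
                   X_train=V.copy() if gamma is not None else None)


def fit_sr(pulses: Sequence[PulseWaveform], latencies,
           channels: Sequence[str] = ("raw",), d: int = DEFAULT_D,
           graph_k: int = DEFAULT_GRAPH_K, ridge: Optional[float] = None,
           assign_delta: float = DEFAULT_ASSIGN_DELTA_MS,
           s: int = DEFAULT_S, sigma: float = 3.0) -> SrModel:
    """Fit linear spectral regression.

    ``latencies`` is an (n, 3) array of complete peak-latency triples.
    ``ridge`` defaults to 1e-3 * n.
    """
    spec = InputSpec(s=s, channels=tuple(channels), sigma=sigma)
    V, Y, fm, fsd = _prepare_training(pulses, latencies, spec)
    return _fit_common(V, Y, fm, fsd, spec, d, graph_k, ridge,
                       assign_delta, gamma=None)


def fit_ksr(pulses: Sequence[PulseWaveform], latencies,
            channels: Sequence[str] = ("raw",), d: int = DEFAULT_D,
            graph_k: int = DEFAULT_GRAPH_K, ridge: Optional[float] = None,
            gamma: Optional[float] = None,
            assign_delta: float = DEFAULT_ASSIGN_DELTA_MS,
            s: int = DEFAULT_S, sigma: float = 3.0) -> SrModel:
    """Fit kernel spectral regression (RBF features against the training set).

    ``gamma`` defaults to ``1 / (dim * var(X))``.  The training inputs are
    retained in the model — the price of the kernel projection.
    """
    spec = InputSpec(s=s, channels=tuple(channels), sigma=sigma)
    V, Y, fm, fsd = _prepare_training(pulses, latencies, spec)
    if gamma is None:
        v = float(V.var())
        gamma = 1.0 / (V.shape[1] * v) if v > 0 else 1.0
    return _fit_common(V, Y, fm, fsd, spec, d, graph_k, ridge,
                       assign_delta, gamma=float(gamma))


def greedy_match(yhat, latencies, delta: float):
    """One-to-one peak/candidate matching by increasing distance.

    Processing (peak, candidate) pairs in order of |prediction - candidate|
    yields the matching whose sorted distance sequence is lexicographically
    smallest.  Peaks whose best remaining candidate is farther than
    ``delta`` stay unassigned.  Returns (chosen latencies, source candidate
    indices, greedy assignment step) per peak.
    """
    lat = np.asarray(latencies, dtype=float)
    pairs = sorted((abs(float(yhat[i]) - float(lat[j])), i, j)
                   for i in range(3) for j in range(lat.size))
    chosen: list = [None, None, None]
    src: list = [None, None, None]
    order: list = [None, None, None]
    used: set[int] = set()
    step = 0
    for dist, i, j in pairs:
        if chosen[i] is not None or j in used or dist > delta:
            continue
        chosen[i], src[i], order[i] = float(lat[j]), j, step
        used.add(j)
        step += 1
    return chosen, src, order


def recognize_sr(model: SrModel, pulse: PulseWaveform,
                 candidates: CandidateSet) -> PeakAssignment:
    """Snap predicted latencies to the nearest candidates.

    Greedy one-to-one matching by increasing |prediction - candidate|
    (equivalently: the assignment whose sorted distance sequence is
    lexicographically smallest).  A peak whose best remaining candidate is
    farther than ``assign_delta`` stays MISSING, and if the surviving
    designations violate p1 < p2 < p3 the later-assigned offender is dropped.
    """
    lat = candidates.latencies_ms
    if lat.size == 0:
        return PeakAssignment.all_missing()
    yhat = model.predict_latencies(pulse)
    chosen, src, order = greedy_match(yhat, lat, model.assign_delta)

    # ordering repair: drop the later-assigned peak of any violating pair
    changed = True
    while changed:
        changed = False
        present = [i for i in range(3) if chosen[i] is not None]
        for a, b in zip(present, present[1:]):
            if chosen[b] <= chosen[a]:
                drop = b if order[b] > order[a] else a
                chosen[drop], src[drop], order[drop] = None, None, None
                changed = True
                break
    return PeakAssignment(chosen[0], chosen[1], chosen[2],
                          source_indices=tuple(src))


class _SpectralBase:
    kernel = False

    def __init__(self, channels: Sequence[str] = ("raw",), d: int = DEFAULT_D,
                 graph_k: int = DEFAULT_GRAPH_K, ridge: Optional[float] = None,
                 assign_delta: float = DEFAULT_ASSIGN_DELTA_MS,
                 s: int = DEFAULT_S, sigma: float = 3.0,
                 gamma: Optional[float] = None):
        self.params = dict(channels=tuple(channels), d=d, graph_k=graph_k,
                           ridge=ridge, assign_delta=assign_delta, s=s,
                           sigma=sigma)
        self.gamma = gamma
        self.model: SrModel | None = None

    def fit(self, training: Sequence[AnnotatedPulse]):
        pulses, rows = [], []
        for ap in training:
            t = ap.truth.latencies
            if all(v is not None for v in t):
                pulses.append(ap.pulse)
                rows.append([float(v) for v in t])
        Y = np.asarray(rows, dtype=float)
        if self.kernel:
            self.model = fit_ksr(pulses, Y, gamma=self.gamma, **self.params)
        else:
            self.model = fit_sr(pulses, Y, **self.params)
        return self

    def predict(self, pulse, candidates: CandidateSet) -> PeakAssignment:
        if self.model is None:
            raise RuntimeError("recognizer is not fitted")
        return recognize_sr(self.model, pulse, candidates)


class SrRecognizer(_SpectralBase):
    """Linear spectral-regression recognizer."""

    kernel = False


class KsrRecognizer(_SpectralBase):
    """RBF-kernel spectral-regression recognizer."""

    kernel = True
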