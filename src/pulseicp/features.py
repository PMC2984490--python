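"""Differential feature channels and inflection-based peak-candidate detection.

The smoothed pulse ``L`` is obtained by Gaussian convolution of the raw
signal.  Derivatives follow the backward-difference convention

    Lx(x)  = L(x)  - L(x+1)
    Lxx(x) = Lx(x) - Lx(x+1)

Note the orientation: ``Lx`` is the *negated* slope, so pressure is rising
wherever ``Lx < 0``.  ``Lxx`` double-negates and therefore carries the usual
curvature sign (negative on concave regions around a peak).  Everywhere in
this module "rising edge" means pressure increasing.

Candidates are placed at

* every strict local maximum of ``L`` (a fully formed peak), and
* sign changes of ``Lxx`` that open a concave dome on a monotone edge —
  the shoulder of a merged peak that never becomes a local maximum.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .types import CandidateSet, PulseWaveform

DEFAULT_SIGMA = 3.0  # smoothing scale, in samples


@dataclass(frozen=True)
class FeatureChannels:
    """Smoothed signal and its differential channels for one pulse."""

    L: np.ndarray
    Lx: np.ndarray
    Lxx: np.ndarray
    K: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        n = self.L.size
        if not (self.Lx.size == self.Lxx.size == self.K.size == n):
            raise ValueError("all feature channels must have the same length")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")

    def channel(self, name: str) -> np.ndarray:
        try:
            return {"raw": self.L, "L": self.L, "Lx": self.Lx,
                    "Lxx": self.Lxx, "K": self.K}[name]
        except KeyError:
            raise KeyError(f"unknown feature channel {name!r}") from None


def smooth(signal: np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Gaussian smoothing with edge replication; length preserving."""
    arr = np.asarray(signal, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot smooth an empty signal")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    return gaussian_filter1d(arr, sigma, mode="nearest")


def first_derivative(L: np.ndarray) -> np.ndarray:
    """Backward difference ``Lx(x) = L(x) - L(x+1)``, last element replicated."""
    arr = np.asarray(L, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    out = np.empty_like(arr)
    out[:-1] = arr[:-1] - arr[1:]
    out[-1] = out[-2]
    return out


def second_derivative(Lx: np.ndarray) -> np.ndarray:
    """Backward difference of the first derivative."""
    return first_derivative(Lx)


def curvature(Lx: np.ndarray, Lxx: np.ndarray) -> np.ndarray:
    """Curvature ``K = Lxx / (1 + Lx^2)^(3/2)`` (finite, denominator >= 1)."""
    a, b = np.asarray(Lx, dtype=float), np.asarray(Lxx, dtype=float)
    if a.shape != b.shape:
        raise ValueError("Lx and Lxx must have the same shape")
    return b / np.power(1.0 + a * a, 1.5)


def compute_features(pulse, sigma: float = DEFAULT_SIGMA) -> FeatureChannels:
    """Compute all channels for a pulse (array or :class:`PulseWaveform`)."""
    samples = pulse.samples if isinstance(pulse, PulseWaveform) else np.asarray(pulse, float)
    L = smooth(samples, sigma)
    Lx = first_derivative(L)
    Lxx = second_derivative(Lx)
    K = curvature(Lx, Lxx)
    return FeatureChannels(L=L, Lx=Lx, Lxx=Lxx, K=K, sigma=sigma)


def detect_candidates(channels: FeatureChannels, fs: float) -> CandidateSet:
    """Detect peak candidates on one pulse.

    Strict local maxima of the smoothed pulse are always candidates.  In
    addition, a concave dome opening on a monotone edge (a merged-peak
    shoulder) is marked at the sign change of ``Lxx``: a ``+ -> -`` change
    on the descending side (``Lx > 0`` in the backward-difference
    orientation) or a ``- -> +`` change on the rising side (``Lx < 0``).
    A run of exact zeros in ``Lxx`` places the change at the last index of
    the run.  Candidates closer than one sample are merged (earlier kept).
    """
    L, Lx, Lxx = channels.L, channels.Lx, channels.Lxx
    found: set[int] = set()

    if L.size >= 3:
        interior = np.flatnonzero((L[1:-1] > L[:-2]) & (L[1:-1] > L[2:])) + 1
        found.update(int(i) for i in interior)

    # Deadband against floating-point residue: double-differencing an
    # affine stretch leaves +-few-ulp noise in Lxx whose sign flips would
    # otherwise spawn spurious inflections on straight segments.
    eps = 64.0 * np.finfo(float).eps * max(1.0, float(np.max(np.abs(L))))
    sign = np.where(np.abs(Lxx) <= eps, 0.0, np.sign(Lxx))
    nz = np.flatnonzero(sign != 0)
    if nz.size >= 2:
        snz = sign[nz]
        changes = np.flatnonzero(snz[:-1] != snz[1:])
        for c in changes:
            a, b = int(nz[c]), int(nz[c + 1])
            idx = b - 1  # last index of the zero run (== a when adjacent)
            if snz[c] > 0 and snz[c + 1] < 0 and Lx[idx] > 0:
                found.add(idx)  # dome opens on the descending side
            elif snz[c] < 0 and snz[c + 1] > 0 and Lx[idx] < 0:
                found.add(idx)  # dome closes on the rising side

    indices: list[int] = []
    for idx in sorted(found):
        if not indices or idx - indices[-1] > 1:
            indices.append(idx)
    idx_arr = np.asarray(indices, dtype=int)
    lat = idx_arr * (1000.0 / fs)
    return CandidateSet(latencies_ms=lat, indices=idx_arr)


def candidates_from_pulse(pulse: PulseWaveform,
                          sigma: float = DEFAULT_SIGMA) -> CandidateSet:
    """Convenience wrapper: features + candidate detection in one call."""
    return detect_candidates(compute_features(pulse, sigma), pulse.fs)
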