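"""Beat segmentation and dominant-pulse extraction.

A continuous recording is split into beats at supplied onset times (ECG QRS
references; detecting them is out of scope — they are trusted inputs).
Within each fixed-length segment (3 minutes by default) the beats are
length-normalised, clustered by average-linkage agglomerative clustering on
correlation distance, and the centroid of the largest cluster is returned as
the segment's dominant pulse — a noise-robust representative beat.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import PulseWaveform

DEFAULT_SEGMENT_MS = 180_000.0  # 3-minute segments
DEFAULT_RESAMPLE_LEN = 500
DEFAULT_CUT_HEIGHT = 0.15  # correlation-distance tree cut


@dataclass(frozen=True)
class Recording:
    """A continuous ICP trace plus per-beat onset times."""

    samples: np.ndarray
    fs: float
    beat_onsets_ms: np.ndarray
    patient_id: str = ""
    file_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        onsets = np.asarray(self.beat_onsets_ms, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("samples must be a non-empty 1-d array")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if onsets.ndim != 1:
            raise ValueError("beat_onsets_ms must be 1-d")
        if onsets.size > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("beat onsets must be strictly increasing")
        span = arr.size * 1000.0 / self.fs
        if onsets.size and (onsets[0] < 0 or onsets[-1] > span + 1e-9):
            raise ValueError(
                f"beat onsets must lie within the sample span [0, {span:.3f}] ms")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "beat_onsets_ms", onsets)

    @property
    def duration_ms(self) -> float:
        return self.samples.size * 1000.0 / self.fs


def segment_beats(rec: Recording) -> list:
    """Split a recording into one pulse per consecutive onset pair.

    Beats are half-open intervals ``[onset_k, onset_{k+1})``; each returned
    pulse records its own onset, so latencies restart at 0 per beat.
    """
    onsets = rec.beat_onsets_ms
    if onsets.size < 2:
        raise ValueError("need at least 2 beat onsets to segment a recording")
    idx = np.round(onsets * rec.fs / 1000.0).astype(int)
    idx = np.clip(idx, 0, rec.samples.size)
    pulses = []
    for k in range(onsets.size - 1):
        i0, i1 = int(idx[k]), int(idx[k + 1])
        if i1 <= i0:
            raise ValueError(f"beat {k} spans no samples (onsets too close)")
        pulses.append(PulseWaveform(rec.samples[i0:i1], fs=rec.fs,
                                    onset_ms=float(onsets[k])))
    return pulses


@dataclass(frozen=True)
class DominantPulse:
    """Centroid of the largest beat cluster within one segment."""

    waveform: PulseWaveform
    segment_span: tuple  # [start_ms, end_ms) of the source segment
    n_member_pulses: int

    def __post_init__(self) -> None:
        if self.n_member_pulses < 1:
            raise ValueError("a dominant pulse must summarise >= 1 beat")


def _resample(y: np.ndarray, n_out: int) -> np.ndarray:
    if y.size == n_out:
        return y.astype(float, copy=False)
    x_old = np.linspace(0.0, 1.0, y.size)
    x_new = np.linspace(0.0, 1.0, n_out)
    return np.interp(x_new, x_old, y)


def _dominant_of_group(pulses: Sequence[PulseWaveform], span: tuple,
                       cut_height: float, resample_len: int) -> DominantPulse | None:
    fs = pulses[0].fs
    usable = []
    for p in pulses:
        if np.ptp(p.samples) == 0.0 or np.std(p.samples) == 0.0:
            warnings.warn("excluding a flat (zero-variance) pulse from "
                          "dominant-pulse clustering", stacklevel=3)
            continue
        usable.append(p)
    if not usable:
        warnings.warn("segment contained no usable pulses; skipped", stacklevel=3)
        return None
    if len(usable) == 1:
        return DominantPulse(waveform=usable[0], segment_span=span,
                             n_member_pulses=1)

    lengths = np.array([p.n_samples for p in usable])
    common = int(lengths[0]) if np.all(lengths == lengths[0]) else resample_len
    M = np.vstack([_resample(p.samples, common) for p in usable])

    corr = np.corrcoef(M)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance")

    uniq, sizes = np.unique(labels, return_counts=True)
    max_size = sizes.max()
    best_label, best_score = None, np.inf
    for lab, size in zip(uniq, sizes):
        if size != max_size:
            continue
        members = M[labels == lab]
        centroid = members.mean(axis=0)
        if np.std(centroid) == 0.0:
            score = np.inf
        else:
            c = np.corrcoef(np.vstack([centroid, members]))[0, 1:]
            score = float(np.mean(1.0 - c))
        if score < best_score:
            best_label, best_score = lab, score
    mask = labels == best_label
    centroid = M[mask].mean(axis=0)

    n_out = int(np.median(lengths[mask]))
    wave = _resample(centroid, n_out)
    return DominantPulse(
        waveform=PulseWaveform(wave, fs=fs, onset_ms=float(span[0])),
        segment_span=span, n_member_pulses=int(mask.sum()))


def dominant_pulse(pulses: Sequence[PulseWaveform],
                   segment_ms: float = DEFAULT_SEGMENT_MS,
                   cut_height: float = DEFAULT_CUT_HEIGHT,
                   resample_len: int = DEFAULT_RESAMPLE_LEN) -> list:
    """Extract one dominant pulse per ``segment_ms`` window of beats.

    Beats are grouped by their onset time into consecutive half-open
    segments.  Within each group, beats are resampled to a common length,
    clustered (average linkage, distance = 1 - Pearson correlation, tree cut
    at ``cut_height``), and the pointwise mean of the largest cluster is
    returned, reported at the median beat length of that cluster.  Ties in
    cluster size are broken toward the cluster whose centroid is closest to
    its members on average.  Empty or all-flat segments are skipped with a
    warning.  The result does not depend on the order of the input list.
    """
    if not pulses:
        raise ValueError("need at least one pulse")
    if segment_ms <= 0:
        raise ValueError("segment_ms must be positive")
    ordered = sorted(pulses, key=lambda p: (p.onset_ms,
                                            -p.n_samples,
                                            tuple(p.samples[:4])))
    groups: dict[int, list] = {}
    for p in ordered:
        groups.setdefault(int(p.onset_ms // segment_ms), []).append(p)

    out = []
    for key in sorted(groups):
        span = (key * segment_ms, (key + 1) * segment_ms)
        dom = _dominant_of_group(groups[key], span, cut_height, resample_len)
        if dom is not None:
            out.append(dom)
    return out
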