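"""Core value types shared across the pulse-analysis pipeline.

Conventions used throughout the package:

* latencies are in milliseconds, measured from the beat onset (the ECG
  QRS time of the beat);
* pressures are in mmHg;
* sample indices are 0-based and beat intervals are half-open;
* an absent peak is represented by :data:`MISSING` (``None``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MISSING: None = None
"""The empty peak designation (written a0 in the recognition objective)."""

#: Peak labels in physiological order.
PEAK_NAMES = ("p1", "p2", "p3")


@dataclass(frozen=True)
class PulseWaveform:
    """One beat's pressure samples.

    Parameters
    ----------
    samples:
        Pressure samples in mmHg, one beat long.
    fs:
        Sampling rate in Hz.
    onset_ms:
        Time of the beat onset (ECG QRS) in the source recording.  Latencies
        within the pulse are measured from this reference, i.e. sample 0 is
        latency 0.
    """

    samples: np.ndarray
    fs: float
    onset_ms: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("pulse samples must be a non-empty 1-d array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        """Latency of every sample, in ms from beat onset."""
        return np.arange(self.n_samples) * (1000.0 / self.fs)


@dataclass(frozen=True)
class CandidateSet:
    """Latencies of detected peak candidates a1..aN within one pulse.

    The empty designation a0 is not stored explicitly; recognizers always
    have it available (``includes_empty`` records the convention).
    """

    latencies_ms: np.ndarray
    indices: np.ndarray
    includes_empty: bool = True

    def __post_init__(self) -> None:
        lat = np.asarray(self.latencies_ms, dtype=float)
        idx = np.asarray(self.indices, dtype=int)
        if lat.shape != idx.shape or lat.ndim != 1:
            raise ValueError("latencies and indices must be matching 1-d arrays")
        if lat.size > 1 and not np.all(np.diff(lat) > 0):
            raise ValueError("candidate latencies must be strictly increasing")
        object.__setattr__(self, "latencies_ms", lat)
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.latencies_ms.size)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0


@dataclass(frozen=True)
class PeakAssignment:
    """The (p1, p2, p3) designation of one pulse.

    Each entry is either a candidate latency in ms or :data:`MISSING`.
    Latencies of the present peaks must be strictly increasing.
    """

    p1: Optional[float]
    p2: Optional[float]
    p3: Optional[float]
    source_indices: tuple = field(default=(None, None, None), compare=False)

    def __post_init__(self) -> None:
        present = [v for v in (self.p1, self.p2, self.p3) if v is not None]
        if any(b <= a for a, b in zip(present, present[1:])):
            raise ValueError(
                f"present peak latencies must be strictly increasing, got "
                f"({self.p1}, {self.p2}, {self.p3})"
            )

    @property
    def latencies(self) -> tuple:
        return (self.p1, self.p2, self.p3)

    @property
    def n_missing(self) -> int:
        return sum(v is None for v in self.latencies)

    def __iter__(self):
        return iter(self.latencies)

    @classmethod
    def all_missing(cls) -> "PeakAssignment":
        return cls(MISSING, MISSING, MISSING)


@dataclass
class AnnotatedPulse:
    """A pulse together with its candidates and ground-truth designation."""

    pulse: PulseWaveform
    candidates: CandidateSet
    truth: PeakAssignment
    pulse_id: str = ""
    file_id: str = ""
    patient_id: str = ""
    is_hard: bool = False
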