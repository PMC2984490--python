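"""Common recognizer interface and factory."""
from __future__ import annotations

from typing import Protocol, Sequence, runtime_checkable

from ..types import AnnotatedPulse, CandidateSet, PeakAssignment, PulseWaveform


@runtime_checkable
class PeakRecognizer(Protocol):
    """A trainable model that designates (p1, p2, p3) among candidates."""

    def fit(self, training: Sequence[AnnotatedPulse]) -> "PeakRecognizer":
        ...

    def predict(self, pulse: PulseWaveform, candidates: CandidateSet) -> PeakAssignment:
        ...


def make_recognizer(method: str, **params) -> PeakRecognizer:
    """Instantiate a recognizer by name: gaussian | gmm | sr | ksr."""
    from .gaussian import GaussianRecognizer
    from .gmm import GmmRecognizer
    from .spectral import KsrRecognizer, SrRecognizer

    registry = {
        "gaussian": GaussianRecognizer,
        "gmm": GmmRecognizer,
        "sr": SrRecognizer,
        "ksr": KsrRecognizer,
    }
    try:
        cls = registry[method.lower()]
    except KeyError:
        raise ValueError(f"unknown recognizer method {method!r}; "
                         f"choose one of {sorted(registry)}") from None
    return cls(**params)
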