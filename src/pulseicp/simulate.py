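"""Synthetic triphasic ICP pulse and corpus generator.

Real intracranial-pressure beats show up to three sub-peaks (P1 percussion,
P2 tidal, P3 dicrotic) riding on a decaying baseline, with pulse-to-pulse
latency and amplitude jitter, occasional missing peaks, slow drift and
acquisition noise.  The generator emulates those traits with Gaussian-shaped
components on an exponentially decaying baseline; "challenging" morphology
is obtained continuously by widening the components so that they merge into
shoulders, together with more latency dispersion, noise and drift.

Corpora are organised as patients -> files (recordings) -> pulses, with a
patient-specific :class:`MorphologyProfile` shared by all of the patient's
pulses, so that patient-grouped cross-validation is meaningful.

The generated beats stand for *dominant* pulses — the cluster-averaged
representative beats that peak-recognition libraries are built from — so
the default ``noise_sd`` values model the small residual noise left after
averaging, not raw acquisition noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .types import MISSING, CandidateSet, PeakAssignment, PulseWaveform

#: Profiles at or below this challenge level are considered "easy".
EASY_CHALLENGE_MAX = 0.2

#: Base widths (SD, ms) of the three Gaussian components at challenge 0.
_BASE_WIDTHS_MS = (16.0, 20.0, 24.0)

#: Mean-ICP offset added to every pulse (removed by elevation-invariant
#: features; kept for realism of raw traces).
_MEAN_ICP_MMHG = 8.0

_BASELINE_TAU_MS = 450.0
_NOISE_CORR_SAMPLES = 6.0  # correlation scale of residual noise, samples
_AMPLITUDE_FLOOR_MMHG = 0.3
_RETRY_CAP = 25

DEFAULT_FS_HZ = 400.0
DEFAULT_BEAT_MS = 800.0


class DegenerateProfileError(ValueError):
    """Raised when a profile cannot produce increasing component latencies."""


@dataclass(frozen=True)
class MorphologyProfile:
    """Patient-level generative parameters for triphasic pulses.

    ``latency_means``/``latency_sds`` (ms) and ``amplitude_means``/
    ``amplitude_sds`` (mmHg) describe per-pulse sampling of the three
    components; ``missing_probs`` gives the per-component probability of
    absence; ``challenge_level`` in [0, 1] widens the components so they
    overlap (1 = heavily merged morphology).
    """

    latency_means: tuple
    latency_sds: tuple
    amplitude_means: tuple
    amplitude_sds: tuple
    missing_probs: tuple
    noise_sd: float
    drift_amplitude: float
    challenge_level: float

    def __post_init__(self) -> None:
        for name in ("latency_means", "latency_sds", "amplitude_means",
                     "amplitude_sds", "missing_probs"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != 3:
                raise ValueError(f"{name} must have exactly 3 entries")
            object.__setattr__(self, name, vals)
        if not all(a < b for a, b in zip(self.latency_means, self.latency_means[1:])):
            raise ValueError("latency_means must be strictly increasing")
        if any(s < 0 for s in self.latency_sds + self.amplitude_sds):
            raise ValueError("standard deviations must be non-negative")
        if any(not 0.0 <= p <= 1.0 for p in self.missing_probs):
            raise ValueError("missing_probs must lie in [0, 1]")
        if not 0.0 <= self.challenge_level <= 1.0:
            raise ValueError("challenge_level must lie in [0, 1]")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be non-negative")

    @property
    def component_widths_ms(self) -> tuple:
        """Component SDs in ms; widen with challenge so components merge."""
        scale = 1.0 + 1.2 * self.challenge_level
        return tuple(w * scale for w in _BASE_WIDTHS_MS)

    @property
    def is_hard(self) -> bool:
        return self.challenge_level > EASY_CHALLENGE_MAX


def easy_profile(rng: np.random.Generator) -> MorphologyProfile:
    """Draw a patient profile with common, well-separated morphology.

    Population values: P1/P2/P3 latencies around 110/210/320 ms after the
    QRS with ~8 ms patient-level spread, P1-dominant amplitudes, missing
    rates close to the clinically observed ~8/4/5 %.
    """
    base = np.array([110.0, 210.0, 320.0]) + rng.normal(0.0, 8.0, 3)
    base.sort()
    return MorphologyProfile(
        latency_means=tuple(base),
        latency_sds=(6.0, 7.0, 8.0),
        amplitude_means=tuple(np.array([3.0, 2.3, 1.6]) + rng.normal(0.0, 0.25, 3)),
        amplitude_sds=(0.35, 0.35, 0.3),
        missing_probs=(0.08, 0.04, 0.05),
        noise_sd=0.05,
        drift_amplitude=0.4,
        challenge_level=float(rng.uniform(0.0, 0.15)),
    )


#: Recurring challenging-morphology archetypes.  Clinical hard files are not
#: idiosyncratic one-offs: the same uncommon patterns (rounded P2-dominant
#: domes, merged early peaks, elevated dicrotic waves, delayed low-amplitude
#: pulses) recur across patients, which is what makes training on sampled
#: challenging pulses transfer to new patients.
_CHALLENGE_ARCHETYPES = (
    dict(lat=(95.0, 150.0, 260.0), amp=(1.8, 2.9, 1.9), miss=(0.30, 0.05, 0.08)),
    dict(lat=(120.0, 230.0, 305.0), amp=(2.2, 1.9, 2.8), miss=(0.15, 0.08, 0.05)),
    dict(lat=(140.0, 250.0, 380.0), amp=(1.6, 2.4, 2.1), miss=(0.35, 0.05, 0.06)),
    dict(lat=(90.0, 185.0, 330.0), amp=(2.8, 2.0, 1.5), miss=(0.20, 0.08, 0.10)),
)


def challenging_profile(rng: np.random.Generator) -> MorphologyProfile:
    """Draw a patient profile with uncommon, merged-peak morphology.

    The patient is assigned one of the recurring challenging archetypes
    (peak-identity ambiguity across archetypes defeats global latency
    priors), with patient-level jitter on latencies and amplitudes, wide
    components that merge into shoulders, stronger drift, and a raised P1
    missing rate comparable to hard clinical files.
    """
    arch = _CHALLENGE_ARCHETYPES[int(rng.integers(len(_CHALLENGE_ARCHETYPES)))]
    base = np.array(arch["lat"]) + rng.normal(0.0, 8.0, 3)
    base.sort()
    return MorphologyProfile(
        latency_means=tuple(base),
        latency_sds=(9.0, 11.0, 13.0),
        amplitude_means=tuple(np.array(arch["amp"]) + rng.normal(0.0, 0.3, 3)),
        amplitude_sds=(0.45, 0.45, 0.4),
        missing_probs=arch["miss"],
        noise_sd=0.12,
        drift_amplitude=1.0,
        challenge_level=float(rng.uniform(0.6, 1.0)),
    )


def make_pulse(profile: MorphologyProfile,
               fs: float = DEFAULT_FS_HZ,
               duration_ms: float = DEFAULT_BEAT_MS,
               rng: Optional[np.random.Generator] = None,
               onset_ms: float = 0.0):
    """Generate one synthetic beat.

    Returns
    -------
    (pulse, apexes) :
        ``pulse`` is a :class:`~pulseicp.types.PulseWaveform`;
        ``apexes`` is a 3-tuple of true component apex times in ms
        (``None`` where the component is absent).
    """
    rng = np.random.default_rng(rng)
    if not fs > 0:
        raise ValueError("fs must be positive")
    if duration_ms <= max(profile.latency_means) + 3 * max(profile.latency_sds):
        raise ValueError("duration too short for the profile's latency range")

    n = int(round(duration_ms * fs / 1000.0))
    t = np.arange(n) * (1000.0 / fs)

    present = rng.random(3) >= np.asarray(profile.missing_probs)
    lats = None
    for _ in range(_RETRY_CAP):
        draw = rng.normal(profile.latency_means, profile.latency_sds)
        if np.all(np.diff(draw) > 0):
            lats = draw
            break
    if lats is None:
        raise DegenerateProfileError(
            "could not sample strictly increasing component latencies; "
            "latency_means too close relative to latency_sds")
    amps = np.maximum(rng.normal(profile.amplitude_means, profile.amplitude_sds),
                      _AMPLITUDE_FLOOR_MMHG)
    widths = np.asarray(profile.component_widths_ms)

    pulse_pressure = rng.uniform(2.5, 6.0)
    deterministic = pulse_pressure * np.exp(-t / _BASELINE_TAU_MS) + _MEAN_ICP_MMHG

    drift_freq = rng.uniform(0.5, 1.5)
    drift_phase = rng.uniform(0.0, 2.0 * math.pi)
    if profile.drift_amplitude > 0:
        deterministic = deterministic + profile.drift_amplitude * np.sin(
            2.0 * math.pi * drift_freq * t / duration_ms + drift_phase)

    for i in range(3):
        if present[i]:
            deterministic = deterministic + amps[i] * np.exp(
                -0.5 * ((t - lats[i]) / widths[i]) ** 2)

    # Residual noise of an averaged (dominant) pulse is low-pass, not white:
    # smooth a white draw and rescale it to the requested SD.
    white = rng.normal(0.0, 1.0, n)
    if profile.noise_sd > 0:
        smoothed = gaussian_filter1d(white, _NOISE_CORR_SAMPLES, mode="wrap")
        sd = smoothed.std()
        noise = profile.noise_sd * (smoothed / sd if sd > 0 else smoothed)
    else:
        noise = np.zeros(n)
    waveform = PulseWaveform(deterministic + noise, fs=fs, onset_ms=onset_ms)

    apexes = _component_apexes(deterministic, t, lats, widths, present, fs)
    return waveform, apexes


def _component_apexes(det: np.ndarray, t: np.ndarray, lats: np.ndarray,
                      widths: np.ndarray, present: np.ndarray,
                      fs: float) -> tuple:
    """True apex time of each present component on the noiseless waveform.

    A component's apex is where it observably manifests on the deterministic
    waveform, located by the same curve geometry an annotator works with: a
    local maximum for a separated component, the inflection marking the
    shoulder dome for a merged one.  Each present component takes the
    nearest such landmark within 2.5 component SDs of its sampled latency
    (closest component wins a contested landmark); a component with no
    landmark in range — or an assignment that breaks the p1 < p2 < p3
    ordering — falls back to its generative latency.
    """
    from .features import compute_features, detect_candidates

    landmarks = detect_candidates(compute_features(det), fs).latencies_ms
    apexes: list = [float(lats[i]) if present[i] else None for i in range(3)]
    if landmarks.size:
        claims = []
        for i in range(3):
            if not present[i]:
                continue
            dist = np.abs(landmarks - lats[i])
            j = int(np.argmin(dist))
            if dist[j] <= 2.5 * widths[i]:
                claims.append((float(dist[j]), i, j))
        taken: set[int] = set()
        for _, i, j in sorted(claims):
            if j not in taken:
                taken.add(j)
                apexes[i] = float(landmarks[j])
    seq = [a for a in apexes if a is not None]
    if any(b <= a for a, b in zip(seq, seq[1:])):
        # heavily merged: fall back entirely to the generative latencies
        apexes = [float(lats[i]) if present[i] else None for i in range(3)]
    return tuple(apexes)


@dataclass
class SimulatedPulse:
    """One generated beat with bookkeeping and ground truth."""

    pulse_id: str
    file_id: str
    patient_id: str
    waveform: PulseWaveform
    apexes: tuple  # per component: apex time in ms or None
    is_hard: bool

    @property
    def missing(self) -> tuple:
        return tuple(a is None for a in self.apexes)


@dataclass
class SimulatedFile:
    """One synthetic recording: consecutive beats on a uniform grid."""

    file_id: str
    patient_id: str
    fs: float
    beat_ms: float
    is_hard: bool
    pulses: list = field(default_factory=list)

    @property
    def beat_onsets_ms(self) -> np.ndarray:
        """Beat-onset times, including the closing boundary of the last beat."""
        return np.arange(len(self.pulses) + 1) * self.beat_ms

    @property
    def samples(self) -> np.ndarray:
        return np.concatenate([p.waveform.samples for p in self.pulses])

    def to_recording(self):
        from .preprocess import Recording
        return Recording(samples=self.samples, fs=self.fs,
                         beat_onsets_ms=self.beat_onsets_ms,
                         patient_id=self.patient_id, file_id=self.file_id)


@dataclass
class SimulatedPatient:
    patient_id: str
    profile: MorphologyProfile
    is_hard: bool
    files: list = field(default_factory=list)


@dataclass
class SyntheticCorpus:
    """A collection of synthetic patients -> files -> pulses."""

    patients: list
    rng_seed: int

    def iter_pulses(self) -> Iterator[SimulatedPulse]:
        for pat in self.patients:
            for f in pat.files:
                yield from f.pulses

    def iter_files(self) -> Iterator[SimulatedFile]:
        for pat in self.patients:
            yield from pat.files

    @property
    def n_pulses(self) -> int:
        return sum(1 for _ in self.iter_pulses())

    def missing_counts(self) -> tuple:
        counts = [0, 0, 0]
        for p in self.iter_pulses():
            for i, absent in enumerate(p.missing):
                counts[i] += int(absent)
        return tuple(counts)

    def summary(self) -> dict:
        return {
            "n_patients": len(self.patients),
            "n_files": sum(len(p.files) for p in self.patients),
            "n_pulses": self.n_pulses,
            "n_hard_patients": sum(p.is_hard for p in self.patients),
            "missing_counts": self.missing_counts(),
            "rng_seed": self.rng_seed,
        }


def make_corpus(n_patients: int,
                files_per_patient: int,
                pulses_per_file: int,
                challenge_mix: float,
                rng_seed: int,
                fs: float = DEFAULT_FS_HZ,
                beat_ms: float = DEFAULT_BEAT_MS,
                easy_profile_fn=easy_profile,
                hard_profile_fn=challenging_profile) -> SyntheticCorpus:
    """Generate a full synthetic corpus.

    A fraction ``challenge_mix`` of patients (rounded) receives a
    challenging profile; the rest receive easy profiles.  The corpus records
    which patients/files are hard by construction.  Identical seeds produce
    bitwise-identical corpora.
    """
    if min(n_patients, files_per_patient, pulses_per_file) < 1:
        raise ValueError("all corpus counts must be >= 1")
    if not 0.0 <= challenge_mix <= 1.0:
        raise ValueError("challenge_mix must lie in [0, 1]")

    rng = np.random.default_rng(rng_seed)
    n_hard = int(round(challenge_mix * n_patients))
    hard_ids = set(rng.choice(n_patients, size=n_hard, replace=False).tolist())

    patients = []
    for ip in range(n_patients):
        hard = ip in hard_ids
        profile = hard_profile_fn(rng) if hard else easy_profile_fn(rng)
        pid = f"P{ip:03d}"
        patient = SimulatedPatient(patient_id=pid, profile=profile, is_hard=hard)
        for jf in range(files_per_patient):
            fid = f"{pid}-F{jf:02d}"
            rec = SimulatedFile(file_id=fid, patient_id=pid, fs=fs,
                                beat_ms=beat_ms, is_hard=hard)
            for kb in range(pulses_per_file):
                wave, apexes = make_pulse(profile, fs=fs, duration_ms=beat_ms,
                                          rng=rng, onset_ms=kb * beat_ms)
                rec.pulses.append(SimulatedPulse(
                    pulse_id=f"{fid}-B{kb:04d}", file_id=fid, patient_id=pid,
                    waveform=wave, apexes=apexes, is_hard=hard))
            patient.files.append(rec)
        patients.append(patient)
    return SyntheticCorpus(patients=patients, rng_seed=rng_seed)


def ground_truth_designation(apexes: Sequence, candidates: CandidateSet,
                             tol_ms: float = 10.0) -> PeakAssignment:
    """Map true component apexes onto detected candidates.

    Mirrors manual annotation, where the annotator picks the right peak
    among the automatically detected candidates: each present component is
    designated as the nearest candidate within ``tol_ms``; components with
    no candidate in range are MISSING.  If two components claim the same
    candidate the closer one wins.  The result always satisfies the
    p1 < p2 < p3 ordering (a later peak violating it is dropped to MISSING).
    """
    lat = candidates.latencies_ms
    chosen: list = [None, None, None]
    chosen_idx: list = [None, None, None]
    if lat.size:
        claims = []
        for i, apex in enumerate(apexes):
            if apex is None:
                continue
            j = int(np.argmin(np.abs(lat - apex)))
            d = abs(float(lat[j]) - apex)
            if d <= tol_ms:
                claims.append((d, i, j))
        taken: set[int] = set()
        for d, i, j in sorted(claims):
            if j not in taken:
                taken.add(j)
                chosen[i] = float(lat[j])
                chosen_idx[i] = j
    # enforce physiological ordering deterministically: keep earlier peaks
    prev = -np.inf
    for i in range(3):
        if chosen[i] is not None:
            if chosen[i] <= prev:
                chosen[i] = None
                chosen_idx[i] = None
            else:
                prev = chosen[i]
    return PeakAssignment(chosen[0], chosen[1], chosen[2],
                          source_indices=tuple(chosen_idx))
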