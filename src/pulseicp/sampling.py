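"""Error-weighted sampling of challenging pulses and training-set assembly.

Each recording (file) receives a weight equal to its fraction of wrongly
assigned peaks under a baseline recognizer,

    w_i = (E_p1 + E_p2 + E_p3) / (N_p1 + N_p2 + N_p3),

where E counts per-peak wrong designations (a prediction is wrong whenever
it differs from the ground-truth designation, MISSING mismatches included)
and N counts the per-peak designation slots, i.e. the number of evaluated
pulses per peak — so w = 1 means every peak in the file was designated
incorrectly.  Challenging pulses are then drawn file-first with probability
v_i = w_i / sum(w), each pulse at most once; exhausted files are removed and
the probabilities renormalised.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import PeakAssignment


@dataclass(frozen=True)
class FileWeight:
    """Per-file wrong-designation tallies and the resulting weight."""

    file_id: str
    E: tuple  # wrong designations per peak
    N: tuple  # designation slots per peak

    def __post_init__(self) -> None:
        if len(self.E) != 3 or len(self.N) != 3:
            raise ValueError("E and N must have 3 entries")
        if any(e < 0 or e > n for e, n in zip(self.E, self.N)):
            raise ValueError("need 0 <= E_i <= N_i per peak")

    @property
    def w(self) -> float:
        total = sum(self.N)
        return sum(self.E) / total if total > 0 else 0.0


def _same_designation(a, b) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return float(a) == float(b)


def _latencies(x) -> tuple:
    return x.latencies if isinstance(x, PeakAssignment) else tuple(x)


def file_weights(groundtruth: Mapping, predictions: Mapping,
                 pulse_files: Mapping) -> list:
    """Per-file error weights from aligned ground truth and predictions.

    All three mappings are keyed by pulse id; ``groundtruth`` and
    ``predictions`` hold (p1, p2, p3) designations, ``pulse_files`` the file
    id of each pulse.  Raises if the pulse ids are misaligned.  Files with
    no evaluated pulses get w = 0 with a warning.
    """
    if set(groundtruth) != set(predictions):
        raise ValueError("groundtruth and predictions cover different pulse ids")
    missing_files = set(groundtruth) - set(pulse_files)
    if missing_files:
        raise ValueError(f"no file id for pulses: {sorted(missing_files)[:5]}")

    E: dict[str, np.ndarray] = {}
    N: dict[str, np.ndarray] = {}
    for fid in set(pulse_files.values()):
        E[fid] = np.zeros(3, dtype=int)
        N[fid] = np.zeros(3, dtype=int)
    for pid, truth in groundtruth.items():
        fid = pulse_files[pid]
        t = _latencies(truth)
        p = _latencies(predictions[pid])
        for i in range(3):
            N[fid][i] += 1
            if not _same_designation(p[i], t[i]):
                E[fid][i] += 1

    out = []
    for fid in sorted(E):
        fw = FileWeight(file_id=fid, E=tuple(int(v) for v in E[fid]),
                        N=tuple(int(v) for v in N[fid]))
        if sum(fw.N) == 0:
            warnings.warn(f"file {fid} has no evaluated pulses; weight set to 0")
        out.append(fw)
    return out


def sampling_probabilities(weights: Sequence[FileWeight]) -> np.ndarray:
    """Per-file selection probabilities v_i = w_i / sum(w)."""
    w = np.array([fw.w for fw in weights], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("all file weights are zero; nothing to sample")
    return w / total


def sample_challenging(weights: Sequence[FileWeight],
                       pulses_by_file: Mapping,
                       n: int,
                       rng) -> list:
    """Draw ``n`` distinct pulse ids, file-first with probability v_i.

    At every draw a file is selected with probability proportional to its
    weight, then one of its not-yet-selected pulses uniformly.  A file with
    no pulses left is removed and the probabilities renormalised over the
    remaining files.
    """
    rng = np.random.default_rng(rng)
    w = np.array([fw.w for fw in weights], dtype=float)
    if w.sum() <= 0:
        raise ValueError("all file weights are zero; nothing to sample")
    pools = []
    for fw in weights:
        pool = list(pulses_by_file.get(fw.file_id, ()))
        pools.append(pool)
    reachable = sum(len(p) for wt, p in zip(w, pools) if wt > 0)
    if n > reachable:
        raise ValueError(f"requested {n} pulses but only {reachable} are "
                         "available in positively weighted files")

    active = [i for i in range(len(weights)) if w[i] > 0 and pools[i]]
    cum = np.cumsum(w[active])
    cum /= cum[-1]
    out: list = []
    while len(out) < n:
        f = active[int(np.searchsorted(cum, rng.random(), side="right"))]
        pool = pools[f]
        j = int(rng.integers(len(pool)))
        pool[j], pool[-1] = pool[-1], pool[j]
        out.append(pool.pop())
        if not pool:
            active = [i for i in active if pools[i]]
            if not active and len(out) < n:
                raise ValueError("ran out of pulses in weighted files")
            if active:
                cum = np.cumsum(w[active])
                cum /= cum[-1]
    return out


def build_training_sets(pulse_ids: Sequence,
                        weights: Sequence[FileWeight],
                        pulses_by_file: Mapping,
                        size: int,
                        rng,
                        reference_ids: Optional[Sequence] = None) -> tuple:
    """Assemble the two training libraries.

    T1 (*reference library*) is a uniform sample of ``size`` pulses from the
    reference pool (``reference_ids`` if given, else all of ``pulse_ids``).
    T2 (*weighted sampling*) mixes ``size // 2`` error-weighted challenging
    pulses with uniform reference pulses for the remainder; the two halves
    are disjoint.  Fixed seeds give identical sets.
    """
    rng = np.random.default_rng(rng)
    pool = list(reference_ids) if reference_ids is not None else list(pulse_ids)
    if size < 1:
        raise ValueError("size must be >= 1")
    if len(pool) < size:
        raise ValueError(f"reference pool has {len(pool)} pulses; need {size}")

    t1 = [pool[i] for i in rng.choice(len(pool), size=size, replace=False)]

    n_chal = size // 2
    n_unif = size - n_chal
    chal = sample_challenging(weights, pulses_by_file, n_chal, rng) if n_chal else []
    chal_set = set(chal)
    avail = [p for p in pool if p not in chal_set]
    if len(avail) < n_unif:
        raise ValueError("not enough reference pulses left for the uniform half")
    unif = [avail[i] for i in rng.choice(len(avail), size=n_unif, replace=False)]
    return t1, unif + chal
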