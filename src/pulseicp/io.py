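"""File formats: corpus read/write, recordings, annotations, models, results.

All tables are comma-separated UTF-8 CSV with a header row; times are in ms,
pressures in mmHg, and a missing peak is an empty cell.  Floats are written
with 17 significant digits so a write/read round trip is bitwise exact.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import Recording
from .recognize.gaussian import GaussianPriorModel
from .recognize.gmm import GmmModel
from .recognize.spectral import SrModel
from .simulate import (MorphologyProfile, SimulatedFile, SimulatedPatient,
                       SimulatedPulse, SyntheticCorpus)
from .types import PeakAssignment, PulseWaveform

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------- recordings

def write_recording(rec: Recording, path) -> None:
    t = np.arange(rec.samples.size) * (1000.0 / rec.fs)
    df = pd.DataFrame({"time_ms": t, "icp_mmhg": rec.samples})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording(path, beat_onsets_ms=None, patient_id: str = "",
                   file_id: str = "") -> Recording:
    """Read a two-column (time_ms, icp_mmhg) CSV into a Recording.

    Validates the header, a strictly increasing time column, and a uniform
    sampling interval; errors name the offending line (1-based, header is
    line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["time_ms", "icp_mmhg"]:
        raise ParseError(f"{path.name}: line 1: expected header "
                         f"'time_ms,icp_mmhg', got {list(df.columns)!r}")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    icp = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path.name}: need at least 2 samples")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ParseError(f"{path.name}: line {bad[0] + 3}: time column not "
                         "strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        j = int(np.argmax(np.abs(dt - dt[0])))
        raise ParseError(f"{path.name}: line {j + 3}: mixed sampling intervals")
    fs = 1000.0 / float(dt[0])
    onsets = (np.asarray(beat_onsets_ms, dtype=float)
              if beat_onsets_ms is not None
              else np.array([t[0], t[-1] + dt[0]]))
    return Recording(samples=icp, fs=fs, beat_onsets_ms=onsets,
                     patient_id=patient_id, file_id=file_id)


# -------------------------------------------------------------------- corpus

def write_corpus(corpus: SyntheticCorpus, out_dir) -> None:
    """One JSON manifest + per-file sample CSVs + one annotation table."""
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)

    manifest = {"rng_seed": corpus.rng_seed, "patients": []}
    ann_rows = []
    for pat in corpus.patients:
        pentry = {
            "patient_id": pat.patient_id,
            "is_hard": pat.is_hard,
            "profile": {
                "latency_means": list(pat.profile.latency_means),
                "latency_sds": list(pat.profile.latency_sds),
                "amplitude_means": list(pat.profile.amplitude_means),
                "amplitude_sds": list(pat.profile.amplitude_sds),
                "missing_probs": list(pat.profile.missing_probs),
                "noise_sd": pat.profile.noise_sd,
                "drift_amplitude": pat.profile.drift_amplitude,
                "challenge_level": pat.profile.challenge_level,
            },
            "files": [],
        }
        for f in pat.files:
            pentry["files"].append({
                "file_id": f.file_id, "fs": f.fs, "beat_ms": f.beat_ms,
                "n_pulses": len(f.pulses), "is_hard": f.is_hard,
                "beat_onsets_ms": f.beat_onsets_ms.tolist(),
            })
            write_recording(f.to_recording(), out / "recordings" / f"{f.file_id}.csv")
            for sp in f.pulses:
                a = sp.apexes
                ann_rows.append({
                    "pulse_id": sp.pulse_id, "file_id": sp.file_id,
                    "patient_id": sp.patient_id,
                    "onset_ms": sp.waveform.onset_ms,
                    "p1_ms": a[0], "p2_ms": a[1], "p3_ms": a[2],
                })
        manifest["patients"].append(pentry)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    pd.DataFrame(ann_rows).to_csv(out / "annotations.csv", index=False,
                                  float_format=_FLOAT_FMT)


def read_corpus(in_dir) -> SyntheticCorpus:
    """Rebuild a corpus from manifest + recordings + annotations."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    ann = pd.read_csv(root / "annotations.csv", float_precision="round_trip")
    ann_by_file = {fid: grp.sort_values("onset_ms")
                   for fid, grp in ann.groupby("file_id")}

    patients = []
    for pentry in manifest["patients"]:
        profile = MorphologyProfile(**pentry["profile"])
        pat = SimulatedPatient(patient_id=pentry["patient_id"], profile=profile,
                               is_hard=bool(pentry["is_hard"]))
        for fentry in pentry["files"]:
            fid = fentry["file_id"]
            rec = read_recording(root / "recordings" / f"{fid}.csv",
                                 beat_onsets_ms=fentry["beat_onsets_ms"],
                                 patient_id=pat.patient_id, file_id=fid)
            f = SimulatedFile(file_id=fid, patient_id=pat.patient_id,
                              fs=fentry["fs"], beat_ms=fentry["beat_ms"],
                              is_hard=bool(fentry["is_hard"]))
            rows = ann_by_file[fid]
            onsets = np.asarray(fentry["beat_onsets_ms"], dtype=float)
            idx = np.round(onsets * fentry["fs"] / 1000.0).astype(int)
            for k, (_, row) in enumerate(rows.iterrows()):
                seg = rec.samples[idx[k]:idx[k + 1]]
                apexes = tuple(None if pd.isna(row[c]) else float(row[c])
                               for c in ("p1_ms", "p2_ms", "p3_ms"))
                f.pulses.append(SimulatedPulse(
                    pulse_id=row["pulse_id"], file_id=fid,
                    patient_id=pat.patient_id,
                    waveform=PulseWaveform(seg, fs=fentry["fs"],
                                           onset_ms=float(row["onset_ms"])),
                    apexes=apexes, is_hard=bool(fentry["is_hard"])))
            pat.files.append(f)
        patients.append(pat)
    return SyntheticCorpus(patients=patients,
                           rng_seed=int(manifest["rng_seed"]))


# ------------------------------------------------------- annotations / picks

def read_annotations(path) -> dict:
    """Annotation CSV -> {pulse_id: PeakAssignment} (empty cell = MISSING)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for _, row in df.iterrows():
        vals = [None if pd.isna(row[c]) else float(row[c])
                for c in ("p1_ms", "p2_ms", "p3_ms")]
        out[row["pulse_id"]] = PeakAssignment(*vals)
    return out


def write_assignments(assignments: dict, path) -> None:
    rows = [{"pulse_id": pid, "p1_ms": a.p1, "p2_ms": a.p2, "p3_ms": a.p3}
            for pid, a in assignments.items()]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


# -------------------------------------------------------------------- models

_MODEL_CLASSES = {"gaussian": GaussianPriorModel, "gmm": GmmModel,
                  "sr": SrModel, "ksr": SrModel}


def save_model(model, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path):
    text = Path(path).read_text()
    kind = json.loads(text).get("kind")
    try:
        cls = _MODEL_CLASSES[kind]
    except KeyError:
        raise ParseError(f"{path}: unknown model kind {kind!r}") from None
    return cls.from_json(text)


# ------------------------------------------------------------------- results

def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)
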