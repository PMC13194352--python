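"""File formats: WAV phonocardiograms, CSV ECG traces, JSON ground truth.

A simulated subject is stored as a directory::

    <subject_id>/
        pcg.wav     16-bit PCM at 2,000 Hz (peak-normalized)
        ecg.csv     columns time_ms, amplitude at 500 Hz
        truth.json  ground-truth fiducials and artifact log

Cohort tables are plain CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocess import ECG_FS, PCG_FS, SyncRecording
from .synth import GroundTruth

__all__ = [
    "write_wav",
    "read_wav",
    "write_ecg_csv",
    "read_ecg_csv",
    "write_subject",
    "read_subject",
]


def write_wav(path, samples: np.ndarray, fs: float = PCG_FS) -> None:
    """Write samples as peak-normalized 16-bit PCM WAV."""
    x = np.asarray(samples, dtype=float)
    peak = np.max(np.abs(x)) or 1.0
    pcm = np.round(x / peak * 0.95 * 32767).astype(np.int16)
    wavfile.write(str(path), int(fs), pcm)


def read_wav(path):
    """Read a WAV file; returns (samples as float in [-1, 1], fs)."""
    fs, pcm = wavfile.read(str(path))
    return pcm.astype(float) / 32768.0, float(fs)


def write_ecg_csv(path, samples: np.ndarray, fs: float = ECG_FS) -> None:
    t = np.arange(len(samples)) / fs * 1000.0
    pd.DataFrame({"time_ms": t, "amplitude": samples}).to_csv(path, index=False)


def read_ecg_csv(path):
    """Read an ECG CSV; returns (samples, fs inferred from time_ms)."""
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    fs = 1000.0 / float(np.median(np.diff(t)))
    return df["amplitude"].to_numpy(dtype=float), fs


def write_subject(
    directory, recording: SyncRecording, truth: GroundTruth | None = None
) -> Path:
    """Write one subject bundle; returns the directory path."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_wav(d / "pcg.wav", recording.pcg, recording.pcg_fs)
    write_ecg_csv(d / "ecg.csv", recording.ecg, recording.ecg_fs)
    meta = {"ecg_fs": recording.ecg_fs, "pcg_fs": recording.pcg_fs}
    if recording.resp_phase is not None:
        meta["resp_phase"] = np.asarray(recording.resp_phase).tolist()
    if truth is not None:
        meta["truth"] = truth.to_dict()
    (d / "truth.json").write_text(json.dumps(meta))
    return d


def read_subject(directory):
    """Read a subject bundle; returns (SyncRecording, GroundTruth | None)."""
    d = Path(directory)
    pcg, pcg_fs = read_wav(d / "pcg.wav")
    ecg, ecg_fs = read_ecg_csv(d / "ecg.csv")
    truth = None
    resp = None
    meta_path = d / "truth.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if "resp_phase" in meta:
            resp = np.asarray(meta["resp_phase"], dtype=float)
        if "truth" in meta:
            truth = GroundTruth.from_dict(meta["truth"])
        ecg_fs = meta.get("ecg_fs", ecg_fs)
        pcg_fs = meta.get("pcg_fs", pcg_fs)
    rec = SyncRecording(ecg=ecg, pcg=pcg, ecg_fs=ecg_fs, pcg_fs=pcg_fs,
                        resp_phase=resp)
    return rec, truth
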