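"""File formats: flat-binary recordings with JSON sidecars, CSV interchange.

Recordings are stored as little-endian float32, channel-major, next to a
JSON sidecar naming the sampling rate, channel count, dtype and units.
Sortings and event tables travel as plain CSV so any sorter's output can be
adapted with one rename.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .curation import SortedUnit
from .preprocess import RecordingBuffer
from .synthgen import LabeledRecording


class FormatError(ValueError):
    pass


def write_recording(path, recording: RecordingBuffer | LabeledRecording) -> Path:
    """Write samples + sidecar; ``path`` is the binary file (sidecar adds .json)."""
    path = Path(path)
    samples = recording.samples
    data = np.ascontiguousarray(samples, dtype="<f4")
    data.tofile(path)
    sidecar = {
        "sampling_rate_hz": float(recording.sampling_rate),
        "n_channels": int(samples.shape[0]),
        "dtype": "float32",
        "units": "uV",
        "order": "channel_major",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path) -> RecordingBuffer:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if meta.get("dtype") != "float32":
        raise FormatError(f"unknown dtype {meta.get('dtype')!r} in {sidecar_path}")
    sr = float(meta.get("sampling_rate_hz", 0))
    if sr <= 0:
        raise FormatError(f"invalid sampling_rate_hz {sr} in {sidecar_path}")
    n_ch = int(meta["n_channels"])
    raw = np.fromfile(path, dtype="<f4")
    if raw.size % n_ch:
        expected = (raw.size // n_ch + 1) * n_ch * 4
        raise FormatError(f"{path}: {raw.size * 4} bytes is not a multiple of "
                          f"{n_ch} channels x 4 bytes (next valid size {expected})")
    return RecordingBuffer(raw.reshape(n_ch, -1).astype(np.float64), sr)


def write_events_csv(path, events, sampling_rate: float) -> Path:
    rows = [{"event_id": i, "time_s": e.peak_sample / sampling_rate,
             "channel": e.channel, "peak_uV": e.peak_amplitude}
            for i, e in enumerate(events)]
    pd.DataFrame(rows, columns=["event_id", "time_s", "channel", "peak_uV"]).to_csv(
        path, index=False, float_format="%.9g")
    return Path(path)


def write_sorting(path, units: list[SortedUnit]) -> Path:
    frames = [pd.DataFrame({"unit_id": u.unit_id, "time_s": u.event_times,
                            "channel": 0}) for u in units]
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["unit_id", "time_s", "channel"])
    df.to_csv(path, index=False, float_format="%.9g")
    return Path(path)


def read_sorting(path) -> list[SortedUnit]:
    df = pd.read_csv(path)
    required = {"unit_id", "time_s", "channel"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df.duplicated(["unit_id", "time_s"]).any():
        warnings.warn(f"{path}: duplicate (unit_id, time_s) rows kept")
    units = []
    for uid, g in df.groupby("unit_id", sort=True):
        t = g["time_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) < 0)[0]
        if bad.size:
            rows = (g.index[bad + 1] + 2).tolist()  # 1-based incl. header
            raise FormatError(f"{path}: unit {uid} times decrease at rows {rows}")
        # deduplicate exact ties for a strictly increasing unit
        t = np.unique(t)
        units.append(SortedUnit(int(uid), t))
    return units


def write_ground_truth(path, recording: LabeledRecording) -> Path:
    rows = [{"time_s": t, "channel": ch, "kind": lab.value, "unit_id": tid}
            for t, ch, lab, tid in recording.true_events]
    pd.DataFrame(rows, columns=["time_s", "channel", "kind", "unit_id"]).to_csv(
        path, index=False, float_format="%.9g")
    return Path(path)


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_s", "channel", "kind", "unit_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df


def write_scores(path, scores: np.ndarray, decisions) -> Path:
    pd.DataFrame({"event_id": np.arange(len(scores)), "msle": scores,
                  "decision": [d.value for d in decisions]}).to_csv(
        path, index=False, float_format="%.9g")
    return Path(path)
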