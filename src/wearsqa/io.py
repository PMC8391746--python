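"""Plain-text serialization: CSV waveforms, label tables, feature
matrices and quality tracks.

Record CSV layout: comment header lines ``# key=value`` carrying fs,
kind, record_id and t0, then two columns ``time_s,value``.  Times in all
output files are seconds from record start; window identity is
(record_id, start_s); intervals are half-open [start, end).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import GRADE_CODES, GRADE_NAMES, SignalRecord

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_feature_csv",
    "read_feature_csv",
    "write_track_csv",
    "write_dataset",
]


def write_record_csv(record: SignalRecord, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={record.fs!r}\n")
        fh.write(f"# kind={record.kind}\n")
        fh.write(f"# record_id={record.record_id}\n")
        fh.write(f"# t0={record.t0!r}\n")
        fh.write("time_s,value\n")
        for t, v in zip(record.times, record.samples):
            fh.write(f"{t:.6f},{float(v)!r}\n")


def read_record_csv(path, fs: float | None = None, kind: str | None = None) -> SignalRecord:
    """Read a waveform CSV; fs/kind come from the ``#`` header unless
    given explicitly.  Raises on a missing sampling rate."""
    path = Path(path)
    meta: dict = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    fs = fs if fs is not None else (float(meta["fs"]) if "fs" in meta else None)
    if fs is None:
        raise ValueError(f"{path}: no sampling rate in header and none given")
    kind = kind or meta.get("kind")
    if kind is None:
        raise ValueError(f"{path}: no channel kind in header and none given")
    frame = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if "value" not in frame.columns:
        raise ValueError(f"{path}: malformed record CSV (no 'value' column)")
    return SignalRecord(
        samples=frame["value"].to_numpy(dtype=float),
        fs=float(fs),
        kind=kind,
        t0=float(meta.get("t0", 0.0)),
        record_id=meta.get("record_id", path.stem),
    )


def write_labels_csv(rows, path) -> None:
    """rows: iterable of (record_id, window_start_s, window_len_s, grade)."""
    frame = pd.DataFrame(rows, columns=["record_id", "window_start_s", "window_len_s", "grade"])
    frame["grade"] = [GRADE_NAMES[g] if not isinstance(g, str) else g for g in frame["grade"]]
    frame.to_csv(path, index=False, float_format="%.3f")


def read_labels_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame["grade"] = [GRADE_CODES[g] for g in frame["grade"]]
    return frame


def write_feature_csv(X, names, keys, path) -> None:
    """Feature matrix with header = feature names, keyed by
    (record_id, start_s)."""
    frame = pd.DataFrame(np.asarray(X), columns=list(names))
    frame.insert(0, "record_id", [k[0] for k in keys])
    frame.insert(1, "start_s", [k[1] for k in keys])
    frame.to_csv(path, index=False, float_format="%.9g")


def read_feature_csv(path):
    frame = pd.read_csv(path)
    names = [c for c in frame.columns if c not in ("record_id", "start_s")]
    keys = list(zip(frame["record_id"], frame["start_s"]))
    return frame[names].to_numpy(dtype=float), tuple(names), keys


def write_track_csv(track, path) -> None:
    frame = track.to_frame()
    frame["grade"] = [GRADE_NAMES[g] for g in frame["grade"]]
    frame.to_csv(path, index=False, float_format="%.3f")


def write_dataset(dataset, out_dir) -> None:
    """Persist a synthetic dataset: per-split record CSVs, label CSVs
    for the labeled splits, and a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    truth_all = {}
    for split in ("train", "validation", "test"):
        windows = getattr(dataset, split)
        rec_dir = out_dir / split
        rec_dir.mkdir(parents=True, exist_ok=True)
        labels = []
        for w in windows:
            rec = w.record
            write_record_csv(rec, rec_dir / f"{rec.record_id}.csv")
            truth_all[rec.record_id] = {
                "wander_ratio": w.truth.wander_ratio,
                "impulse_count": w.truth.impulse_count,
                "dropout_s": w.truth.dropout_s,
                "emg_s": w.truth.emg_s,
                "unreadable_beats": w.truth.unreadable_beats,
                "regular_fraction": w.truth.regular_fraction,
                "apnea_s": w.truth.apnea_s,
            }
            if w.grade is not None:
                labels.append((rec.record_id, 0.0, w.truth.window_s, w.grade))
        if labels:
            write_labels_csv(labels, out_dir / f"{split}_labels.csv")
    with (out_dir / "ground_truth.json").open("w") as fh:
        json.dump(truth_all, fh, indent=1)
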