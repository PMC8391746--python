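"""Rule-based arrhythmia flaggers and the quality-gated false-alarm audit.

The flaggers are deliberately simple, documented rules (sustained
rate-limit violations and premature-beat morphology checks) standing in
for a monitoring device's detector; the point of the module is the
audit: an alarm is counted false when its onset lies in a poor-quality
interval of the record's quality track, so gating alarms on assessed
signal quality quantifiably suppresses artifact-driven alarms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import QualityTrack
from .features import BeatSegmentation
from .records import ACCEPTABLE, UNACCEPTABLE, SignalRecord

__all__ = ["AlarmEvent", "AlarmConfig", "detect_alarms", "false_alarm_audit"]

ALARM_TYPES = ("bradycardia", "tachycardia", "APB", "VPB")


@dataclass
class AlarmEvent:
    type: str
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.type not in ALARM_TYPES:
            raise ValueError(f"unknown alarm type {self.type!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass
class AlarmConfig:
    brady_bpm: float = 50.0
    tachy_bpm: float = 100.0
    sustained_s: float = 10.0
    premature_frac: float = 0.8     # RR below this fraction of local median
    wide_beat_s: float = 0.060      # QRS width above this marks a wide beat
    high_amp_factor: float = 1.3    # amplitude above this x median marks VPB


def _beat_morphology(x: np.ndarray, fs: float, peak: int) -> tuple[float, float]:
    """(width_s at half peak amplitude, absolute peak amplitude)."""
    half = int(0.12 * fs)
    lo, hi = max(0, peak - half), min(len(x), peak + half + 1)
    seg = np.abs(x[lo:hi] - np.median(x))
    amp = float(np.abs(x[peak] - np.median(x)))
    above = seg >= amp / 2.0
    return float(np.sum(above)) / fs, amp


def detect_alarms(record: SignalRecord, seg: BeatSegmentation,
                  config: AlarmConfig | None = None) -> list[AlarmEvent]:
    """Flag bradycardia/tachycardia (sustained rate-limit violations)
    and premature beats (APB: normal morphology, VPB: wide or
    high-amplitude) from a beat segmentation of the record."""
    config = config or AlarmConfig()
    peaks_t = record.t0 + seg.peaks / seg.fs
    events: list[AlarmEvent] = []
    if len(peaks_t) < 3:
        return events
    rr = np.diff(peaks_t)
    hr = 60.0 / rr

    def sustained_runs(mask):
        runs = []
        start = None
        for i, m in enumerate(mask):
            if m and start is None:
                start = i
            elif not m and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(mask)))
        return runs

    for name, mask in (
        ("bradycardia", hr < config.brady_bpm),
        ("tachycardia", hr > config.tachy_bpm),
    ):
        for i0, i1 in sustained_runs(mask):
            onset = peaks_t[i0]
            dur = peaks_t[i1] - onset
            if dur >= config.sustained_s:
                events.append(AlarmEvent(type=name, onset_s=float(onset), duration_s=float(dur)))

    med_amp = np.median([
        _beat_morphology(record.samples, record.fs, p)[1] for p in seg.peaks
    ]) or 1.0
    for i in range(1, len(rr)):
        window = rr[max(0, i - 3) : i + 3]
        local_med = float(np.median(window))
        if rr[i - 1] < config.premature_frac * local_med:
            peak = seg.peaks[i]
            width, amp = _beat_morphology(record.samples, record.fs, peak)
            kind = "VPB" if (width > config.wide_beat_s or amp > config.high_amp_factor * med_amp) else "APB"
            events.append(AlarmEvent(type=kind, onset_s=float(peaks_t[i]), duration_s=float(rr[i - 1])))
    events.sort(key=lambda e: e.onset_s)
    return events


def false_alarm_audit(alarms, track: QualityTrack, policy: str = "default") -> dict:
    """Per-type alarm counts and false proportions under quality gating.

    An alarm is false iff its onset falls in a poor-quality interval:
    under the ``"default"`` policy only unacceptable intervals count as
    poor (acceptable signal still supports rate analysis); the
    ``"strict"`` policy treats acceptable-or-worse as poor.  Onsets
    outside the track are reported separately as unauditable.
    """
    if policy == "default":
        poor = {UNACCEPTABLE}
    elif policy == "strict":
        poor = {ACCEPTABLE, UNACCEPTABLE}
    else:
        raise ValueError(f"unknown policy {policy!r}")
    report = {
        t: {"count": 0, "false_count": 0, "false_proportion": None} for t in ALARM_TYPES
    }
    unauditable = 0
    for alarm in alarms:
        grade = track.lookup(alarm.onset_s)
        if grade is None:
            unauditable += 1
            continue
        entry = report[alarm.type]
        entry["count"] += 1
        if grade in poor:
            entry["false_count"] += 1
    for entry in report.values():
        if entry["count"]:
            entry["false_proportion"] = entry["false_count"] / entry["count"]
    report["unauditable"] = unauditable
    return report
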