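"""Core waveform containers shared across the pipeline.

A :class:`SignalRecord` is a uniformly sampled single-channel waveform
(ECG or respiration) with its sampling rate and a stable identifier.
Quality assessment operates on fixed-length observation windows cut from
records: 10 s for ECG, 30 s for respiration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ECG = "ECG"
RESP = "RESP"
KINDS = (ECG, RESP)

#: Observation-window length in seconds per channel kind.
WINDOW_SECONDS = {ECG: 10.0, RESP: 30.0}

#: Default sampling rates in Hz (configurable everywhere they are used).
DEFAULT_FS = {ECG: 200.0, RESP: 25.0}

# Quality grades form a total order: higher = worse.
GOOD, ACCEPTABLE, UNACCEPTABLE = 0, 1, 2
GRADE_NAMES = {GOOD: "good", ACCEPTABLE: "acceptable", UNACCEPTABLE: "unacceptable"}
GRADE_CODES = {v: k for k, v in GRADE_NAMES.items()}


def grade_code(grade: int | str) -> int:
    """Normalize a grade given as int code or name to the int code."""
    if isinstance(grade, str):
        try:
            return GRADE_CODES[grade.lower()]
        except KeyError:
            raise ValueError(f"unknown quality grade {grade!r}") from None
    if grade not in GRADE_NAMES:
        raise ValueError(f"unknown quality grade {grade!r}")
    return int(grade)


@dataclass
class SignalRecord:
    """Uniformly sampled waveform with sampling rate and channel kind."""

    samples: np.ndarray
    fs: float
    kind: str
    t0: float = 0.0
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class ObservationWindow:
    """Fixed-length slice of a record, possibly after conditioning.

    ``flags`` carries deterministic per-window markers set from the raw
    slice: ``flatline`` (near-zero variance, e.g. full-window signal
    loss) and ``saturated`` (a large fraction of samples pinned at the
    rail value).
    """

    record_id: str
    start_s: float
    length_s: float
    fs: float
    kind: str
    samples: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s

    @property
    def key(self) -> tuple:
        return (self.record_id, round(self.start_s, 3))
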