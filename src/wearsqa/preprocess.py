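"""Window conditioning: segmentation, band-pass filtering, robust outlier
clipping, and per-window normalization.

The fixed stage order is filter -> outlier clip -> normalize; baseline
removal is subsumed by the high-pass edge of the band-pass.  Every stage
is length-preserving and windows are conditioned independently, so
streaming and batch processing give identical results.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .records import ECG, RESP, WINDOW_SECONDS, ObservationWindow, SignalRecord

__all__ = [
    "BANDS",
    "segment_windows",
    "bandpass",
    "clip_outliers",
    "normalize",
    "condition_window",
    "condition_record",
]

#: Default pass bands in Hz.  ECG keeps the QRS-relevant band; the
#: respiratory band covers 3-60 breaths/min with room for harmonics.
BANDS = {ECG: (0.5, 40.0), RESP: (0.05, 1.0)}

#: Pre-normalization standard deviation below which a window is flagged
#: flatline (signal loss); flagged windows skip feature extraction and
#: are forced unacceptable downstream.
FLATLINE_TOL = 1e-6

#: Fraction of samples pinned at the extreme value that flags saturation.
SATURATION_FRAC = 0.10


def segment_windows(record: SignalRecord, stride_s: float | None = None) -> list[ObservationWindow]:
    """Cut a record into fixed-length raw windows (10 s ECG / 30 s RESP).

    Default stride equals the window length (non-overlapping); a
    trailing partial window is dropped.  Returns raw, unconditioned
    windows.
    """
    length_s = WINDOW_SECONDS[record.kind]
    stride_s = stride_s or length_s
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    n_win_samples = int(round(length_s * record.fs))
    if len(record.samples) < n_win_samples:
        warnings.warn(f"record {record.record_id!r} shorter than one window")
        return []
    out = []
    start = 0.0
    while int(round(start * record.fs)) + n_win_samples <= len(record.samples):
        i0 = int(round(start * record.fs))
        out.append(
            ObservationWindow(
                record_id=record.record_id,
                start_s=record.t0 + start,
                length_s=length_s,
                fs=record.fs,
                kind=record.kind,
                samples=record.samples[i0 : i0 + n_win_samples].copy(),
            )
        )
        start += stride_s
    return out


def bandpass(x: np.ndarray, fs: float, kind: str | None = None,
             band: tuple | None = None, order: int = 4) -> np.ndarray:
    """Zero-phase IIR band-pass (Butterworth, applied forward-backward)."""
    if band is None:
        band = BANDS[kind]
    lo, hi = band
    if not 0 < lo < hi or hi >= fs / 2:
        raise ValueError(f"band {band} infeasible at fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def clip_outliers(x: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Clip samples beyond median +/- k * robust scale (1.4826 * MAD).

    A constant window (zero scale) passes through unchanged.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    scale = 1.4826 * np.median(np.abs(x - med))
    if scale <= 0:
        return x.copy()
    return np.clip(x, med - k * scale, med + k * scale)


def normalize(x: np.ndarray, flatline_tol: float = FLATLINE_TOL) -> tuple[np.ndarray, bool]:
    """Zero-mean unit-variance scaling; returns (scaled, flatline flag).

    Below the flatline tolerance the samples are only mean-centered and
    the flag is set.
    """
    x = np.asarray(x, dtype=float)
    centered = x - np.mean(x)
    sd = float(np.std(centered))
    if sd < flatline_tol:
        return centered, True
    return centered / sd, False


def condition_window(window: ObservationWindow, k: float = 5.0,
                     band: tuple | None = None) -> ObservationWindow:
    """Run the full conditioning chain on one raw window."""
    raw = window.samples
    n = len(raw)
    vmax, vmin = np.max(raw), np.min(raw)
    saturated = bool(
        np.ptp(raw) > 0
        and max(np.sum(raw == vmax), np.sum(raw == vmin)) > SATURATION_FRAC * n
    )
    x = bandpass(raw, window.fs, kind=window.kind, band=band)
    x = clip_outliers(x, k=k)
    x, flatline = normalize(x)
    # raw flatline (e.g. held dropout value) must flag even though
    # filtering maps it to near-zero noise
    if float(np.std(raw)) < FLATLINE_TOL * max(1.0, abs(float(np.mean(raw)))):
        flatline = True
    return ObservationWindow(
        record_id=window.record_id,
        start_s=window.start_s,
        length_s=window.length_s,
        fs=window.fs,
        kind=window.kind,
        samples=x,
        flags={"flatline": flatline, "saturated": saturated},
    )


def condition_record(record: SignalRecord, stride_s: float | None = None,
                     k: float = 5.0, band: tuple | None = None) -> list[ObservationWindow]:
    """Segment a record and condition every window."""
    return [condition_window(w, k=k, band=band) for w in segment_windows(record, stride_s)]
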