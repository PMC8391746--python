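"""Synthetic ECG / respiration generator with rule-based quality grading.

Real wearable recordings carry baseline wander, mains interference, EMG
bursts, impulse artifacts and flatline signal loss.  This module creates
clean quasi-periodic signals, injects each noise class with retained
ground truth, and grades every observation window with the quantitative
three-grade criteria (good / acceptable / unacceptable) so the whole
quality-assessment pipeline can be exercised and scored without any real
recordings.

Clean ECG is a sum-of-Gaussians beat template (P, Q, R, S, T bumps)
repeated on a jittered beat grid; ectopic beats (VPB/APB) replace normal
slots prematurely.  Clean respiration is a phase-integrated sinusoid
with breath-to-breath period and amplitude jitter and optional apnea
pauses.  Every generator is a pure function of its arguments including
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .records import (
    ACCEPTABLE,
    DEFAULT_FS,
    ECG,
    GOOD,
    KINDS,
    RESP,
    UNACCEPTABLE,
    WINDOW_SECONDS,
    SignalRecord,
)

__all__ = [
    "NoiseSpec",
    "PathologySpec",
    "GroundTruth",
    "SyntheticSignal",
    "NoisySignal",
    "gen_clean_ecg",
    "gen_clean_resp",
    "inject_noise",
    "window_truth",
    "label_window",
    "DatasetConfig",
    "GeneratedWindow",
    "SyntheticDataset",
    "make_dataset",
]


# --------------------------------------------------------------------------
# specs and ground truth


@dataclass
class NoiseSpec:
    """Parameterization of the injected corruption, all amplitudes relative
    to the clean signal's peak-to-peak amplitude."""

    bw_rel_amp: float = 0.0
    bw_freq_hz: tuple = (0.05, 0.4)
    powerline_rel_amp: float = 0.0
    powerline_hz: float = 50.0
    emg_rel_amp: float = 0.0
    emg_burst_spans: tuple = ()       # ((start_s, duration_s), ...)
    impulse_times: tuple = ()         # (t_s, ...)
    impulse_rel_amp: float = 2.0
    dropout_spans: tuple = ()         # ((start_s, duration_s), ...)
    seed: int = 0

    def validate(self, duration_s: float) -> None:
        for name in ("bw_rel_amp", "powerline_rel_amp", "emg_rel_amp", "impulse_rel_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("emg_burst_spans", "dropout_spans"):
            spans = sorted(getattr(self, name))
            for start, dur in spans:
                if dur <= 0 or start < 0 or start + dur > duration_s + 1e-9:
                    raise ValueError(f"{name} span ({start}, {dur}) outside record")
            for (s0, d0), (s1, _) in zip(spans, spans[1:]):
                if s1 < s0 + d0 - 1e-9:
                    raise ValueError(f"{name} spans overlap")
        for t in self.impulse_times:
            if not 0 <= t <= duration_s:
                raise ValueError(f"impulse time {t} outside record")


@dataclass
class PathologySpec:
    """Planted rhythm pathology.  Pathology never degrades the quality
    grade; it exists so the pipeline can be shown not to confuse ectopy
    with noise."""

    ectopic_type: str = "none"        # VPB | APB | none
    ectopic_beat_indices: tuple = ()
    rate_mode: str = "normal"         # normal | tachycardia | bradycardia

    def validate(self) -> None:
        if self.ectopic_type not in ("VPB", "APB", "none"):
            raise ValueError(f"unknown ectopic_type {self.ectopic_type!r}")
        if self.rate_mode not in ("normal", "tachycardia", "bradycardia"):
            raise ValueError(f"unknown rate_mode {self.rate_mode!r}")


@dataclass
class GroundTruth:
    """Per-window aggregation of the realized noise, the quantities the
    rule-based labeler thresholds."""

    kind: str
    window_s: float
    wander_ratio: float = 0.0         # max |wander| / clean peak-to-peak
    impulse_count: int = 0
    dropout_s: float = 0.0
    emg_s: float = 0.0
    emg_rel_amp: float = 0.0
    unreadable_beats: int = 0         # ECG: cardiac cycles whose QRS is obscured
    regular_fraction: float = 1.0     # RESP: fraction of window with regular breathing
    apnea_s: float = 0.0              # RESP
    pathology: PathologySpec = field(default_factory=PathologySpec)


@dataclass
class SyntheticSignal:
    """A clean generated record plus its event-time ground truth."""

    record: SignalRecord
    event_times: np.ndarray           # beat instants (ECG) or breath peaks (RESP)
    event_types: tuple = ()           # per-beat: normal | VPB | APB
    trough_times: np.ndarray | None = None
    apnea_spans: tuple = ()
    pathology: PathologySpec = field(default_factory=PathologySpec)


@dataclass
class NoisySignal:
    """Corrupted record together with the realized noise components,
    from which per-window ground truth is derived deterministically."""

    record: SignalRecord
    clean: SyntheticSignal
    spec: NoiseSpec
    wander: np.ndarray
    powerline: np.ndarray
    emg: np.ndarray
    impulses: np.ndarray


# --------------------------------------------------------------------------
# clean generators

# (center offset s from R, width s, amplitude) per wave
_NORMAL_BEAT = (
    (-0.18, 0.025, 0.12),   # P
    (-0.026, 0.010, -0.10), # Q
    (0.0, 0.012, 1.00),     # R
    (0.028, 0.011, -0.18),  # S
    (0.22, 0.055, 0.28),    # T
)
# VPB: wide, high-amplitude QRS, no P wave, discordant T
_VPB_BEAT = (
    (0.0, 0.045, 1.55),
    (0.085, 0.035, -0.45),
    (0.33, 0.070, -0.32),
)

_RATE_MODE_BPM = {"tachycardia": 120.0, "bradycardia": 45.0}


def _beat_waveform(t: np.ndarray, center: float, waves) -> np.ndarray:
    out = np.zeros_like(t)
    for off, width, amp in waves:
        out += amp * np.exp(-0.5 * ((t - center - off) / width) ** 2)
    return out


def gen_clean_ecg(
    duration_s: float,
    fs: float = DEFAULT_FS[ECG],
    hr_bpm: float = 60.0,
    hrv_frac: float = 0.05,
    seed: int = 0,
    pathology: PathologySpec | None = None,
    record_id: str = "ecg",
) -> SyntheticSignal:
    """Generate clean single-lead ECG with P-QRS-T morphology.

    ``hrv_frac`` is the fractional standard deviation of the beat
    period.  ``pathology.rate_mode`` overrides the heart rate
    (tachycardia 120 bpm, bradycardia 45 bpm); ectopic beats replace the
    listed beat slots with premature (VPB: wide, large) complexes.
    """
    pathology = pathology or PathologySpec()
    pathology.validate()
    if duration_s < WINDOW_SECONDS[ECG]:
        raise ValueError("duration must cover at least one 10 s window")
    hr_bpm = _RATE_MODE_BPM.get(pathology.rate_mode, hr_bpm)
    if not 30 <= hr_bpm <= 220:
        raise ValueError("hr_bpm out of range [30, 220]")
    if not 0 <= hrv_frac < 0.3:
        raise ValueError("hrv_frac out of range [0, 0.3)")

    rng = np.random.default_rng(seed)
    period = 60.0 / hr_bpm
    n_beats = int(duration_s / period) + 2
    jitter = rng.standard_normal(n_beats) * hrv_frac if hrv_frac > 0 else np.zeros(n_beats)
    periods = period * (1.0 + np.clip(jitter, -0.29, 0.29))
    beat_times = 0.35 + np.concatenate(([0.0], np.cumsum(periods[:-1])))

    ectopic = set(pathology.ectopic_beat_indices)
    if ectopic and pathology.ectopic_type == "none":
        raise ValueError("ectopic indices given but ectopic_type is 'none'")
    if any(i < 1 or i >= n_beats for i in ectopic):
        raise ValueError("ectopic beat index out of range")
    beat_times = beat_times.copy()
    for i in sorted(ectopic):
        # premature slot: ectopic beat arrives at 60% of the nominal
        # coupling interval; the next beat keeps its grid position
        # (compensatory pause).
        beat_times[i] = beat_times[i - 1] + 0.6 * period

    keep = beat_times < duration_s - 0.05
    beat_times = beat_times[keep]
    types = tuple(
        pathology.ectopic_type if i in ectopic else "normal"
        for i in range(len(beat_times))
    )

    t = np.arange(int(round(duration_s * fs))) / fs
    x = np.zeros_like(t)
    for bt, btype in zip(beat_times, types):
        waves = _VPB_BEAT if btype == "VPB" else _NORMAL_BEAT
        lo = np.searchsorted(t, bt - 0.45)
        hi = np.searchsorted(t, bt + 0.55)
        x[lo:hi] += _beat_waveform(t[lo:hi], bt, waves)

    record = SignalRecord(samples=x, fs=fs, kind=ECG, record_id=record_id)
    return SyntheticSignal(
        record=record,
        event_times=np.asarray(beat_times),
        event_types=types,
        pathology=pathology,
    )


def gen_clean_resp(
    duration_s: float,
    fs: float = DEFAULT_FS[RESP],
    rr_bpm: float = 15.0,
    var_frac: float = 0.05,
    apnea_spans: tuple = (),
    seed: int = 0,
    record_id: str = "resp",
) -> SyntheticSignal:
    """Generate clean respiration: quasi-sinusoidal breathing with
    breath-to-breath period/amplitude jitter and near-flat apnea spans."""
    if duration_s < WINDOW_SECONDS[RESP]:
        raise ValueError("duration must cover at least one 30 s window")
    if not 5 <= rr_bpm <= 40:
        raise ValueError("rr_bpm out of range [5, 40]")
    for start, dur in apnea_spans:
        if dur <= 0 or start < 0 or start + dur > duration_s + 1e-9:
            raise ValueError(f"apnea span ({start}, {dur}) outside record")

    rng = np.random.default_rng(seed)
    period = 60.0 / rr_bpm
    n_breaths = int(duration_s / period) + 3
    pj = rng.standard_normal(n_breaths) * var_frac if var_frac > 0 else np.zeros(n_breaths)
    periods = period * (1.0 + np.clip(pj, -0.45, 0.45))
    aj = rng.standard_normal(n_breaths) * var_frac if var_frac > 0 else np.zeros(n_breaths)
    amps = np.clip(1.0 + aj, 0.3, None)

    starts = np.concatenate(([0.0], np.cumsum(periods)))
    t = np.arange(int(round(duration_s * fs))) / fs
    breath_idx = np.searchsorted(starts, t, side="right") - 1
    breath_idx = np.clip(breath_idx, 0, n_breaths - 1)
    phase = 2 * np.pi * (t - starts[breath_idx]) / periods[breath_idx]
    x = amps[breath_idx] * np.sin(phase)

    peak_times = starts[:-1] + periods * 0.25
    trough_times = starts[:-1] + periods * 0.75

    # apnea: ramp down over 0.5 s then hold the baseline
    apnea_spans = tuple(sorted(apnea_spans))
    for start, dur in apnea_spans:
        i0, i1 = int(start * fs), int((start + dur) * fs)
        ramp = np.clip((t[i0:i1] - start) / 0.5, 0.0, 1.0)
        x[i0:i1] = x[i0:i1] * (1.0 - ramp) ** 2 * 0.05

    def _outside(times):
        m = np.ones(len(times), bool)
        for start, dur in apnea_spans:
            m &= ~((times >= start) & (times < start + dur))
        return m

    keep_p = (peak_times < duration_s) & _outside(peak_times)
    keep_t = (trough_times < duration_s) & _outside(trough_times)

    record = SignalRecord(samples=x, fs=fs, kind=RESP, record_id=record_id)
    return SyntheticSignal(
        record=record,
        event_times=peak_times[keep_p],
        trough_times=trough_times[keep_t],
        apnea_spans=apnea_spans,
    )


# --------------------------------------------------------------------------
# noise injection


def _span_overlap_s(spans, start: float, end: float) -> float:
    return sum(max(0.0, min(end, s + d) - max(start, s)) for s, d in spans)


def inject_noise(clean: SyntheticSignal, spec: NoiseSpec) -> NoisySignal:
    """Additively corrupt a clean record, keeping every realized noise
    component so per-window ground truth stays computable.

    Baseline wander is a band-limited random walk plus a slow sinusoid,
    scaled so its peak deviation equals ``bw_rel_amp`` times the clean
    peak-to-peak amplitude.  Dropouts overwrite with the last held value
    (zero at record start); impulses are short high-amplitude
    deflections; EMG bursts are band-passed broadband noise inside their
    spans.
    """
    record = clean.record
    duration_s = record.duration_s
    spec.validate(duration_s)
    rng = np.random.default_rng(spec.seed)
    fs = record.fs
    n = len(record.samples)
    t = np.arange(n) / fs
    p2p = float(np.ptp(record.samples))
    if p2p == 0:
        p2p = 1.0

    wander = np.zeros(n)
    if spec.bw_rel_amp > 0:
        walk = np.cumsum(rng.standard_normal(n))
        lo, hi = spec.bw_freq_hz
        sos = sps.butter(2, [max(lo, 1e-3), min(hi, 0.45 * fs)], "bandpass", fs=fs, output="sos")
        walk = sps.sosfiltfilt(sos, walk)
        f0 = rng.uniform(max(lo, 1e-3), min(hi, 0.45 * fs))
        sine = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        raw = walk / (np.max(np.abs(walk)) or 1.0) + 0.6 * sine
        wander = raw / np.max(np.abs(raw)) * spec.bw_rel_amp * p2p

    powerline = np.zeros(n)
    if spec.powerline_rel_amp > 0:
        powerline = (
            spec.powerline_rel_amp * p2p / 2.0
            * np.sin(2 * np.pi * spec.powerline_hz * t + rng.uniform(0, 2 * np.pi))
        )

    emg = np.zeros(n)
    if spec.emg_rel_amp > 0 and spec.emg_burst_spans:
        hi_edge = 0.45 * fs
        sos = sps.butter(2, min(20.0, 0.5 * hi_edge), "highpass", fs=fs, output="sos")
        broadband = sps.sosfiltfilt(sos, rng.standard_normal(n))
        broadband /= np.std(broadband) or 1.0
        for start, dur in spec.emg_burst_spans:
            i0, i1 = int(start * fs), min(int((start + dur) * fs), n)
            emg[i0:i1] = broadband[i0:i1] * spec.emg_rel_amp * p2p / 2.0

    impulses = np.zeros(n)
    for ti in spec.impulse_times:
        amp = spec.impulse_rel_amp * p2p * (1 if rng.uniform() < 0.5 else -1)
        width = 0.015  # s
        lo_i = max(0, int((ti - 4 * width) * fs))
        hi_i = min(n, int((ti + 4 * width) * fs))
        impulses[lo_i:hi_i] += amp * np.exp(-0.5 * ((t[lo_i:hi_i] - ti) / width) ** 2)

    noisy = record.samples + wander + powerline + emg + impulses

    for start, dur in spec.dropout_spans:
        i0, i1 = int(start * fs), min(int((start + dur) * fs), n)
        held = noisy[i0 - 1] if i0 > 0 else 0.0
        noisy[i0:i1] = held

    out = SignalRecord(
        samples=noisy, fs=fs, kind=record.kind,
        t0=record.t0, record_id=record.record_id,
    )
    return NoisySignal(
        record=out, clean=clean, spec=spec,
        wander=wander, powerline=powerline, emg=emg, impulses=impulses,
    )


# --------------------------------------------------------------------------
# per-window ground truth and the rule-based labeler

#: Local noise RMS above this fraction of the clean beat amplitude marks
#: the cardiac cycle's QRS as unreadable.
UNREADABLE_SNR = 0.5

#: Breath periods within +/- this fraction of the record median count as
#: regular breathing.
REGULAR_PERIOD_BOUND = 0.25


def window_truth(noisy: NoisySignal, start_s: float, length_s: float | None = None) -> GroundTruth:
    """Aggregate realized noise over one observation window."""
    kind = noisy.record.kind
    if length_s is None:
        length_s = WINDOW_SECONDS[kind]
    end_s = start_s + length_s
    fs = noisy.record.fs
    i0, i1 = int(start_s * fs), int(end_s * fs)
    spec = noisy.spec

    clean_w = noisy.clean.record.samples[i0:i1]
    p2p = float(np.ptp(clean_w)) or 1.0
    wander_ratio = float(np.max(np.abs(noisy.wander[i0:i1]))) / p2p if i1 > i0 else 0.0
    impulse_count = sum(1 for ti in spec.impulse_times if start_s <= ti < end_s)
    dropout_s = _span_overlap_s(spec.dropout_spans, start_s, end_s)
    emg_s = _span_overlap_s(spec.emg_burst_spans, start_s, end_s)
    emg_rel = spec.emg_rel_amp if emg_s > 0 else 0.0

    truth = GroundTruth(
        kind=kind, window_s=length_s,
        wander_ratio=wander_ratio, impulse_count=impulse_count,
        dropout_s=dropout_s, emg_s=emg_s, emg_rel_amp=emg_rel,
        pathology=noisy.clean.pathology,
    )

    if kind == ECG:
        truth.unreadable_beats = _count_unreadable_beats(noisy, start_s, end_s)
    else:
        apnea_s = _span_overlap_s(noisy.clean.apnea_spans, start_s, end_s)
        truth.apnea_s = apnea_s
        truth.regular_fraction = _regular_fraction(noisy, start_s, end_s)
    return truth


def _count_unreadable_beats(noisy: NoisySignal, start_s: float, end_s: float) -> int:
    fs = noisy.record.fs
    beats = noisy.clean.event_times
    in_win = beats[(beats >= start_s) & (beats < end_s)]
    obscuring = noisy.emg + noisy.impulses
    count = 0
    for bt in in_win:
        # beats inside dropout are covered by the signal-loss clause and
        # are not double-counted as unreadable QRS
        if _span_overlap_s(noisy.spec.dropout_spans, bt - 0.15, bt + 0.15) > 0:
            continue
        i0 = max(0, int((bt - 0.15) * fs))
        i1 = min(len(obscuring), int((bt + 0.15) * fs))
        c0 = noisy.clean.record.samples[i0:i1]
        beat_amp = float(np.ptp(c0)) or 1.0
        noise_rms = float(np.sqrt(np.mean(obscuring[i0:i1] ** 2))) if i1 > i0 else 0.0
        if noise_rms > UNREADABLE_SNR * beat_amp:
            count += 1
    return count


def _regular_fraction(noisy: NoisySignal, start_s: float, end_s: float) -> float:
    """Fraction of the window covered by breaths with near-median period,
    outside apnea / dropout / EMG-burst spans."""
    clean = noisy.clean
    peaks = clean.event_times
    if len(peaks) < 2:
        return 0.0
    periods = np.diff(peaks)
    med = float(np.median(periods))
    bad_spans = tuple(clean.apnea_spans) + tuple(noisy.spec.dropout_spans) + tuple(
        noisy.spec.emg_burst_spans if noisy.spec.emg_rel_amp >= 0.05 else ()
    )
    regular = 0.0
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        lo, hi = max(p0, start_s), min(p1, end_s)
        if hi <= lo:
            continue
        if abs((p1 - p0) - med) > REGULAR_PERIOD_BOUND * med:
            continue
        regular += (hi - lo) - _span_overlap_s(bad_spans, lo, hi)
    return max(0.0, min(1.0, regular / (end_s - start_s)))


def label_window(truth: GroundTruth, kind: str | None = None) -> int:
    """Grade one window's ground truth with the quantitative criteria.

    The returned grade is the worst one triggered by any clause;
    pathology annotations never degrade the grade (ectopy is a rhythm
    property, not a quality defect).
    """
    kind = kind or truth.kind
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    if kind == ECG:
        # unacceptable: signal loss > 2 s, wander beyond the signal
        # amplitude, > 2 impulse artifacts, or >= 2 unreadable QRS cycles
        if (
            truth.dropout_s > 2.0
            or truth.wander_ratio >= 1.0
            or truth.impulse_count > 2
            or truth.unreadable_beats >= 2
        ):
            return UNACCEPTABLE
        # acceptable: any signal loss (< 2 s), wander above one-third of
        # the signal amplitude, 1-2 impulses, one unreadable cycle, or a
        # non-trivial EMG burst
        if (
            truth.dropout_s > 0.0
            or truth.wander_ratio >= 1.0 / 3.0
            or truth.impulse_count >= 1
            or truth.unreadable_beats >= 1
            or (truth.emg_s > 0 and truth.emg_rel_amp >= 0.05)
        ):
            return ACCEPTABLE
        return GOOD
    # RESP
    loss_s = truth.dropout_s + truth.apnea_s
    if (
        truth.regular_fraction < 0.25
        or truth.wander_ratio >= 2.0
        or loss_s >= truth.window_s / 2.0
    ):
        return UNACCEPTABLE
    if truth.regular_fraction > 0.75 and truth.wander_ratio < 1.0:
        return GOOD
    return ACCEPTABLE


# --------------------------------------------------------------------------
# dataset assembly


@dataclass
class DatasetConfig:
    """Sizes, grade mixture and severity recipes for a benchmark split.

    The training set is unlabeled and dominated by clean/mildly noisy
    signal (the anomaly-detection premise that anomalies are few);
    validation and test windows carry rule-derived labels with the
    configured grade mixture.
    """

    kind: str = ECG
    fs: float | None = None
    n_train: int = 1200
    n_validation: int = 1200
    n_test: int = 1000
    train_mix: tuple = (0.90, 0.05, 0.05)
    validation_mix: tuple = (0.8734, 0.0546, 0.0720)
    test_mix: tuple = (0.8039, 0.0606, 0.1355)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.fs is None:
            self.fs = DEFAULT_FS[self.kind]
        for name in ("train_mix", "validation_mix", "test_mix"):
            mix = getattr(self, name)
            if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1) > 1e-6:
                raise ValueError(f"{name} must be 3 non-negative proportions summing to 1")


@dataclass
class GeneratedWindow:
    """One single-window synthetic record with its truth and rule label."""

    noisy: NoisySignal
    truth: GroundTruth
    grade: int | None

    @property
    def record(self) -> SignalRecord:
        return self.noisy.record


@dataclass
class SyntheticDataset:
    config: DatasetConfig
    train: list
    validation: list
    test: list


def _ecg_recipe(grade: int, rng: np.random.Generator, window_s: float) -> NoiseSpec:
    """Draw a noise spec whose rule label is the requested grade by
    construction (mixing the defect classes the grade admits)."""
    seed = int(rng.integers(2**31))
    if grade == GOOD:
        return NoiseSpec(
            bw_rel_amp=rng.uniform(0.0, 0.25),
            powerline_rel_amp=rng.uniform(0.0, 0.04),
            seed=seed,
        )
    if grade == ACCEPTABLE:
        mode = rng.integers(4)
        spec = NoiseSpec(
            bw_rel_amp=rng.uniform(0.0, 0.25),
            powerline_rel_amp=rng.uniform(0.0, 0.05),
            seed=seed,
        )
        if mode == 0:
            spec = replace(spec, bw_rel_amp=rng.uniform(0.40, 0.90))
        elif mode == 1:
            n_imp = int(rng.integers(1, 3))
            times = tuple(np.sort(rng.uniform(0.5, window_s - 0.5, n_imp)))
            spec = replace(spec, impulse_times=times, impulse_rel_amp=rng.uniform(1.5, 3.0))
        elif mode == 2:
            start = rng.uniform(0.5, window_s - 2.3)
            spec = replace(spec, dropout_spans=((start, rng.uniform(0.5, 1.8)),))
        else:
            start = rng.uniform(0.5, window_s - 2.6)
            spec = replace(
                spec,
                emg_rel_amp=rng.uniform(0.08, 0.22),
                emg_burst_spans=((start, rng.uniform(1.0, 2.0)),),
            )
        return spec
    mode = rng.integers(4)
    spec = NoiseSpec(seed=seed, powerline_rel_amp=rng.uniform(0.0, 0.05))
    if mode == 0:
        start = rng.uniform(0.0, window_s - 6.1)
        spec = replace(spec, dropout_spans=((start, rng.uniform(2.5, 6.0)),))
    elif mode == 1:
        start = rng.uniform(0.0, window_s - 8.1)
        spec = replace(
            spec,
            emg_rel_amp=rng.uniform(1.5, 2.5),
            emg_burst_spans=((start, rng.uniform(4.0, 8.0)),),
        )
    elif mode == 2:
        spec = replace(spec, bw_rel_amp=rng.uniform(1.2, 2.5))
    else:
        n_imp = int(rng.integers(3, 7))
        times = tuple(np.sort(rng.uniform(0.3, window_s - 0.3, n_imp)))
        spec = replace(spec, impulse_times=times, impulse_rel_amp=rng.uniform(2.0, 4.0))
    return spec


def _resp_recipe(grade: int, rng: np.random.Generator, window_s: float):
    """Return (NoiseSpec, apnea_spans, var_frac) hitting the requested grade."""
    seed = int(rng.integers(2**31))
    if grade == GOOD:
        spec = NoiseSpec(bw_rel_amp=rng.uniform(0.0, 0.5), seed=seed)
        return spec, (), rng.uniform(0.02, 0.10)
    if grade == ACCEPTABLE:
        mode = rng.integers(3)
        spec = NoiseSpec(bw_rel_amp=rng.uniform(0.0, 0.5), seed=seed)
        apnea, var = (), rng.uniform(0.02, 0.10)
        if mode == 0:
            start = rng.uniform(1.0, window_s - 14.2)
            apnea = ((start, rng.uniform(8.0, 14.0)),)
        elif mode == 1:
            spec = replace(spec, bw_rel_amp=rng.uniform(1.1, 1.8))
        else:
            start = rng.uniform(1.0, window_s - 13.2)
            spec = replace(
                spec,
                emg_rel_amp=rng.uniform(0.3, 0.8),
                emg_burst_spans=((start, rng.uniform(8.0, 13.0)),),
            )
        return spec, apnea, var
    mode = rng.integers(3)
    spec = NoiseSpec(seed=seed)
    apnea, var = (), rng.uniform(0.02, 0.10)
    if mode == 0:
        start = rng.uniform(0.0, window_s - 24.1)
        apnea = ((start, rng.uniform(16.0, 24.0)),)
    elif mode == 1:
        spec = replace(spec, bw_rel_amp=rng.uniform(2.2, 4.0))
    else:
        start = rng.uniform(0.0, window_s - 25.0)
        spec = replace(
            spec,
            emg_rel_amp=rng.uniform(0.9, 2.0),
            emg_burst_spans=((start, rng.uniform(24.0, min(28.0, window_s - start))),),
        )
    return spec, apnea, var


def _gen_window(kind: str, fs: float, grade: int, rng: np.random.Generator,
                record_id: str) -> GeneratedWindow:
    window_s = WINDOW_SECONDS[kind]
    if kind == ECG:
        pathology = PathologySpec()
        hr = rng.uniform(55, 95)
        # occasional ectopy in clean-ish signal: pathology must not
        # degrade the grade
        if grade == GOOD and rng.uniform() < 0.08:
            n_beats = int(window_s / (60 / hr))
            idx = int(rng.integers(2, max(3, n_beats - 2)))
            pathology = PathologySpec(ectopic_type="VPB" if rng.uniform() < 0.6 else "APB",
                                      ectopic_beat_indices=(idx,))
        clean = gen_clean_ecg(
            window_s, fs=fs, hr_bpm=hr, hrv_frac=rng.uniform(0.02, 0.10),
            seed=int(rng.integers(2**31)), pathology=pathology, record_id=record_id,
        )
        spec = _ecg_recipe(grade, rng, window_s)
        noisy = inject_noise(clean, spec)
    else:
        spec, apnea, var = _resp_recipe(grade, rng, window_s)
        clean = gen_clean_resp(
            window_s, fs=fs, rr_bpm=rng.uniform(10, 20), var_frac=var,
            apnea_spans=apnea, seed=int(rng.integers(2**31)), record_id=record_id,
        )
        noisy = inject_noise(clean, spec)
    truth = window_truth(noisy, 0.0, window_s)
    return GeneratedWindow(noisy=noisy, truth=truth, grade=label_window(truth))


def make_dataset(config: DatasetConfig) -> SyntheticDataset:
    """Generate disjoint train / validation / test splits.

    Training windows are unlabeled (their ``grade`` is None) and drawn
    from a clean-dominated mixture; validation and test windows carry
    rule-derived labels at the configured grade mixture.
    """
    rng = np.random.default_rng(config.seed)
    splits = {}
    for split, n, mix in (
        ("train", config.n_train, config.train_mix),
        ("val", config.n_validation, config.validation_mix),
        ("test", config.n_test, config.test_mix),
    ):
        windows = []
        targets = rng.choice(3, size=n, p=mix)
        for i, g in enumerate(targets):
            rid = f"{config.kind.lower()}-{split}-{i:05d}"
            w = _gen_window(config.kind, config.fs, int(g), rng, rid)
            if split == "train":
                w.grade = None
            windows.append(w)
        splits[split] = windows
    return SyntheticDataset(
        config=config, train=splits["train"],
        validation=splits["val"], test=splits["test"],
    )
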