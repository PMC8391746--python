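"""Signal-quality feature extraction.

Each conditioned window is summarized by a fixed-order vector of
signal-quality indices: the classic distribution moments (sSQI =
skewness, kSQI = kurtosis, population convention, non-excess), dynamic
time warping distances between adjacent beats/breaths, rhythm-detector
statistics, and Welch power-spectrum descriptors.  ECG windows map to 8
features and respiratory windows to 18; the identities are fixed module
constants so serialized feature matrices are stable.

Flatline-flagged windows yield a documented sentinel vector instead of
being dropped: signal loss must stay visible to the anomaly model.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import signal as sps

from .records import ECG, RESP, ObservationWindow

__all__ = [
    "ECG_FEATURES",
    "RESP_FEATURES",
    "skewness",
    "kurtosis",
    "dtw_distance",
    "BeatSegmentation",
    "detect_r_peaks",
    "detect_breath_extrema",
    "adjacent_waveform_dtw_stats",
    "spectral_features",
    "ecg_feature_vector",
    "resp_feature_vector",
    "feature_vector",
    "feature_names",
]

#: Fixed ECG feature order (8 features).
ECG_FEATURES = (
    "skewness",
    "kurtosis",
    "dtw_mean",
    "dtw_max",
    "rate_deviation",
    "p2p_ratio",
    "qrs_band_fraction",
    "hf_fraction",
)

#: Fixed respiratory feature order (18 features).
RESP_FEATURES = (
    "skewness",
    "kurtosis",
    "dtw_mean",
    "dtw_max",
    "dtw_sd",
    "breath_count",
    "period_mean",
    "period_sd",
    "period_cv",
    "peak_amp_mean",
    "peak_amp_sd",
    "peak_amp_cv",
    "trough_asymmetry",
    "zero_crossing_rate",
    "resp_band_fraction",
    "hf_fraction",
    "spectral_entropy",
    "dominant_freq",
)

#: Sentinel DTW distance reported when fewer than 3 beats are available
#: (rhythm unassessable); far above any clean adjacent-beat distance.
DTW_SENTINEL = 10.0

#: Beats are resampled to this many samples (and z-normalized) before DTW.
BEAT_RESAMPLE_N = 64


def feature_names(kind: str) -> tuple:
    return ECG_FEATURES if kind == ECG else RESP_FEATURES


# --------------------------------------------------------------------------
# distribution moments (population convention, non-excess kurtosis)


def _moments(x) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    mu = x.mean()
    sigma = np.sqrt(np.mean((x - mu) ** 2))
    if sigma == 0:
        raise ValueError("zero standard deviation (flatline input)")
    z = (x - mu) / sigma
    return float(np.mean(z**3)), float(np.mean(z**4))


def skewness(x) -> float:
    """Third standardized central moment (population convention)."""
    return _moments(x)[0]


def kurtosis(x) -> float:
    """Fourth standardized central moment, non-excess (Gaussian -> 3)."""
    return _moments(x)[1]


# --------------------------------------------------------------------------
# dynamic time warping


@njit(cache=True)
def _dtw_kernel(a, b):  # pragma: no cover - exercised through dtw_distance
    n, m = len(a), len(b)
    big = 1e300
    d = np.empty((n + 1, m + 1))
    d[0, :] = big
    d[:, 0] = big
    d[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = abs(a[i - 1] - b[j - 1])
            prev = d[i - 1, j - 1]
            if d[i - 1, j] < prev:
                prev = d[i - 1, j]
            if d[i, j - 1] < prev:
                prev = d[i, j - 1]
            d[i, j] = cost + prev
    return d[n, m]


def dtw_distance(a, b) -> float:
    """Classic dynamic-programming DTW distance with absolute-difference
    local cost and an unconstrained warping window.

    Symmetric, non-negative, and zero iff the sequences are equal up to
    repetition of samples along the warping path.
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    return float(_dtw_kernel(a, b))


# --------------------------------------------------------------------------
# beat / breath segmentation


class BeatSegmentation:
    """Detected fiducial points of one window.

    For ECG, ``peaks`` holds R-peak sample indices.  For respiration,
    ``peaks`` and ``troughs`` hold breath extrema with alternation
    enforced.
    """

    def __init__(self, peaks, fs: float, troughs=None):
        self.peaks = np.asarray(peaks, dtype=int)
        self.troughs = None if troughs is None else np.asarray(troughs, dtype=int)
        self.fs = float(fs)

    @property
    def peak_times(self) -> np.ndarray:
        return self.peaks / self.fs

    def beat_spans(self, n_samples: int) -> list[tuple[int, int]]:
        """Non-overlapping per-beat spans bounded by midpoints between
        adjacent peaks."""
        p = self.peaks
        if len(p) == 0:
            return []
        mids = ((p[:-1] + p[1:]) // 2).tolist()
        bounds = [0] + mids + [n_samples]
        return [(bounds[i], bounds[i + 1]) for i in range(len(p))]


def detect_r_peaks(x, fs: float, refractory_s: float = 0.25) -> BeatSegmentation:
    """Derivative-square-integrate R-peak detector with an adaptive
    threshold; pure noise may legitimately yield no peaks."""
    x = np.asarray(x, dtype=float)
    if len(x) < int(fs):
        return BeatSegmentation([], fs)
    deriv = np.gradient(x)
    energy = deriv**2
    win = max(1, int(0.15 * fs))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    height = 0.18 * np.percentile(integ, 99)
    if height <= 0:
        return BeatSegmentation([], fs)
    locs, _ = sps.find_peaks(integ, height=height, distance=max(1, int(refractory_s * fs)))
    # refine each detection to the local extremum of the waveform itself
    half = int(0.10 * fs)
    refined = []
    med = np.median(x)
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(x), loc + half + 1)
        refined.append(lo + int(np.argmax(np.abs(x[lo:hi] - med))))
    refined = np.unique(refined)
    # re-apply refractory after refinement
    keep = []
    for r in refined:
        if keep and (r - keep[-1]) < refractory_s * fs:
            if np.abs(x[r] - med) > np.abs(x[keep[-1]] - med):
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    return BeatSegmentation(keep, fs)


def detect_breath_extrema(x, fs: float, min_period_s: float = 1.5) -> BeatSegmentation:
    """Smoothed local-extremum breath detector; alternating peak/trough
    sequence enforced by keeping the most prominent of any same-type run."""
    x = np.asarray(x, dtype=float)
    if len(x) < int(min_period_s * fs) or np.ptp(x) == 0:
        return BeatSegmentation([], fs, troughs=[])
    win = max(1, int(0.4 * fs))
    smooth = np.convolve(x, np.ones(win) / win, mode="same")
    dist = max(1, int(min_period_s * fs))
    prom = 0.25 * np.std(smooth)
    peaks, _ = sps.find_peaks(smooth, distance=dist, prominence=prom)
    troughs, _ = sps.find_peaks(-smooth, distance=dist, prominence=prom)
    events = sorted(
        [(int(i), 1, smooth[i]) for i in peaks] + [(int(i), -1, smooth[i]) for i in troughs]
    )
    cleaned: list[tuple[int, int, float]] = []
    for idx, typ, val in events:
        if cleaned and cleaned[-1][1] == typ:
            # same-type run: keep the more extreme one
            if (typ == 1 and val > cleaned[-1][2]) or (typ == -1 and val < cleaned[-1][2]):
                cleaned[-1] = (idx, typ, val)
        else:
            cleaned.append((idx, typ, val))
    return BeatSegmentation(
        [i for i, typ, _ in cleaned if typ == 1],
        fs,
        troughs=[i for i, typ, _ in cleaned if typ == -1],
    )


# --------------------------------------------------------------------------
# derived statistics


def _znorm_resample(seg: np.ndarray, n: int = BEAT_RESAMPLE_N) -> np.ndarray:
    seg = np.asarray(seg, dtype=float)
    grid = np.linspace(0, len(seg) - 1, n)
    out = np.interp(grid, np.arange(len(seg)), seg)
    sd = np.std(out)
    return (out - np.mean(out)) / sd if sd > 0 else out - np.mean(out)


def adjacent_waveform_dtw_stats(x, seg: BeatSegmentation,
                                sentinel: float = DTW_SENTINEL) -> tuple[float, float, float]:
    """(mean, max, SD) of DTW distances between consecutive beats.

    Beats are cut to a fixed width centered on each fiducial (0.3 of the
    median beat period on each side, enough for the full P-QRS-T complex
    while excluding neighbouring complexes; beats whose span does not fit the
    window are skipped), resampled to a common length and z-normalized
    so the comparison is purely morphological.  With fewer than 3 usable
    beats the rhythm is unassessable and the sentinel triple is
    returned.
    """
    x = np.asarray(x, dtype=float)
    peaks = seg.peaks
    if len(peaks) < 3:
        return (sentinel, sentinel, sentinel)
    half = int(0.3 * float(np.median(np.diff(peaks))))
    beats = []
    for pk in peaks:
        lo, hi = pk - half, pk + half + 1
        if lo >= 0 and hi <= len(x) and hi - lo >= 3:
            beats.append(_znorm_resample(x[lo:hi]))
    if len(beats) < 3:
        return (sentinel, sentinel, sentinel)
    dists = np.array([dtw_distance(beats[i], beats[i + 1]) for i in range(len(beats) - 1)])
    # scale: distances grow with resample length; normalize per sample
    dists = dists / BEAT_RESAMPLE_N
    return (float(dists.mean()), float(dists.max()), float(dists.std()))


def spectral_features(x, fs: float, kind: str) -> dict:
    """Welch-PSD descriptors: in-band power fraction, high-frequency
    fraction, spectral entropy (nats) and dominant frequency."""
    x = np.asarray(x, dtype=float)
    nperseg = min(len(x), 512 if kind == ECG else 256)
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    total = float(np.sum(psd))
    if total <= 0:
        return {
            "band_fraction": 0.0, "hf_fraction": 0.0,
            "spectral_entropy": 0.0, "dominant_freq": 0.0,
        }
    if kind == ECG:
        band = (freqs >= 5.0) & (freqs <= 15.0)
        hf = freqs >= 20.0
    else:
        band = (freqs >= 0.1) & (freqs <= 0.6)
        hf = freqs >= 1.0
    p = psd / total
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    return {
        "band_fraction": float(np.sum(psd[band]) / total),
        "hf_fraction": float(np.sum(psd[hf]) / total),
        "spectral_entropy": entropy,
        "dominant_freq": float(freqs[int(np.argmax(psd))]),
    }


# --------------------------------------------------------------------------
# feature vectors

_ECG_SENTINEL = {
    "skewness": 0.0, "kurtosis": 0.0,
    "dtw_mean": DTW_SENTINEL, "dtw_max": DTW_SENTINEL,
    "rate_deviation": 20.0, "p2p_ratio": 0.0,
    "qrs_band_fraction": 0.0, "hf_fraction": 0.0,
}
_RESP_SENTINEL = {
    "skewness": 0.0, "kurtosis": 0.0,
    "dtw_mean": DTW_SENTINEL, "dtw_max": DTW_SENTINEL, "dtw_sd": DTW_SENTINEL,
    "breath_count": 0.0, "period_mean": 0.0, "period_sd": 0.0, "period_cv": 0.0,
    "peak_amp_mean": 0.0, "peak_amp_sd": 0.0, "peak_amp_cv": 0.0,
    "trough_asymmetry": 0.0, "zero_crossing_rate": 0.0,
    "resp_band_fraction": 0.0, "hf_fraction": 0.0,
    "spectral_entropy": 0.0, "dominant_freq": 0.0,
}


def _as_vector(values: dict, names: tuple) -> np.ndarray:
    vec = np.array([values[n] for n in names], dtype=float)
    return np.nan_to_num(vec, nan=0.0, posinf=DTW_SENTINEL, neginf=-DTW_SENTINEL)


def ecg_feature_vector(window: ObservationWindow) -> np.ndarray:
    """Compute the 8 ECG quality features of one conditioned window."""
    if window.flags.get("flatline"):
        return _as_vector(_ECG_SENTINEL, ECG_FEATURES)
    x = window.samples
    fs = window.fs
    sk, ku = _moments(x)
    seg = detect_r_peaks(x, fs)
    dtw_mean, dtw_max, _ = adjacent_waveform_dtw_stats(x, seg)

    n_peaks = len(seg.peaks)
    if n_peaks >= 2:
        rr_med = float(np.median(np.diff(seg.peak_times)))
        expected = window.length_s / rr_med
        rate_dev = abs(n_peaks - expected)
    else:
        rate_dev = _ECG_SENTINEL["rate_deviation"]

    # amplitude stability over 1 s subwindows
    sub = int(fs)
    n_sub = len(x) // sub
    p2ps = np.array([np.ptp(x[i * sub : (i + 1) * sub]) for i in range(n_sub)])
    med_p2p = float(np.median(p2ps))
    p2p_ratio = float(np.max(p2ps) / med_p2p) if med_p2p > 0 else 0.0

    spec = spectral_features(x, fs, ECG)
    return _as_vector(
        {
            "skewness": sk, "kurtosis": ku,
            "dtw_mean": dtw_mean, "dtw_max": dtw_max,
            "rate_deviation": rate_dev, "p2p_ratio": p2p_ratio,
            "qrs_band_fraction": spec["band_fraction"],
            "hf_fraction": spec["hf_fraction"],
        },
        ECG_FEATURES,
    )


def resp_feature_vector(window: ObservationWindow) -> np.ndarray:
    """Compute the 18 respiratory quality features of one conditioned window."""
    if window.flags.get("flatline"):
        return _as_vector(_RESP_SENTINEL, RESP_FEATURES)
    x = window.samples
    fs = window.fs
    sk, ku = _moments(x)
    seg = detect_breath_extrema(x, fs)
    dtw_mean, dtw_max, dtw_sd = adjacent_waveform_dtw_stats(x, seg)

    peaks = seg.peaks
    troughs = seg.troughs if seg.troughs is not None else np.array([], int)
    values = dict(_RESP_SENTINEL)
    values.update(
        skewness=sk, kurtosis=ku,
        dtw_mean=dtw_mean, dtw_max=dtw_max, dtw_sd=dtw_sd,
        breath_count=float(len(peaks)),
    )
    if len(peaks) >= 2:
        periods = np.diff(peaks) / fs
        pm, psd_ = float(periods.mean()), float(periods.std())
        values.update(period_mean=pm, period_sd=psd_,
                      period_cv=psd_ / pm if pm > 0 else 0.0)
    if len(peaks) >= 1:
        amps = x[peaks]
        am, asd = float(amps.mean()), float(amps.std())
        values.update(peak_amp_mean=am, peak_amp_sd=asd,
                      peak_amp_cv=asd / abs(am) if am != 0 else 0.0)
    if len(peaks) >= 1 and len(troughs) >= 1:
        pa = float(np.mean(np.abs(x[peaks])))
        ta = float(np.mean(np.abs(x[troughs])))
        values["trough_asymmetry"] = (pa - ta) / (pa + ta) if pa + ta > 0 else 0.0

    zc = np.sum(np.diff(np.signbit(x - np.mean(x))) != 0)
    values["zero_crossing_rate"] = float(zc) / window.length_s

    spec = spectral_features(x, fs, RESP)
    values.update(
        resp_band_fraction=spec["band_fraction"],
        hf_fraction=spec["hf_fraction"],
        spectral_entropy=spec["spectral_entropy"],
        dominant_freq=spec["dominant_freq"],
    )
    return _as_vector(values, RESP_FEATURES)


def feature_vector(window: ObservationWindow) -> np.ndarray:
    """Dispatch on window kind."""
    return ecg_feature_vector(window) if window.kind == ECG else resp_feature_vector(window)
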