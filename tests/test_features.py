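"""Feature extraction: moment formulas against a direct-evaluation
oracle, DTW against exhaustive warping-path enumeration, detectors
against generator ground truth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from wearsqa.features import (
    DTW_SENTINEL,
    ECG_FEATURES,
    RESP_FEATURES,
    adjacent_waveform_dtw_stats,
    detect_breath_extrema,
    detect_r_peaks,
    dtw_distance,
    ecg_feature_vector,
    kurtosis,
    resp_feature_vector,
    skewness,
    spectral_features,
)
from wearsqa.preprocess import condition_record
from wearsqa.records import ECG, RESP, ObservationWindow
from wearsqa.synth import PathologySpec, gen_clean_ecg, gen_clean_resp


# --------------------------------------------------------------------------
# independent oracles


def moment_oracle(x, order):
    """Direct evaluation of the standardized central moment with exact
    (fsum) accumulation — independent of the vectorized implementation."""
    xs = [float(v) for v in x]
    n = len(xs)
    mu = math.fsum(xs) / n
    var = math.fsum((v - mu) ** 2 for v in xs) / n
    sigma = math.sqrt(var)
    return math.fsum(((v - mu) / sigma) ** order for v in xs) / n


def dtw_bruteforce(a, b):
    """Minimum path cost over ALL monotone warping paths, by exhaustive
    recursion from cell (n-1, m-1) back to (0, 0)."""

    def best(i, j):
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        options = []
        if i > 0:
            options.append(best(i - 1, j))
        if j > 0:
            options.append(best(i, j - 1))
        if i > 0 and j > 0:
            options.append(best(i - 1, j - 1))
        return cost + min(options)

    return best(len(a) - 1, len(b) - 1)


# --------------------------------------------------------------------------
# moments


class TestMoments:
    def test_symmetric_vector_has_zero_skew(self):
        assert skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-15)

    def test_two_point_symmetric_kurtosis_is_one(self):
        assert kurtosis([-1.0, 1.0, -1.0, 1.0]) == pytest.approx(1.0, abs=1e-15)

    def test_closed_form_single_spike(self):
        # [0,0,0,1]: skew = 2/sqrt(3), kurtosis = 7/3 by direct evaluation
        assert skewness([0.0, 0.0, 0.0, 1.0]) == pytest.approx(2 / math.sqrt(3), abs=1e-12)
        assert kurtosis([0.0, 0.0, 0.0, 1.0]) == pytest.approx(7 / 3, abs=1e-12)

    def test_against_direct_moment_oracle(self, rng):
        for _ in range(50):
            x = rng.standard_normal(rng.integers(5, 200))
            assert skewness(x) == pytest.approx(moment_oracle(x, 3), abs=1e-12)
            assert kurtosis(x) == pytest.approx(moment_oracle(x, 4), abs=1e-12)

    def test_permutation_invariance(self, rng):
        x = rng.standard_normal(50)
        assert skewness(x) == pytest.approx(skewness(x[::-1]), abs=1e-13)

    def test_gaussian_kurtosis_near_three(self):
        x = np.random.default_rng(777).standard_normal(100_000)
        assert kurtosis(x) == pytest.approx(3.0, abs=0.2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            skewness([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            kurtosis([1.0, 2.0])


# --------------------------------------------------------------------------
# DTW


class TestDTW:
    def test_matches_bruteforce_enumeration_on_short_pairs(self, rng):
        for _ in range(40):
            a = rng.standard_normal(rng.integers(1, 6))
            b = rng.standard_normal(rng.integers(1, 6))
            assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b), abs=1e-12)

    def test_known_small_instance(self):
        a, b = [0.0, 0.0, 1.0, 0.0], [0.0, 1.0, 0.0]
        assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(arrays(float, st.integers(1, 30),
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_identity(self, a):
        assert dtw_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        arrays(float, st.integers(1, 20), elements=st.floats(-50, 50, allow_nan=False)),
        arrays(float, st.integers(1, 20), elements=st.floats(-50, 50, allow_nan=False)),
    )
    def test_symmetry_and_nonnegativity(self, a, b):
        d = dtw_distance(a, b)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(b, a), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


# --------------------------------------------------------------------------
# detectors


def _conditioned(sig):
    return condition_record(sig.record)[0]


class TestDetectors:
    def test_r_peaks_match_ground_truth(self):
        sig = gen_clean_ecg(10, hr_bpm=60, hrv_frac=0.0, seed=1)
        win = _conditioned(sig)
        seg = detect_r_peaks(win.samples, win.fs)
        truth = sig.event_times[sig.event_times < 10.0]
        assert abs(len(seg.peaks) - len(truth)) <= 1
        detected = seg.peak_times
        for bt in truth:
            assert np.min(np.abs(detected - bt)) < 0.05

    def test_r_peaks_flatline_none(self):
        seg = detect_r_peaks(np.zeros(2000), 200.0)
        assert len(seg.peaks) == 0

    def test_vpb_still_detected(self):
        pat = PathologySpec(ectopic_type="VPB", ectopic_beat_indices=(5,))
        clean = gen_clean_ecg(10, hr_bpm=60, hrv_frac=0.0, seed=1)
        ect = gen_clean_ecg(10, hr_bpm=60, hrv_frac=0.0, seed=1, pathology=pat)
        n_clean = len(detect_r_peaks(_conditioned(clean).samples, 200.0).peaks)
        n_ect = len(detect_r_peaks(_conditioned(ect).samples, 200.0).peaks)
        assert n_ect == n_clean

    def test_breath_extrema_count_and_alternation(self):
        sig = gen_clean_resp(30, rr_bpm=12, var_frac=0.0, seed=2)
        win = _conditioned(sig)
        seg = detect_breath_extrema(win.samples, win.fs)
        assert abs(len(seg.peaks) - 6) <= 1
        events = sorted([(i, 1) for i in seg.peaks] + [(i, -1) for i in seg.troughs])
        types = [t for _, t in events]
        assert all(a != b for a, b in zip(types, types[1:]))

    def test_breath_extrema_flatline_none(self):
        seg = detect_breath_extrema(np.zeros(750), 25.0)
        assert len(seg.peaks) == 0 and len(seg.troughs) == 0


class TestDtwStats:
    def test_clean_periodic_ecg_has_small_adjacent_dtw(self):
        sig = gen_clean_ecg(10, hr_bpm=60, hrv_frac=0.0, seed=3)
        win = _conditioned(sig)
        seg = detect_r_peaks(win.samples, win.fs)
        mean, mx, sd = adjacent_waveform_dtw_stats(win.samples, seg)
        assert mean < 0.05  # per-sample distance on z-normalized beats
        assert sd >= 0 and mx >= mean

    def test_vpb_inflates_max_over_mean(self):
        pat = PathologySpec(ectopic_type="VPB", ectopic_beat_indices=(5,))
        sig = gen_clean_ecg(10, hr_bpm=60, hrv_frac=0.0, seed=3, pathology=pat)
        win = _conditioned(sig)
        seg = detect_r_peaks(win.samples, win.fs)
        mean, mx, _ = adjacent_waveform_dtw_stats(win.samples, seg)
        assert mx > 3 * mean

    def test_too_few_beats_gives_sentinel(self):
        from wearsqa.features import BeatSegmentation

        seg = BeatSegmentation([100, 500], 200.0)
        assert adjacent_waveform_dtw_stats(np.zeros(2000), seg) == (
            DTW_SENTINEL, DTW_SENTINEL, DTW_SENTINEL)


class TestSpectral:
    def test_in_band_tone_dominates(self):
        fs = 200.0
        t = np.arange(2000) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        out = spectral_features(tone, fs, ECG)
        assert out["band_fraction"] > 0.95

    def test_white_noise_entropy_near_maximum(self):
        x = np.random.default_rng(5).standard_normal(2000)
        out = spectral_features(x, 200.0, ECG)
        n_bins = 512 // 2 + 1
        assert out["spectral_entropy"] > 0.9 * np.log(n_bins)

    def test_dominant_frequency_of_breathing_tone(self):
        fs = 25.0
        t = np.arange(750) / fs
        out = spectral_features(np.sin(2 * np.pi * 0.2 * t), fs, RESP)
        assert out["dominant_freq"] == pytest.approx(0.2, abs=fs / 256)


class TestFeatureVectors:
    def test_arity_and_finiteness(self):
        ecg = gen_clean_ecg(10, seed=6)
        v = ecg_feature_vector(_conditioned(ecg))
        assert v.shape == (len(ECG_FEATURES),) and np.all(np.isfinite(v))
        resp = gen_clean_resp(30, seed=6)
        v = resp_feature_vector(_conditioned(resp))
        assert v.shape == (len(RESP_FEATURES),) and np.all(np.isfinite(v))

    def test_flatline_window_yields_sentinel_vector(self):
        win = ObservationWindow(record_id="r", start_s=0, length_s=10, fs=200.0,
                                kind=ECG, samples=np.zeros(2000),
                                flags={"flatline": True})
        v = ecg_feature_vector(win)
        assert v[ECG_FEATURES.index("dtw_mean")] == DTW_SENTINEL
        assert np.all(np.isfinite(v))

    def test_determinism(self):
        sig = gen_clean_ecg(10, seed=8)
        w = _conditioned(sig)
        assert np.array_equal(ecg_feature_vector(w), ecg_feature_vector(w))
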