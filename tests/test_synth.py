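"""Generator determinism, noise bookkeeping, and the rule-based labeler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearsqa.records import ACCEPTABLE, ECG, GOOD, RESP, UNACCEPTABLE
from wearsqa.synth import (
    DatasetConfig,
    GroundTruth,
    NoiseSpec,
    PathologySpec,
    gen_clean_ecg,
    gen_clean_resp,
    inject_noise,
    label_window,
    make_dataset,
    window_truth,
)


class TestCleanGenerators:
    def test_zero_hrv_gives_constant_beat_period(self):
        sig = gen_clean_ecg(60, hr_bpm=60, hrv_frac=0.0, seed=0)
        intervals = np.diff(sig.event_times)
        assert np.allclose(intervals, 1.0)
        assert abs(len(sig.event_times) - 60) <= 1

    def test_ecg_beats_have_qrs_morphology(self):
        sig = gen_clean_ecg(10, hr_bpm=60, hrv_frac=0.0, seed=3)
        x, fs = sig.record.samples, sig.record.fs
        for bt in sig.event_times:
            i = int(bt * fs)
            lo, hi = max(0, i - int(0.05 * fs)), i + int(0.05 * fs)
            # R wave dominates its local neighbourhood
            assert x[lo:hi].max() > 0.9

    def test_seed_determinism(self):
        a = gen_clean_ecg(12, hr_bpm=72, hrv_frac=0.08, seed=42)
        b = gen_clean_ecg(12, hr_bpm=72, hrv_frac=0.08, seed=42)
        assert np.array_equal(a.record.samples, b.record.samples)
        r1 = gen_clean_resp(30, rr_bpm=14, var_frac=0.1, seed=9)
        r2 = gen_clean_resp(30, rr_bpm=14, var_frac=0.1, seed=9)
        assert np.array_equal(r1.record.samples, r2.record.samples)

    def test_resp_constant_period_without_jitter(self):
        sig = gen_clean_resp(60, rr_bpm=12, var_frac=0.0, seed=0)
        periods = np.diff(sig.event_times)
        assert np.allclose(periods, 5.0)

    def test_apnea_span_is_near_flat(self):
        sig = gen_clean_resp(40, rr_bpm=15, var_frac=0.0, apnea_spans=((15, 10),), seed=1)
        fs = sig.record.fs
        inside = sig.record.samples[int(16 * fs) : int(24 * fs)]
        outside = sig.record.samples[: int(14 * fs)]
        assert np.var(inside) < 0.01 * np.var(outside)

    @pytest.mark.parametrize(
        "call",
        [
            lambda: gen_clean_ecg(5),                       # shorter than a window
            lambda: gen_clean_ecg(20, hr_bpm=300),
            lambda: gen_clean_ecg(20, hrv_frac=0.5),
            lambda: gen_clean_resp(40, rr_bpm=3),
            lambda: gen_clean_resp(40, apnea_spans=((35, 10),)),
        ],
    )
    def test_parameter_validation(self, call):
        with pytest.raises(ValueError):
            call()

    def test_ectopic_beat_is_premature(self):
        pat = PathologySpec(ectopic_type="VPB", ectopic_beat_indices=(5,))
        sig = gen_clean_ecg(20, hr_bpm=60, hrv_frac=0.0, seed=0, pathology=pat)
        intervals = np.diff(sig.event_times)
        assert intervals[4] == pytest.approx(0.6, abs=0.01)
        assert sig.event_types[5] == "VPB"


class TestInjectNoise:
    def test_zero_spec_is_identity(self):
        sig = gen_clean_ecg(10, seed=0)
        noisy = inject_noise(sig, NoiseSpec())
        assert np.array_equal(noisy.record.samples, sig.record.samples)

    def test_wander_ratio_bookkeeping(self):
        sig = gen_clean_ecg(10, seed=0)
        noisy = inject_noise(sig, NoiseSpec(bw_rel_amp=0.5, seed=1))
        truth = window_truth(noisy, 0.0)
        assert truth.wander_ratio == pytest.approx(0.5, abs=0.02)

    def test_dropout_seconds_bookkeeping(self):
        sig = gen_clean_ecg(10, seed=0)
        noisy = inject_noise(sig, NoiseSpec(dropout_spans=((2.0, 3.0),)))
        truth = window_truth(noisy, 0.0)
        assert truth.dropout_s == pytest.approx(3.0)
        # dropout samples are the held value
        fs = sig.record.fs
        span = noisy.record.samples[int(2.1 * fs) : int(4.9 * fs)]
        assert np.ptp(span) == 0.0

    def test_impulse_count_bookkeeping(self):
        sig = gen_clean_ecg(10, seed=0)
        noisy = inject_noise(sig, NoiseSpec(impulse_times=(2.0, 7.5), seed=3))
        assert window_truth(noisy, 0.0).impulse_count == 2

    def test_invalid_spans_rejected(self):
        sig = gen_clean_ecg(10, seed=0)
        with pytest.raises(ValueError):
            inject_noise(sig, NoiseSpec(dropout_spans=((8.0, 5.0),)))
        with pytest.raises(ValueError):
            inject_noise(sig, NoiseSpec(bw_rel_amp=-0.1))


class TestLabeler:
    def test_ecg_good_mild_wander(self):
        truth = GroundTruth(kind=ECG, window_s=10, wander_ratio=0.25)
        assert label_window(truth) == GOOD

    def test_ecg_long_dropout_unacceptable(self):
        truth = GroundTruth(kind=ECG, window_s=10, dropout_s=3.0)
        assert label_window(truth) == UNACCEPTABLE

    def test_ecg_short_dropout_moderate_wander_acceptable(self):
        truth = GroundTruth(kind=ECG, window_s=10, dropout_s=1.5, wander_ratio=0.6)
        assert label_window(truth) == ACCEPTABLE

    def test_ecg_impulse_rules(self):
        t2 = GroundTruth(kind=ECG, window_s=10, impulse_count=2)
        t3 = GroundTruth(kind=ECG, window_s=10, impulse_count=3)
        assert label_window(t2) == ACCEPTABLE
        assert label_window(t3) == UNACCEPTABLE

    def test_resp_regular_fraction_rules(self):
        good = GroundTruth(kind=RESP, window_s=30, regular_fraction=0.80)
        acc = GroundTruth(kind=RESP, window_s=30, regular_fraction=0.40)
        bad = GroundTruth(kind=RESP, window_s=30, regular_fraction=0.10)
        assert label_window(good) == GOOD
        assert label_window(acc) == ACCEPTABLE
        assert label_window(bad) == UNACCEPTABLE

    def test_resp_half_window_loss_unacceptable(self):
        truth = GroundTruth(kind=RESP, window_s=30, regular_fraction=0.5, apnea_s=16.0)
        assert label_window(truth) == UNACCEPTABLE

    def test_pathology_never_degrades(self):
        pat = PathologySpec(ectopic_type="VPB", ectopic_beat_indices=(3,))
        truth = GroundTruth(kind=ECG, window_s=10, pathology=pat)
        assert label_window(truth) == GOOD

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            label_window(GroundTruth(kind=ECG, window_s=10), kind="EEG")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        wander=st.floats(0, 3), dropout=st.floats(0, 8), impulses=st.integers(0, 5),
        unreadable=st.integers(0, 4),
        d_wander=st.floats(0, 2), d_dropout=st.floats(0, 4),
    )
    def test_monotone_degradation(self, wander, dropout, impulses, unreadable,
                                  d_wander, d_dropout):
        """Increasing dropout or wander, all else fixed, never improves the grade."""
        base = GroundTruth(kind=ECG, window_s=10, wander_ratio=wander,
                           dropout_s=dropout, impulse_count=impulses,
                           unreadable_beats=unreadable)
        worse = GroundTruth(kind=ECG, window_s=10, wander_ratio=wander + d_wander,
                            dropout_s=dropout + d_dropout, impulse_count=impulses,
                            unreadable_beats=unreadable)
        assert label_window(worse) >= label_window(base)


class TestMakeDataset:
    def test_split_disjointness_and_label_presence(self):
        cfg = DatasetConfig(kind=ECG, n_train=20, n_validation=15, n_test=15, seed=5)
        ds = make_dataset(cfg)
        ids = [w.record.record_id for split in (ds.train, ds.validation, ds.test) for w in split]
        assert len(ids) == len(set(ids))
        assert all(w.grade is None for w in ds.train)
        assert all(w.grade in (0, 1, 2) for w in ds.validation + ds.test)

    def test_zero_noise_mix_gives_all_good(self):
        cfg = DatasetConfig(kind=ECG, n_train=2, n_validation=25, n_test=2,
                            validation_mix=(1.0, 0.0, 0.0), seed=2)
        ds = make_dataset(cfg)
        assert all(w.grade == GOOD for w in ds.validation)

    def test_validation_mixture_realized_within_tolerance(self):
        # labels only: no features needed, so n=3000 is cheap
        cfg = DatasetConfig(kind=ECG, n_train=2, n_validation=3000, n_test=2, seed=8)
        ds = make_dataset(cfg)
        grades = np.array([w.grade for w in ds.validation])
        for grade, target in zip((GOOD, ACCEPTABLE, UNACCEPTABLE), cfg.validation_mix):
            assert abs(np.mean(grades == grade) - target) < 0.03

    def test_infeasible_mixture_rejected(self):
        with pytest.raises(ValueError):
            DatasetConfig(kind=ECG, validation_mix=(0.5, 0.2, 0.2))
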