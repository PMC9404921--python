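import numpy as np
import pytest

from ecgssl.preprocess import (
    EcgPreprocessor,
    clip_saturation,
    highpass_baseline,
    resample_record,
    smote_balance,
    window_record,
    zscore_per_subject,
)
from ecgssl.records import EcgRecord, SegmentSet
from ecgssl.synthetic import ConditionSchedule, SubjectProfile, gen_ecg_record


def _sine_record(freq_hz, fs, duration_s=20.0, subject="s"):
    t = np.arange(int(duration_s * fs)) / fs
    sig = np.sin(2 * np.pi * freq_hz * t)
    return EcgRecord(subject, fs, sig, np.zeros(len(t), dtype=int))


class TestResample:
    def test_identity_when_rates_match(self):
        rec = _sine_record(5.0, 256.0)
        assert resample_record(rec, 256.0) is rec

    def test_wesad_style_ratio(self):
        rec = EcgRecord("s", 700.0, np.random.default_rng(0).normal(size=7000),
                        np.zeros(7000, dtype=int))
        out = resample_record(rec, 256.0)
        assert abs(out.n_samples - 2560) <= 1
        assert out.fs == 256.0
        assert out.labels.shape == out.signal.shape

    def test_spectral_peak_preserved(self):
        rec = _sine_record(5.0, 700.0)
        out = resample_record(rec, 256.0)
        spec = np.abs(np.fft.rfft(out.signal))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / 256.0)
        bin_w = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(spec)] - 5.0) <= bin_w

    def test_upsampling_warns_and_invalid_rejected(self):
        rec = _sine_record(5.0, 128.0)
        with pytest.warns(UserWarning):
            resample_record(rec, 256.0)
        with pytest.raises(ValueError):
            resample_record(rec, 0.0)


class TestHighpass:
    def test_dc_rejected(self):
        rec = EcgRecord("s", 256.0, np.full(5120, 3.7), np.zeros(5120, dtype=int))
        out = highpass_baseline(rec)
        assert np.max(np.abs(out.signal)) < 1e-6 * 3.7

    def test_passband_gain_near_unity(self):
        rec = _sine_record(5.0, 256.0)
        out = highpass_baseline(rec)
        core = slice(512, -512)  # avoid filter edge transients
        ratio = np.sqrt(np.mean(out.signal[core] ** 2) / np.mean(rec.signal[core] ** 2))
        assert abs(ratio - 1.0) < 0.05

    def test_drift_attenuated(self):
        rec = _sine_record(0.1, 256.0, duration_s=60.0)
        out = highpass_baseline(rec)
        ratio = np.sqrt(np.mean(out.signal**2) / np.mean(rec.signal**2))
        assert ratio < 0.10

    def test_zero_phase_keeps_peak_position(self, clean_record):
        out = highpass_baseline(clean_record)
        # R peaks are the dominant sharp features; the filtered argmax must not shift
        w = slice(0, 512)
        assert abs(int(np.argmax(out.signal[w])) - int(np.argmax(clean_record.signal[w]))) <= 2

    def test_passband_above_nyquist_rejected(self):
        rec = _sine_record(1.0, 128.0)
        with pytest.raises(ValueError):
            highpass_baseline(rec, passband_hz=70.0)


class TestZscore:
    def test_mean_zero_sd_one(self):
        rec = _sine_record(2.0, 128.0)
        rec.signal += 5.0
        (out,) = zscore_per_subject([rec])
        assert abs(np.mean(out.signal)) < 1e-8
        assert abs(np.std(out.signal) - 1.0) < 1e-8

    def test_idempotent(self):
        rec = _sine_record(2.0, 128.0)
        (once,) = zscore_per_subject([rec])
        (twice,) = zscore_per_subject([once])
        assert np.allclose(once.signal, twice.signal, atol=1e-8)

    def test_no_cross_subject_pooling(self):
        a = _sine_record(2.0, 128.0, subject="a")
        b = _sine_record(2.0, 128.0, subject="b")
        b.signal = b.signal + 100.0  # large offset would leak into pooled stats
        out_a, out_b = zscore_per_subject([a, b])
        assert abs(np.mean(out_a.signal)) < 1e-8
        assert abs(np.mean(out_b.signal)) < 1e-8
        pooled = np.concatenate([a.signal, b.signal])
        pooled_z = (a.signal - pooled.mean()) / pooled.std()
        assert not np.allclose(out_a.signal, pooled_z)

    def test_zero_variance_rejected(self):
        rec = EcgRecord("s", 128.0, np.ones(100), np.zeros(100, dtype=int))
        with pytest.raises(ValueError, match="variance"):
            zscore_per_subject([rec])


class TestClip:
    def test_identity_within_bounds(self):
        rec = _sine_record(2.0, 128.0)
        out = clip_saturation(rec, bound_sd=10.0)
        assert np.array_equal(out.signal, rec.signal)

    def test_clips_to_bound(self):
        sig = np.zeros(100)
        sig[3] = 50.0
        rec = EcgRecord("s", 128.0, sig, np.zeros(100, dtype=int))
        out = clip_saturation(rec, bound_sd=10.0)
        assert out.signal[3] == 10.0
        assert np.array_equal(out.signal[:3], sig[:3])

    def test_synthetic_saturation_clipped(self):
        p = SubjectProfile("s", saturation_level=0.5, amplitude_gain=1.2)
        rec = gen_ecg_record(p, ConditionSchedule([(0, 30.0)]), 256.0, seed=3)
        rec.signal *= 30.0  # plateaus at +/-15 now exceed the clip bound
        out = clip_saturation(rec, bound_sd=10.0)
        assert np.max(np.abs(out.signal)) == 10.0

    def test_invalid_bound_rejected(self):
        with pytest.raises(ValueError):
            clip_saturation(_sine_record(1.0, 128.0), bound_sd=0.0)


class TestWindowing:
    def test_whole_windows_uniform_condition(self):
        rec = EcgRecord("s", 256.0, np.arange(15360.0), np.zeros(15360, dtype=int))
        segs = window_record(rec, 10.0)
        assert len(segs) == 6
        assert segs.segment_length == 2560

    def test_remainder_discarded(self):
        n = int(12 * 128)
        rec = EcgRecord("s", 128.0, np.arange(float(n)), np.zeros(n, dtype=int))
        segs = window_record(rec, 5.0)
        assert len(segs) == 2

    def test_mixed_label_window_discarded(self):
        fs = 128.0
        n = int(15 * fs)
        labels = np.zeros(n, dtype=int)
        labels[int(7 * fs):] = 1  # label change mid-way through window 5-10 s
        rec = EcgRecord("s", fs, np.arange(float(n)), labels)
        segs = window_record(rec, 5.0)
        assert len(segs) == 2
        assert sorted(segs.labels.tolist()) == [0, 1]

    def test_short_record_warns_empty(self):
        rec = EcgRecord("s", 128.0, np.arange(100.0), np.zeros(100, dtype=int))
        with pytest.warns(UserWarning):
            segs = window_record(rec, 5.0)
        assert len(segs) == 0

    def test_sample_conservation(self, clean_record):
        segs = window_record(clean_record, 7.0)
        assert len(segs) * segs.segment_length <= clean_record.n_samples


def _random_segset(counts, L=64, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for cls, cnt in counts.items():
        rows.append(rng.normal(loc=cls, size=(cnt, L)))
        labels.extend([cls] * cnt)
    return SegmentSet(
        segments=np.concatenate(rows), labels=np.asarray(labels),
        subject_ids=np.array([f"s{i % 3}" for i in range(sum(counts.values()))]),
        fs=float(L), window_s=1.0,
    )


class TestSmote:
    def test_three_level_imbalance_242_88_48_balances_to_726(self):
        segs = _random_segset({0: 242, 1: 88, 2: 48})
        out = smote_balance(segs, seed=0)
        assert len(out) == 726
        counts = dict(zip(*np.unique(out.labels, return_counts=True)))
        assert counts == {0: 242, 1: 242, 2: 242}

    def test_balanced_input_unchanged(self):
        segs = _random_segset({0: 30, 1: 30})
        out = smote_balance(segs, seed=0)
        assert np.array_equal(out.segments, segs.segments)

    def test_originals_preserved_and_majority_untouched(self):
        segs = _random_segset({0: 40, 1: 12})
        out = smote_balance(segs, seed=1)
        assert np.array_equal(out.segments[: len(segs)], segs.segments)
        assert int(np.sum(out.labels == 0)) == 40

    def test_synthetic_rows_are_convex_combinations(self):
        segs = _random_segset({0: 40, 1: 12}, L=16, seed=2)
        out = smote_balance(segs, seed=2)
        minority = segs.segments[segs.labels == 1]
        for row in out.segments[len(segs):]:
            # a convex combination of two parents stays inside the pairwise envelope
            ok = False
            for i in range(len(minority)):
                # find a pair (i, j) bracketing the row componentwise
                lo = np.minimum(minority[i], minority)
                hi = np.maximum(minority[i], minority)
                ok = np.any(np.all((row >= lo - 1e-9) & (row <= hi + 1e-9), axis=1))
                if ok:
                    break
            assert ok

    def test_deterministic_given_seed(self):
        segs = _random_segset({0: 40, 1: 12})
        a = smote_balance(segs, seed=5)
        b = smote_balance(segs, seed=5)
        assert np.array_equal(a.segments, b.segments)

    def test_single_class_warns_unchanged(self):
        segs = _random_segset({0: 20})
        with pytest.warns(UserWarning):
            out = smote_balance(segs, seed=0)
        assert np.array_equal(out.segments, segs.segments)

    def test_singleton_class_rejected(self):
        segs = _random_segset({0: 20, 1: 1})
        with pytest.raises(ValueError):
            smote_balance(segs, seed=0)


class TestPipeline:
    def test_full_chain_produces_model_ready_segments(self, small_segments):
        assert len(small_segments) > 0
        assert small_segments.segment_length == 1280
        # z-scoring and clipping keep amplitudes moderate
        assert np.max(np.abs(small_segments.segments)) <= 10.0

    def test_chain_with_smote_balances(self):
        from ecgssl.synthetic import gen_dataset

        recs = gen_dataset(
            2, ConditionSchedule([(0, 60.0), (1, 30.0)]), 128.0, seed=4
        )
        segs = EcgPreprocessor(fs_out=128.0, window_s=5.0, smote=True, seed=4).transform(recs)
        _, counts = np.unique(segs.labels, return_counts=True)
        assert counts[0] == counts[1]


class TestOverlappingWindows:
    def test_half_stride_doubles_coverage(self):
        n = int(20 * 128)
        rec = EcgRecord("s", 128.0, np.arange(float(n)), np.zeros(n, dtype=int))
        plain = window_record(rec, 5.0)
        dense = window_record(rec, 5.0, stride_s=2.5)
        assert len(plain) == 4
        assert len(dense) == 7
        assert dense.segment_length == plain.segment_length
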