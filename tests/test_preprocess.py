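"""R-peak detection, windowing, standardization, balancing and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgpipe.io import ECGRecord
from ecgpipe.preprocess import (
    MissingClassError,
    RecordTooShortError,
    RPeakSet,
    Segment,
    SegmentDataset,
    ZeroVarianceError,
    balance_classes,
    detect_rpeaks,
    segment_beats,
    split_dataset,
    zscore_segment,
)
from ecgpipe.synth import NoiseSpec, add_noise, generate_record, white_sd_for_snr


def match_counts(truth, detected, tol):
    matched = set()
    tp = 0
    for d in detected:
        j = int(np.argmin(np.abs(truth - d)))
        if abs(int(truth[j]) - int(d)) <= tol and j not in matched:
            tp += 1
            matched.add(j)
    return tp


class TestDetectRPeaks:
    def test_all_zero_signal_yields_nothing(self):
        record = ECGRecord(samples=np.zeros(3600), fs=360.0)
        assert len(detect_rpeaks(record)) == 0

    def test_short_record_rejected(self):
        record = ECGRecord(samples=np.ones(100) + np.sin(np.arange(100.0)), fs=360.0)
        with pytest.raises(RecordTooShortError):
            detect_rpeaks(record)

    def test_single_clean_beat_located(self):
        record, r_idx, _ = generate_record(["N"] * 3, heart_rate=60, seed=0)
        peaks = detect_rpeaks(record)
        tol = int(round(0.05 * record.fs))
        assert match_counts(r_idx, peaks.indices, tol) == 3

    def test_noisy_minute_sensitivity_and_ppv(self):
        """>= 99 % sensitivity and precision at 20 dB SNR, ±50 ms tolerance."""
        rng = np.random.default_rng(0)
        labels = list(rng.choice(list("NAVLR"), 80))
        record, r_idx, _ = generate_record(labels, heart_rate=80, seed=42)
        sd = white_sd_for_snr(record.samples, 20.0)
        noisy = add_noise(record, NoiseSpec(white_sd=sd, baseline_amp=0.1,
                                            powerline_amp=0.02, seed=7))
        detected = detect_rpeaks(noisy)
        tol = int(round(0.05 * record.fs))
        tp = match_counts(r_idx, detected.indices, tol)
        assert tp / len(r_idx) >= 0.99
        assert tp / len(detected) >= 0.99


class TestSegmentBeats:
    def _record(self, n=1000):
        return ECGRecord(samples=np.arange(float(n)), fs=360.0)

    def test_window_arithmetic(self):
        record = self._record(1000)
        segs = segment_beats(record, RPeakSet(indices=np.array([500]), fs=360.0))
        assert len(segs) == 1
        seg = segs[0]
        assert len(seg) == 360 and seg.r_offset == 179
        assert seg.samples[0] == 321.0 and seg.samples[-1] == 680.0
        assert seg.samples[179] == 500.0

    def test_boundary_beats_dropped(self):
        record = self._record(1000)
        segs = segment_beats(record, RPeakSet(indices=np.array([100, 500, 900]),
                                              fs=360.0))
        assert len(segs) == 1  # 100 lacks left context, 900 lacks right

    def test_exact_fit_kept(self):
        record = self._record(360)
        segs = segment_beats(record, RPeakSet(indices=np.array([179]), fs=360.0))
        assert len(segs) == 1
        np.testing.assert_array_equal(segs[0].samples, record.samples)

    def test_labels_align(self):
        record = self._record(2000)
        segs = segment_beats(record, RPeakSet(indices=np.array([200, 1000]),
                                              fs=360.0), labels=["V", "L"])
        assert [s.label for s in segs] == ["V", "L"]
        with pytest.raises(ValueError):
            segment_beats(record, RPeakSet(indices=np.array([200]), fs=360.0),
                          labels=["V", "L"])


class TestZScore:
    def test_worked_example(self):
        seg = zscore_segment(Segment(samples=[1.0, 2.0, 3.0], r_offset=1))
        np.testing.assert_allclose(
            seg.samples, [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert seg.standardized

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        seg = zscore_segment(Segment(samples=rng.normal(2.0, 3.0, 360)))
        again = zscore_segment(seg)
        np.testing.assert_allclose(again.samples, seg.samples, atol=1e-12)

    def test_constant_segment_rejected(self):
        with pytest.raises(ZeroVarianceError):
            zscore_segment(Segment(samples=np.full(360, 5.0)))

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.01, 100.0), st.floats(-50.0, 50.0), st.integers(0, 1000))
    def test_scale_shift_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=120)
        z1 = zscore_segment(Segment(samples=x, r_offset=60)).samples
        z2 = zscore_segment(Segment(samples=a * x + b, r_offset=60)).samples
        np.testing.assert_allclose(z1, z2, atol=1e-9)


def tiny_dataset(counts, seed=0):
    rng = np.random.default_rng(seed)
    segments = []
    for label, n in counts.items():
        for _ in range(n):
            segments.append(Segment(samples=rng.normal(size=8), r_offset=4,
                                    label=label))
    return SegmentDataset(segments=segments)


class TestBalanceClasses:
    def test_mixed_over_and_under_sampling(self):
        ds = tiny_dataset({"N": 12, "A": 2})
        out = balance_classes(ds, 5, seed=1)
        assert out.class_counts == {"N": 5, "A": 2 + 3}
        # undersampled class: 5 distinct originals
        n_ids = {id(s.samples) for s in out.segments if s.label == "N"}
        assert len(n_ids) == 5
        # oversampled class: every member is one of the 2 originals
        a_orig = {id(s.samples) for s in ds.segments if s.label == "A"}
        for s in out.segments:
            if s.label == "A":
                assert id(s.samples) in a_orig

    def test_already_balanced_unchanged_up_to_order(self):
        ds = tiny_dataset({"N": 5, "V": 5})
        out = balance_classes(ds, 5, seed=0)
        assert sorted(id(s.samples) for s in out.segments) == \
               sorted(id(s.samples) for s in ds.segments)

    def test_never_invents_sample_values(self):
        ds = tiny_dataset({"N": 3, "V": 9, "L": 1})
        originals = {s.samples.tobytes() for s in ds.segments}
        out = balance_classes(ds, 4, seed=3)
        assert all(s.samples.tobytes() in originals for s in out.segments)

    def test_unlabeled_rejected(self):
        ds = SegmentDataset(segments=[Segment(samples=np.zeros(8) + np.arange(8),
                                              r_offset=0)])
        with pytest.raises(ValueError):
            balance_classes(ds, 5)

    def test_deterministic_under_seed(self):
        ds = tiny_dataset({"N": 30, "A": 3})
        a = balance_classes(ds, 10, seed=9)
        b = balance_classes(ds, 10, seed=9)
        assert [id(s.samples) for s in a.segments] == \
               [id(s.samples) for s in b.segments]


class TestSplitDataset:
    def test_stated_split_arithmetic(self):
        ds = tiny_dataset({"N": 200, "A": 200, "V": 200, "L": 200, "R": 200})
        train, val, test = split_dataset(ds, 0.7, 0.0, seed=0)
        assert (len(train), len(val), len(test)) == (700, 0, 300)

    def test_stratified_proportions(self):
        ds = tiny_dataset({c: 100 for c in "NAVLR"})
        train, val, test = split_dataset(ds, 0.7, 0.1, seed=1, stratified=True)
        for part, frac in ((train, 0.63), (val, 0.07), (test, 0.30)):
            for label, count in part.class_counts.items():
                assert abs(count - frac * 100) <= 1.0, (label, count, frac)

    def test_partition_is_disjoint_and_exhaustive(self):
        ds = tiny_dataset({"N": 40, "A": 40, "V": 40, "L": 40, "R": 40})
        train, val, test = split_dataset(ds, 0.7, 0.1, seed=2)
        ids = [id(s) for part in (train, val, test) for s in part.segments]
        assert len(ids) == len(ds) and len(set(ids)) == len(ds)
        assert set(ids) == {id(s) for s in ds.segments}

    def test_bad_fractions_rejected(self):
        ds = tiny_dataset({"N": 10, "A": 10})
        with pytest.raises(ValueError):
            split_dataset(ds, 1.5, 0.1)
        with pytest.raises(ValueError):
            split_dataset(ds, 0.7, 1.0)


class TestFullChain:
    def test_clean_normal_beats_peak_at_offset_179(self):
        """synthesize -> detect -> segment -> zscore keeps R at the window max."""
        record, _, _ = generate_record(["N"] * 20, heart_rate=70, seed=5)
        peaks = detect_rpeaks(record)
        segments = [zscore_segment(s) for s in segment_beats(record, peaks)]
        assert len(segments) >= 18
        for seg in segments:
            assert int(np.argmax(seg.samples)) == 179
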