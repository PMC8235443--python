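"""Temporal encoding, resampling, pairing, and display normalisation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.fft import rfft, rfftfreq

from mcpdnet.preprocessing import (
    EncodingSpec,
    build_paired_dataset,
    channel_spans,
    normalize_for_display,
    resample_accel,
    temporal_encode,
)
from mcpdnet.synthetic import RawAccelSequence, SilhouetteSequence


def binary_sequence(n, h=8, w=10, seed=0, fps=8.0):
    rng = np.random.default_rng(seed)
    frames = (rng.random((n, h, w)) < 0.4).astype(np.uint8)
    frames[:, 0, 0] = 1  # keep at least one foreground pixel
    return SilhouetteSequence(frames, fps, np.arange(n) / fps, "t")


def uniform_accel(n, rate=10.0, seed=0, t0=0.0):
    rng = np.random.default_rng(seed)
    return RawAccelSequence(rng.normal(size=(n, 3)), rate, t0 + np.arange(n) / rate, "t")


class TestTemporalEncode:
    def test_constant_sequence_reproduces_frame_in_every_channel(self):
        frames = np.zeros((20, 6, 6), dtype=np.uint8)
        frames[:, 2:4, 1:5] = 1
        seq = SilhouetteSequence(frames, 8.0, np.arange(20) / 8.0, "t")
        enc = temporal_encode(seq, EncodingSpec((2, 5, 10), 8.0), i=15)
        for d in range(3):
            assert np.array_equal(enc.stack[:, :, d], frames[0].astype(float))

    def test_earliest_valid_index_is_longest_interval(self):
        seq = binary_sequence(300)
        spec = EncodingSpec((5, 150, 250), 8.0)
        temporal_encode(seq, spec, i=250)  # earliest valid index works
        with pytest.raises(ValueError, match="250"):
            temporal_encode(seq, spec, i=249)

    def test_matches_brute_force_mean_exactly(self):
        seq = binary_sequence(300, seed=5)
        spec = EncodingSpec((5, 150, 250), 8.0)
        enc = temporal_encode(seq, spec, i=300)
        for d, t_d in enumerate(spec.intervals):
            brute = seq.frames[300 - t_d : 300].mean(axis=0)
            assert np.array_equal(enc.stack[:, :, d], brute)

    def test_elements_within_unit_interval(self):
        seq = binary_sequence(40, seed=2)
        enc = temporal_encode(seq, EncodingSpec((3, 7), 8.0), i=30)
        assert enc.stack.min() >= 0.0 and enc.stack.max() <= 1.0

    def test_channel_depends_only_on_its_window(self):
        """Perturbing any frame before i - t_d + 1 leaves channel d unchanged."""
        seq = binary_sequence(60, seed=3)
        spec = EncodingSpec((4, 12), 8.0)
        i = 50
        base = temporal_encode(seq, spec, i)
        frames2 = seq.frames.copy()
        frames2[: i - spec.intervals[-1]] ^= 1  # flip everything before the deepest window
        seq2 = SilhouetteSequence(frames2, seq.fps, seq.timestamps, "t")
        pert = temporal_encode(seq2, spec, i)
        assert np.array_equal(base.stack, pert.stack)


class TestChannelSpans:
    def test_reference_intervals_display(self):
        spec = EncodingSpec((5, 150, 250), 8.0)
        assert channel_spans(spec, display=True) == [0.6, 18.8, 31.3]
        assert channel_spans(spec) == [5 / 8, 150 / 8, 250 / 8]

    def test_single_interval(self):
        assert channel_spans(EncodingSpec((10,), 10.0), display=True) == [1.0]

    def test_half_up_rounding(self):
        assert channel_spans(EncodingSpec((7,), 8.0)) == [0.875]
        assert channel_spans(EncodingSpec((7,), 8.0), display=True) == [0.9]

    def test_invalid_fps(self):
        with pytest.raises(ValueError):
            channel_spans(EncodingSpec((5,), fps=-1.0))


class TestEncodingSpecValidation:
    @pytest.mark.parametrize("bad", [(), (0, 5), (5, 5), (10, 5)])
    def test_bad_intervals_rejected(self, bad):
        with pytest.raises(ValueError):
            EncodingSpec(bad, 8.0)


class TestResample:
    def test_25s_window_at_10hz_has_250_samples(self):
        out = resample_accel(uniform_accel(2500, rate=100.0), 10.0)
        assert len(out.samples) == 250
        assert out.rate == 10.0

    @pytest.mark.parametrize("n", [1000, 1001, 1033, 2499])
    def test_length_contract(self, n):
        out = resample_accel(uniform_accel(n, rate=100.0), 10.0)
        assert len(out.samples) == int(np.floor(n / 100.0 * 10.0))

    def test_dc_preserved(self):
        raw = RawAccelSequence(np.full((1000, 3), 0.7), 100.0, np.arange(1000) / 100.0, "t")
        out = resample_accel(raw, 10.0)
        # interior samples (edges carry filter transients)
        assert np.allclose(out.samples[5:-5], 0.7, atol=1e-6)

    def test_2hz_sine_survives_decimation(self):
        t = np.arange(3000) / 100.0
        sig = np.sin(2 * np.pi * 2.0 * t)
        raw = RawAccelSequence(np.stack([sig] * 3, axis=1), 100.0, t, "t")
        out = resample_accel(raw, 10.0)
        x = out.samples[:, 0]
        freqs = rfftfreq(len(x), 0.1)
        spec = np.abs(rfft(x))
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(2.0, abs=freqs[1] - freqs[0] + 1e-12)
        amp = 2 * spec.max() / len(x)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample_accel(uniform_accel(100, rate=10.0), 20.0)

    def test_timestamps_regenerated_on_target_grid(self):
        out = resample_accel(uniform_accel(1000, rate=100.0, t0=5.0), 10.0)
        assert np.allclose(out.timestamps, 5.0 + np.arange(100) / 10.0)


class TestPairing:
    def test_matches_exhaustive_nearest_predecessor_search(self):
        sil = binary_sequence(40, fps=8.0)
        acc = uniform_accel(50, rate=10.0)
        spec = EncodingSpec((2, 5, 10), 8.0)
        out = build_paired_dataset(sil, acc, spec, label=1, stride=1)
        t_max = spec.t_max
        expected = []
        for i in range(t_max, sil.n_frames + 1):
            ts = sil.timestamps[i - 1]
            cands = [j for j, t in enumerate(acc.timestamps) if t <= ts]
            if not cands:
                continue
            j = max(cands)  # nearest predecessor; tie -> that sample itself
            if j < t_max - 1 or ts - acc.timestamps[j] > 1.0 / sil.fps:
                continue
            expected.append((i, j))
        assert [(s.sil.frame_index, s.acc.end_timestamp) for s in out] == [
            (i, acc.timestamps[j]) for i, j in expected
        ]
        for s in out:
            assert s.sil.frame_index == s.acc.frame_index
            assert abs(s.sil.timestamp - s.acc.end_timestamp) <= 1.0 / sil.fps
            assert s.acc.window.shape == (t_max, 3)

    def test_exact_timestamp_tie_is_window_end(self):
        sil = binary_sequence(20, fps=10.0)  # frame times coincide with accel times
        acc = uniform_accel(30, rate=10.0)
        out = build_paired_dataset(sil, acc, EncodingSpec((2, 4), 10.0), label=0)
        for s in out:
            assert s.acc.end_timestamp == pytest.approx(s.sil.timestamp)

    def test_no_overlap_raises_with_both_ranges(self):
        sil = binary_sequence(30, fps=8.0)
        late = uniform_accel(40, rate=10.0, t0=100.0)
        with pytest.raises(ValueError, match="accelerometer spans"):
            build_paired_dataset(sil, late, EncodingSpec((2, 5), 8.0), label=1)

    def test_stride_subsamples_frames(self):
        sil = binary_sequence(40, fps=8.0)
        acc = uniform_accel(60, rate=10.0)
        spec = EncodingSpec((2, 5), 8.0)
        s1 = build_paired_dataset(sil, acc, spec, label=1, stride=1)
        s3 = build_paired_dataset(sil, acc, spec, label=1, stride=3)
        assert [s.sil.frame_index for s in s3] == [s.sil.frame_index for s in s1][::3]


class TestNormalizeForDisplay:
    def test_linear_map(self):
        assert np.allclose(normalize_for_display(np.array([2.0, 4.0, 6.0])), [0, 0.5, 1])

    def test_constant_maps_to_zeros(self):
        assert np.array_equal(normalize_for_display(np.full(5, 3.3)), np.zeros(5))

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_range_and_order_preserved(self, seed):
        s = np.random.default_rng(seed).normal(size=20)
        out = normalize_for_display(s)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)
        assert np.array_equal(np.argsort(out), np.argsort(s))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_for_display(np.array([]))
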