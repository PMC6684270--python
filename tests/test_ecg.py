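"""ECG chain: channel choice, filtering, beat detection, interval rules,
rate conversion and arousal percentiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from vocloco import synth
from vocloco.ecg import (BeatSeries, EcgRecording, ISI_MAX_S, ISI_MIN_S,
                         correct_intervals, coverage_ok, detect_beats,
                         isi_to_bpm, preprocess, rate_from_beats,
                         select_channel, to_percentiles, HeartRateSeries)


def test_isi_bounds_convert_to_stated_bpm():
    assert isi_to_bpm(ISI_MIN_S) == 600.0
    assert isi_to_bpm(ISI_MAX_S) == 150.0


class TestSelectChannel:
    def _rec(self, ch0, ch1, mask=()):
        return EcgRecording(fs=40_000, channels=np.vstack([ch0, ch1]),
                            artifact_mask=list(mask))

    def test_clean_beats_beat_noise(self):
        rng = np.random.default_rng(0)
        beats = np.arange(0.1, 9.9, 0.25)
        rec = synth.simulate_ecg(beats, 40_000, noise_sd=0.1,
                                 duration_s=10.0, rng=rng)
        # channel 1 carries the full-amplitude pulse train
        assert select_channel(rec) == 1

    def test_tie_goes_to_lowest_index(self):
        x = np.random.default_rng(1).normal(0, 1, 40_000)
        assert select_channel(self._rec(x, x.copy())) == 0

    def test_fully_masked_recording_rejected(self):
        x = np.zeros(40_000)
        with pytest.raises(ValueError):
            select_channel(self._rec(x, x, mask=[(0.0, 1.0)]))


class TestPreprocess:
    def _attenuation_db(self, freq):
        fs = 40_000
        t = np.arange(4 * fs) / fs
        x = np.sin(2 * np.pi * freq * t)
        rec = EcgRecording(fs=fs, channels=np.vstack([x, x]))
        y = preprocess(rec, 0)
        y = y[np.isfinite(y)][1000:-1000]
        return 20 * np.log10(np.std(x) / np.std(y))

    def test_5hz_attenuated_by_highpass(self):
        assert self._attenuation_db(5.0) > 20

    def test_60hz_attenuated_by_notch(self):
        assert self._attenuation_db(60.0) > 20

    def test_mask_propagates_as_nan(self):
        fs = 40_000
        x = np.random.default_rng(0).normal(0, 1, 10 * fs)
        rec = EcgRecording(fs=fs, channels=np.vstack([x, x]),
                           artifact_mask=[(3.0, 5.0)])
        y = preprocess(rec, 0)
        t = np.arange(len(y)) / 1500.0
        assert np.isnan(y[(t >= 3.05) & (t < 4.95)]).all()
        assert np.isfinite(y[(t > 0.5) & (t < 2.5)]).all()


class TestDetectBeats:
    def test_noiseless_pulse_train_recovered(self):
        fs = 1500
        x = np.zeros(10 * fs)
        truth = np.arange(0.125, 10, 0.25)
        x[(truth * fs).astype(int)] = 1.0
        got = detect_beats(x, fs)
        assert len(got) == len(truth)
        assert np.abs(got - truth).max() <= 1.0 / fs

    def test_flat_signal_yields_no_spikes(self):
        assert len(detect_beats(np.zeros(3000), 1500)) == 0

    def test_recall_precision_at_snr10(self):
        rng = np.random.default_rng(7)
        truth = np.cumsum(rng.uniform(0.15, 0.35, 300))
        dur = truth[-1] + 0.5
        rec = synth.simulate_ecg(truth, 40_000, noise_sd=0.1,
                                 duration_s=dur, rng=rng)
        beats = correct_intervals(detect_beats(preprocess(rec, 1))).beat_times
        d = np.abs(beats[:, None] - truth[None, :])
        recall = (d.min(axis=0) < 0.010).mean()
        precision = (d.min(axis=1) < 0.010).mean()
        assert recall >= 0.99 and precision >= 0.99


def brute_force_interval_rules(times):
    """Literal repeated application of the two ISI rules from scratch."""
    times = sorted(times)
    while True:
        for i in range(len(times) - 1):
            if times[i + 1] - times[i] < ISI_MIN_S:
                merged = (times[i] + times[i + 1]) / 2
                times = times[:i] + [merged] + times[i + 2:]
                break
        else:
            break
    invalid = [(a, b) for a, b in zip(times[:-1], times[1:]) if b - a > ISI_MAX_S]
    return np.asarray(times), invalid


class TestCorrectIntervals:
    def test_doublet_merged_at_midpoint(self):
        out = correct_intervals([1.00, 1.05, 1.30])
        assert np.allclose(out.beat_times, [1.025, 1.30])
        assert out.invalid_intervals == []

    def test_long_gap_marked_invalid_beats_kept(self):
        out = correct_intervals([1.0, 1.6])
        assert np.allclose(out.beat_times, [1.0, 1.6])
        assert out.invalid_intervals == [(1.0, 1.6)]

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 60)
        # trains with injected doublets and gaps
        isis = rng.choice([0.03, 0.08, 0.2, 0.3, 0.5, 0.8], size=n,
                          p=[0.1, 0.1, 0.3, 0.3, 0.1, 0.1])
        times = np.cumsum(isis)
        got = correct_intervals(times)
        exp_times, exp_invalid = brute_force_interval_rules(list(times))
        assert np.allclose(got.beat_times, exp_times)
        assert np.allclose(np.asarray(got.invalid_intervals).ravel(),
                           np.asarray(exp_invalid).ravel())

    def test_no_short_or_unmarked_long_interval_remains(self):
        rng = np.random.default_rng(3)
        times = np.cumsum(rng.uniform(0.03, 0.6, 200))
        out = correct_intervals(times)
        isi = np.diff(out.beat_times)
        invalid = set((round(a, 9), round(b, 9)) for a, b in out.invalid_intervals)
        for a, b in zip(out.beat_times[:-1], out.beat_times[1:]):
            assert b - a >= ISI_MIN_S
            if b - a > ISI_MAX_S:
                assert (round(a, 9), round(b, 9)) in invalid


class TestRateFromBeats:
    def test_periodic_train_gives_constant_rate(self):
        beats = correct_intervals(np.arange(0.2, 59.8, 0.25))
        hr = rate_from_beats(beats, 60)
        interior = hr.bpm[5:55]
        assert np.abs(interior - 240.0).max() < 0.5

    def test_empty_train_is_zero(self):
        hr = rate_from_beats(BeatSeries(np.array([]), []), 30)
        assert np.all(hr.bpm == 0.0)

    def test_matches_direct_kernel_sum(self):
        rng = np.random.default_rng(5)
        bt = np.sort(rng.uniform(0, 120, 500))
        hr = rate_from_beats(correct_intervals(bt), 120)
        from vocloco.ecg import KERNEL_SIGMA_S
        fs, sigma = 1500.0, KERNEL_SIGMA_S
        # oracle: direct Gaussian kernel sum over (sample-quantized) beats
        bq = np.floor(correct_intervals(bt).beat_times * fs) / fs
        checks = rng.integers(2, 118, 100)
        for k in checks:
            t = hr.t[k]
            tau = t - bq
            tau = tau[np.abs(tau) <= 0.5 + 1e-9]
            dens = np.sum(np.exp(-0.5 * (tau / sigma) ** 2))
            norm = np.sum(np.exp(-0.5 * ((np.arange(-750, 751) / fs) / sigma) ** 2)) / fs
            expected = dens / norm * 60.0
            if np.isfinite(hr.bpm[k]):
                assert hr.bpm[k] == pytest.approx(expected, rel=1e-6)

    def test_time_translation_equivariance(self):
        bt = np.arange(5.0, 55.0, 0.3)
        hr1 = rate_from_beats(correct_intervals(bt), 60)
        hr2 = rate_from_beats(correct_intervals(bt + 2.0), 60)
        assert np.allclose(hr1.bpm[10:50], hr2.bpm[12:52], atol=1e-6)


class TestCoverageAndPercentiles:
    def _hr(self, bpm):
        bpm = np.asarray(bpm, float)
        return HeartRateSeries(t=np.arange(len(bpm)) + 0.5, bpm=bpm)

    def test_coverage_boundary_inclusive(self):
        bpm = np.full(600, np.nan)
        bpm[:299] = 300.0
        assert not coverage_ok(self._hr(bpm))
        bpm[:300] = 300.0
        assert coverage_ok(self._hr(bpm))
        assert not coverage_ok(self._hr(np.full(600, np.nan)))

    def test_increasing_series_percentiles_match_rank_oracle(self):
        bpm = np.linspace(200, 400, 600)
        pct = to_percentiles(self._hr(bpm)).percentile
        ranks = rankdata(bpm)
        oracle = (ranks - 1) / (len(bpm) - 1) * 100
        assert np.allclose(pct, oracle)
        assert pct[0] == 0.0 and pct[-1] == 100.0

    def test_constant_series_maps_to_50(self):
        pct = to_percentiles(self._hr(np.full(100, 321.0))).percentile
        assert np.allclose(pct, 50.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        bpm = rng.uniform(150, 600, 400)
        p1 = to_percentiles(self._hr(bpm)).percentile
        p2 = to_percentiles(self._hr(np.exp(bpm / 100))).percentile
        assert np.allclose(p1, p2)

    def test_low_coverage_session_rejected(self):
        bpm = np.full(600, np.nan)
        bpm[:100] = 300.0
        with pytest.raises(ValueError):
            to_percentiles(self._hr(bpm))
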