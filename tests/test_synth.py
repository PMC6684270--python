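"""Synthetic-study generator: design layout, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from vocloco import synth
from vocloco.ecg import correct_intervals, detect_beats, preprocess


class TestStudyLayout:
    def test_default_design_reproduces_session_counts(self, small_study):
        bundles, _ = synth.simulate_study(synth.StudyConfig(rng_seed=0),
                                          with_motion=False, with_beats=False)
        assert len(bundles) == sum(synth.SESSIONS_PER_SUBJECT) == 220
        per_subject = pd.Series([b.subject for b in bundles]).value_counts()
        assert tuple(per_subject[f"S{i+1}"] for i in range(7)) == \
            synth.SESSIONS_PER_SUBJECT
        assert sum(b.has_audio for b in bundles) == \
            sum(synth.AUDIO_SESSIONS_PER_SUBJECT) == 192

    def test_modality_layout(self):
        bundles, _ = synth.simulate_study(synth.StudyConfig(rng_seed=3),
                                          with_motion=False)
        assert sum(b.has_ecg for b in bundles) == 149
        assert sum(b.has_video for b in bundles) == 215

    def test_invalid_config_names_field(self):
        cfg = synth.StudyConfig(artifact_fraction=1.5)
        with pytest.raises(ValueError, match="artifact_fraction"):
            cfg.validate()
        cfg = synth.StudyConfig(vocal_midpoint_day=99)
        with pytest.raises(ValueError, match="vocal_midpoint_day"):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_identical_event_tables(self, small_config):
        b1, _ = synth.simulate_study(small_config)
        b2, _ = synth.simulate_study(small_config)
        for x, y in zip(b1, b2):
            assert x.session_id == y.session_id
            if x.calls is not None:
                pd.testing.assert_frame_equal(x.calls, y.calls)
            if x.beat_times is not None:
                assert np.array_equal(x.beat_times, y.beat_times)
            if x.motion_raw is not None:
                assert np.array_equal(x.motion_raw, y.motion_raw)


class TestCallSchedule:
    def test_step_function_limit(self):
        cfg = synth.StudyConfig(maturation_slope=1e6, rng_seed=5,
                                session_duration_s=600.0)
        rng = np.random.default_rng(0)
        early = synth.simulate_session_calls(5, cfg, rng)
        late = synth.simulate_session_calls(20, cfg, rng)
        assert (early["call_type"] == "cry").all()
        assert (late["call_type"] == "phee").all()

    def test_time_share_crosses_half_near_midpoint(self):
        """Across sessions spanning the midpoint, the phee share of vocal
        time crosses 0.5 within +/-2 days of the configured midpoint."""
        cfg = synth.StudyConfig(rng_seed=11, session_duration_s=600.0)
        rng = np.random.default_rng(7)
        days = np.arange(1, 31)
        shares = []
        for d in days:
            reps = [synth.simulate_session_calls(d, cfg, rng) for _ in range(3)]
            calls = pd.concat(reps)
            dur = calls["offset_s"] - calls["onset_s"]
            shares.append(dur[calls["call_type"] == "phee"].sum() / dur.sum())
        shares = np.asarray(shares)
        crossing = days[np.argmin(np.abs(shares - 0.5))]
        assert abs(crossing - cfg.vocal_midpoint_day) <= 2

    def test_phee_share_monotone_in_expectation(self):
        share = synth.logistic_share(np.arange(1, 62), 10.0, 0.35)
        assert np.all(np.diff(share) > 0)


class TestHeartRateTruth:
    def test_simulated_rate_within_validation_bounds(self, small_study):
        _, gt = small_study
        for bt in gt.beat_times.values():
            isi = np.diff(bt)
            bpm = 60.0 / isi
            assert bpm.min() > 150 and bpm.max() < 600


class TestSimulateEcg:
    def test_noiseless_pulse_count_and_position(self):
        beats = np.arange(0.25, 4.8, 0.25)
        rec = synth.simulate_ecg(beats, 40_000, noise_sd=0.0, duration_s=5.0)
        x = rec.channels[1]
        # one stereotyped pulse per beat: count threshold crossings
        above = x > 0.5
        n_pulses = np.sum(np.diff(above.astype(int)) == 1)
        assert n_pulses == len(beats)
        peak_t = np.argmax(x[: 40_000 // 2]) / 40_000
        assert abs(peak_t - 0.25) < 0.010

    def test_empty_beat_list_is_noise_only(self):
        rec = synth.simulate_ecg([], 40_000, noise_sd=0.1, duration_s=1.0,
                                 rng=np.random.default_rng(0))
        assert np.abs(rec.channels[1]).max() < 0.6

    def test_pulse_exceeds_noise_99th_percentile(self):
        rng = np.random.default_rng(2)
        rec = synth.simulate_ecg([0.5], 40_000, noise_sd=0.1, duration_s=1.0,
                                 rng=rng)
        noise = rec.channels[1][: 10_000]
        assert rec.channels[1].max() > np.percentile(np.abs(noise), 99)

    def test_beats_outside_session_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_ecg([2.0], 40_000, 0.1, duration_s=1.0)

    def test_detector_full_recall_on_noiseless_output(self):
        rng = np.random.default_rng(4)
        truth = np.cumsum(rng.uniform(0.15, 0.35, 60))
        rec = synth.simulate_ecg(truth, 40_000, noise_sd=0.0,
                                 duration_s=truth[-1] + 0.5)
        beats = correct_intervals(detect_beats(preprocess(rec, 1))).beat_times
        d = np.abs(beats[:, None] - truth[None, :])
        assert (d.min(axis=0) < 0.010).all()


class TestSimulateMotion:
    def _calls(self, rng, n, dur, call_type="cry"):
        on = np.sort(rng.uniform(5, dur - 10, n))
        return pd.DataFrame({"onset_s": on, "offset_s": on + 2.0,
                             "call_type": call_type})

    def test_zero_coupling_independent_of_calls(self):
        cfg = synth.StudyConfig(coupling_locomotor_cry=0.0,
                                coupling_locomotor_phee_early=0.0,
                                session_duration_s=600.0)
        rng = np.random.default_rng(0)
        calls = self._calls(rng, 40, 600)
        raw = synth.simulate_motion(calls, cfg, rng)
        t = np.arange(600) + 0.5
        inside = np.zeros(600, bool)
        for _, r in calls.iterrows():
            inside |= (t >= r["onset_s"]) & (t < r["offset_s"])
        assert abs(raw[inside].mean() - raw.mean()) < 0.1

    def test_cry_coupling_raises_activity_during_cries(self):
        cfg = synth.StudyConfig(session_duration_s=1200.0)
        rng = np.random.default_rng(1)
        calls = self._calls(rng, 120, 1200)
        raw = synth.simulate_motion(calls, cfg, rng)
        t = np.arange(1200) + 0.5
        inside = np.zeros(1200, bool)
        for _, r in calls.iterrows():
            inside |= (t >= r["onset_s"]) & (t < r["offset_s"])
        assert raw[inside].mean() > raw.mean()

    def test_zero_baseline_no_events_all_zero(self):
        cfg = synth.StudyConfig(motion_baseline=0.0, motion_noise_sd=0.0,
                                session_duration_s=60.0)
        raw = synth.simulate_motion(pd.DataFrame(columns=["onset_s", "offset_s",
                                                          "call_type"]),
                                    cfg, np.random.default_rng(0))
        assert np.all(raw == 0.0)

    def test_nonnegative_even_with_suppressive_coupling(self):
        cfg = synth.StudyConfig(coupling_locomotor_phee_early=-5.0,
                                session_duration_s=300.0)
        rng = np.random.default_rng(2)
        calls = self._calls(rng, 30, 300, call_type="phee")
        raw = synth.simulate_motion(calls, cfg, rng)
        assert raw.min() >= 0.0
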