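"""Synthetic developmental studies with known ground truth.

Emulates a longitudinal infant-marmoset study: 7 subjects observed in
10-minute isolation sessions across postnatal days (PND) 1-61, with scored
contact calls (immature cries -> mature phees), postural/locomotor behavior
logs, per-second video-motion values, and ECG-derived heart beats.  Behavior
maturation follows logistic schedules with configurable midpoints; calls
couple to locomotor activity and heart rate with configurable effect sizes,
so every downstream stage has a recoverable truth.

The default configuration reproduces the study design being emulated:
per-subject session counts (29, 29, 34, 34, 31, 31, 32; 220 total) and the
per-modality session layout (192 audio, 215 video, 149 ECG sessions).

Maturation semantics: the logistic schedule governs the expected *time
share* of the mature behavior within its domain, so the domain's maturity
index (mature time / (mature + immature time)) crosses 0.5 at the configured
midpoint even when mature and immature bouts differ in typical duration
(phees are much longer than cries).  The implied per-call *count*
probability is exposed as :func:`mature_count_probability`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import EcgRecording
from .study import (SessionBundle, POSTURAL_BEHAVIORS, LOCOMOTOR_BEHAVIORS,
                    IMMATURE, MATURE)

__all__ = [
    "StudyConfig", "GroundTruth", "simulate_study", "simulate_ecg",
    "simulate_motion", "simulate_session_calls", "render_audio",
    "mature_count_probability", "logistic_share", "write_study",
    "SESSIONS_PER_SUBJECT", "AUDIO_SESSIONS_PER_SUBJECT",
    "ECG_SESSIONS_PER_SUBJECT", "VIDEO_SESSIONS_PER_SUBJECT",
    "CALLS_PER_SUBJECT", "BEHAVIOR_INSTANCES_PER_SUBJECT",
]

# Study-design tallies of the emulated longitudinal study (per subject 1-7).
SESSIONS_PER_SUBJECT = (29, 29, 34, 34, 31, 31, 32)               # 220
AUDIO_SESSIONS_PER_SUBJECT = (28, 29, 21, 20, 31, 31, 32)         # 192
ECG_SESSIONS_PER_SUBJECT = (16, 14, 21, 19, 26, 25, 28)           # 149
VIDEO_SESSIONS_PER_SUBJECT = (28, 28, 33, 33, 30, 31, 32)         # 215
CALLS_PER_SUBJECT = (1100, 801, 1604, 1021, 1657, 2199, 2574)     # 10,956
BEHAVIOR_INSTANCES_PER_SUBJECT = (662, 635, 414, 574, 207, 427, 276)  # 3,195


@dataclass
class StudyConfig:
    """Ground-truth parameters of a simulated study.

    Durations are seconds, rates are per minute, heart-rate quantities are
    beats/min, coupling terms are additive shifts on the raw per-second
    motion value (mean |luminance difference| per pixel).
    """

    n_subjects: int = 7
    sessions_per_subject: tuple = SESSIONS_PER_SUBJECT
    pnd_range: tuple = (1, 61)
    session_duration_s: float = 600.0
    # logistic maturation schedules (midpoints in days, slope in 1/days)
    vocal_midpoint_day: float = 10.0
    postural_midpoint_day: float = 19.0
    locomotor_midpoint_day: float = 21.0
    maturation_slope: float = 0.35
    # vocal production
    call_rate: float = 5.7                      # calls/min
    cry_params: dict = field(default_factory=lambda: {
        "duration_mean_s": 1.2, "duration_sd_s": 0.4, "entropy_level": -0.8})
    phee_params: dict = field(default_factory=lambda: {
        "duration_mean_s": 3.0, "duration_sd_s": 1.0, "entropy_level": -3.0})
    # vocal-locomotor coupling: shift of raw motion during calls of each type
    coupling_locomotor_cry: float = 0.8
    coupling_locomotor_phee_early: float = -0.6
    # arousal elevations (beats/min) around mature calls and locomotion
    arousal_effect_phee: float = 30.0
    arousal_effect_locomotion: float = 20.0
    # heart rate
    hr_base_bpm: float = 280.0
    hr_pnd_slope_bpm: float = 1.0               # baseline drift per day
    hr_fluctuation_sd_bpm: float = 20.0
    ecg_fs_hz: float = 40_000.0
    ecg_noise_sd: float = 0.1                   # pulse peak amplitude is 1.0
    artifact_fraction: float = 0.05
    # motion baseline (raw luminance-difference units)
    motion_baseline: float = 1.0
    motion_noise_sd: float = 0.25
    motion_locomotion_gain: float = 1.5         # raw shift during locomotor bouts
    # behavior scoring
    behavior_rate: float = 1.5                  # scored bouts/min (both categories)
    behavior_duration_mean_s: float = 5.0
    rng_seed: int = 0

    def validate(self):
        if self.n_subjects <= 0:
            raise ValueError("invalid config field n_subjects: must be > 0")
        if len(self.sessions_per_subject) != self.n_subjects:
            raise ValueError("invalid config field sessions_per_subject: "
                             f"need {self.n_subjects} entries")
        if any(s <= 0 for s in self.sessions_per_subject):
            raise ValueError("invalid config field sessions_per_subject: counts must be > 0")
        if self.session_duration_s <= 0:
            raise ValueError("invalid config field session_duration_s: must be > 0")
        lo, hi = self.pnd_range
        for name in ("vocal_midpoint_day", "postural_midpoint_day", "locomotor_midpoint_day"):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"invalid config field {name}: {v} outside pnd_range {self.pnd_range}")
        if not (0.0 <= self.artifact_fraction < 1.0):
            raise ValueError("invalid config field artifact_fraction: must be in [0, 1)")
        if self.call_rate < 0 or self.behavior_rate < 0:
            raise ValueError("invalid config field call_rate/behavior_rate: must be >= 0")
        return self


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    transition_days: dict                  # domain -> configured midpoint (days)
    beat_times: dict                       # session_id -> true beat times (s)
    coupling: dict                         # effect sizes as configured
    call_types: dict                       # session_id -> list of true types
    config: StudyConfig = None


def logistic_share(pnd, midpoint, slope):
    """Expected mature time share at a given postnatal day."""
    return 1.0 / (1.0 + np.exp(-slope * (np.asarray(pnd, float) - midpoint)))


def mature_count_probability(share, dur_mature, dur_immature):
    """Per-bout probability of the mature form that yields a given time share.

    With mean bout durations ``dur_mature``/``dur_immature``, a count
    probability q gives expected time share q*dm / (q*dm + (1-q)*di);
    inverting for q.
    """
    share = np.asarray(share, float)
    return share * dur_immature / (share * dur_immature + (1.0 - share) * dur_mature)


def _trunc_normal(rng, mean, sd, lo, n):
    x = rng.normal(mean, sd, size=n)
    return np.maximum(x, lo)


def simulate_session_calls(pnd, config: StudyConfig, rng) -> pd.DataFrame:
    """Renewal-process call bouts with logistic maturation of the time share.

    Inter-call gaps are exponential at ``call_rate``; each call's type is
    drawn with the count probability implied by the logistic time-share
    schedule; durations are truncated-normal per type.
    """
    share = float(logistic_share(pnd, config.vocal_midpoint_day, config.maturation_slope))
    dm = config.phee_params["duration_mean_s"]
    di = config.cry_params["duration_mean_s"]
    q = float(mature_count_probability(share, dm, di)) if 0 < share < 1 else share
    rows = []
    t = 0.0
    mean_gap = 60.0 / config.call_rate if config.call_rate > 0 else np.inf
    while np.isfinite(mean_gap):
        t += rng.exponential(mean_gap)
        if t >= config.session_duration_s:
            break
        is_phee = rng.random() < q
        params = config.phee_params if is_phee else config.cry_params
        dur = float(_trunc_normal(rng, params["duration_mean_s"],
                                  params["duration_sd_s"], 0.1, 1)[0])
        off = min(t + dur, config.session_duration_s)
        if off - t >= 0.1:
            rows.append((t, off, "phee" if is_phee else "cry"))
        t = off
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "call_type"])


def _simulate_behaviors(pnd, config: StudyConfig, rng) -> pd.DataFrame:
    """Scored postural/locomotor bouts with logistic maturation.

    Within each category, 70% of bouts come from the immature/mature pair
    (split by the logistic schedule) and 30% from the flat control
    behaviors, so the trend-classification stage has recoverable signs.
    """
    rows = []
    specs = [
        ("postural", POSTURAL_BEHAVIORS, config.postural_midpoint_day),
        ("locomotor", LOCOMOTOR_BEHAVIORS, config.locomotor_midpoint_day),
    ]
    for category, labels, midpoint in specs:
        share = float(logistic_share(pnd, midpoint, config.maturation_slope))
        n = rng.poisson(config.behavior_rate * config.session_duration_s / 60.0 / 2.0)
        controls = [b for b in labels
                    if b not in (IMMATURE[category], MATURE[category])]
        t = rng.uniform(0, 30)
        for _ in range(n):
            if rng.random() < 0.7:
                label = MATURE[category] if rng.random() < share else IMMATURE[category]
            else:
                label = controls[rng.integers(len(controls))]
            dur = float(_trunc_normal(rng, config.behavior_duration_mean_s,
                                      config.behavior_duration_mean_s / 3, 0.5, 1)[0])
            off = min(t + dur, config.session_duration_s)
            if off - t >= 0.2 and t < config.session_duration_s:
                rows.append((t, off, category, label))
            t = off + rng.exponential(60.0 / config.behavior_rate)
            if t >= config.session_duration_s:
                break
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "category", "behavior"])


def _interval_shift(t, events: pd.DataFrame, amount_by_row) -> np.ndarray:
    """Additive shift of a 1 Hz series inside event intervals."""
    shift = np.zeros_like(t)
    for k, (_, row) in enumerate(events.iterrows()):
        inside = (t >= row["onset_s"]) & (t < row["offset_s"])
        shift[inside] += amount_by_row[k]
    return shift


def simulate_motion(call_events: pd.DataFrame, config: StudyConfig, rng,
                    locomotor_events: pd.DataFrame | None = None,
                    duration_s: float | None = None) -> np.ndarray:
    """Raw per-second luminance-difference series with call-type coupling.

    Baseline positive noise, plus ``motion_locomotion_gain`` during
    locomotor bouts, plus the configured per-type shift during calls
    (positive for cries, typically negative for phees).  Nonnegative.
    """
    dur = config.session_duration_s if duration_s is None else duration_s
    t = np.arange(int(round(dur)), dtype=float) + 0.5
    # AR(1) positive baseline
    eps = rng.normal(0, config.motion_noise_sd, size=len(t))
    noise = np.empty_like(eps)
    acc = 0.0
    for i, e in enumerate(eps):
        acc = 0.7 * acc + e
        noise[i] = acc
    raw = config.motion_baseline + noise
    if locomotor_events is not None and len(locomotor_events):
        raw += _interval_shift(t, locomotor_events,
                               [config.motion_locomotion_gain] * len(locomotor_events))
    if call_events is not None and len(call_events):
        amounts = [config.coupling_locomotor_cry if ct == "cry"
                   else config.coupling_locomotor_phee_early
                   for ct in call_events["call_type"]]
        raw += _interval_shift(t, call_events, amounts)
    return np.maximum(raw, 0.0)


def _simulate_beats(pnd, calls, locomotor_events, config: StudyConfig, rng):
    """True beat times from an integrated instantaneous-rate profile.

    Rate = baseline(PND) + OU fluctuation + configured elevations during
    phees and locomotor bouts, clipped to [155, 590] beats/min so interval
    validation never deletes valid beats.
    """
    dur = config.session_duration_s
    tg = np.arange(int(round(dur)), dtype=float) + 0.5
    # OU fluctuation, tau ~ 20 s
    ou = np.empty(len(tg))
    acc = 0.0
    a = np.exp(-1.0 / 20.0)
    innov_sd = config.hr_fluctuation_sd_bpm * np.sqrt(1 - a * a)
    for i in range(len(tg)):
        acc = a * acc + rng.normal(0, innov_sd)
        ou[i] = acc
    rate = config.hr_base_bpm + config.hr_pnd_slope_bpm * pnd + ou
    if calls is not None and len(calls):
        phees = calls[calls["call_type"] == "phee"]
        if len(phees):
            rate += _interval_shift(tg, phees, [config.arousal_effect_phee] * len(phees))
    if locomotor_events is not None and len(locomotor_events):
        rate += _interval_shift(tg, locomotor_events,
                                [config.arousal_effect_locomotion] * len(locomotor_events))
    rate = np.clip(rate, 155.0, 590.0)

    beats = []
    t = float(rng.uniform(0, 0.25))
    while t < dur:
        beats.append(t)
        r = rate[min(int(t), len(rate) - 1)]
        t += 60.0 / r
    return np.asarray(beats), rate


def _artifact_intervals(duration_s, fraction, rng):
    if fraction <= 0:
        return []
    n_int = int(rng.integers(1, 4))
    lengths = rng.dirichlet(np.ones(n_int)) * fraction * duration_s
    starts = np.sort(rng.uniform(0, duration_s - lengths.max(), size=n_int))
    out = []
    for s, L in zip(starts, lengths):
        out.append((float(s), float(min(s + L, duration_s))))
    return out


def simulate_ecg(beat_times, fs, noise_sd, artifact_mask=None,
                 duration_s=None, rng=None) -> EcgRecording:
    """Two-channel ECG waveform: biphasic ~20 ms pulses plus Gaussian noise.

    Channel 1 carries the full-amplitude pulse train (peak 1.0); channel 0
    is an attenuated, noisier electrode so channel selection has work to do.
    Masked regions are zeroed and recorded in the artifact mask.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    beat_times = np.asarray(beat_times, dtype=float)
    if duration_s is None:
        duration_s = float(beat_times.max()) + 0.5 if beat_times.size else 1.0
    if beat_times.size and (beat_times.min() < 0 or beat_times.max() >= duration_s):
        raise ValueError("beat times outside the session")
    n = int(round(duration_s * fs))

    width = 0.020
    tt = np.arange(int(width * fs)) / fs
    template = np.sin(2 * np.pi * tt / width) * np.hanning(len(tt))
    template /= np.abs(template).max()

    clean = np.zeros(n)
    for bt in beat_times:
        i0 = int(round((bt - width / 2) * fs))
        sl0, sl1 = max(i0, 0), min(i0 + len(template), n)
        if sl1 > sl0:
            clean[sl0:sl1] += template[sl0 - i0: sl1 - i0]

    ch1 = clean + rng.normal(0, noise_sd, n)
    ch0 = 0.3 * clean + rng.normal(0, 2.0 * max(noise_sd, 1e-6), n)
    channels = np.vstack([ch0, ch1])
    mask = list(artifact_mask) if artifact_mask else []
    for a, b in mask:
        channels[:, int(a * fs): int(b * fs)] = 0.0
    return EcgRecording(fs=fs, channels=channels, artifact_mask=mask)


def render_audio(calls: pd.DataFrame, duration_s, fs=24_000, rng=None):
    """Session audio: band-noise bursts for cries, tonal phees, else silence."""
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(duration_s * fs))
    wav = rng.normal(0, 1e-4, n)   # faint floor so segmentation sees silence
    for _, row in calls.iterrows():
        i0, i1 = int(row["onset_s"] * fs), int(row["offset_s"] * fs)
        i1 = min(i1, n)
        if i1 <= i0:
            continue
        seg_t = np.arange(i1 - i0) / fs
        env = np.hanning(i1 - i0) * 0.5 + 0.5
        if row["call_type"] == "phee":
            f0 = 7000.0 + rng.normal(0, 200)
            sig = 0.5 * np.sin(2 * np.pi * f0 * seg_t)
        else:
            sig = 0.5 * rng.normal(0, 1, i1 - i0)
        wav[i0:i1] += sig * env
    return wav, fs


def _spread_indices(n, k):
    """k session indices spread evenly through n (deterministic layout)."""
    if k >= n:
        return set(range(n))
    return set(np.round(np.linspace(0, n - 1, k)).astype(int).tolist())


def simulate_study(config: StudyConfig | None = None,
                   with_motion=True, with_beats=True, with_audio=False):
    """Generate one complete study: (list of SessionBundle, GroundTruth).

    Deterministic under ``config.rng_seed``.  ECG is represented by true and
    artifact-censored beat times per session; full waveforms are rendered on
    demand by :func:`simulate_ecg` (a 220-session 40 kHz corpus would be
    tens of gigabytes).
    """
    config = StudyConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    lo, hi = config.pnd_range

    bundles = []
    gt = GroundTruth(
        transition_days={"vocal": config.vocal_midpoint_day,
                         "postural": config.postural_midpoint_day,
                         "locomotor": config.locomotor_midpoint_day},
        beat_times={}, call_types={},
        coupling={"locomotor_cry": config.coupling_locomotor_cry,
                  "locomotor_phee_early": config.coupling_locomotor_phee_early,
                  "arousal_phee": config.arousal_effect_phee,
                  "arousal_locomotion": config.arousal_effect_locomotion},
        config=copy.deepcopy(config),
    )

    for s in range(config.n_subjects):
        subject = f"S{s + 1}"
        n_sess = config.sessions_per_subject[s]
        days = np.sort(rng.choice(np.arange(lo, hi + 1), size=min(n_sess, hi - lo + 1),
                                  replace=False))
        audio_idx = _spread_indices(n_sess, AUDIO_SESSIONS_PER_SUBJECT[s]
                                    if s < 7 else n_sess)
        ecg_idx = _spread_indices(n_sess, ECG_SESSIONS_PER_SUBJECT[s]
                                  if s < 7 else n_sess)
        video_idx = _spread_indices(n_sess, VIDEO_SESSIONS_PER_SUBJECT[s]
                                    if s < 7 else n_sess)
        for k in range(n_sess):
            pnd = int(days[k % len(days)])
            sid = f"{subject}_d{pnd:02d}_{k:03d}"
            calls = simulate_session_calls(pnd, config, rng)
            behaviors = _simulate_behaviors(pnd, config, rng)
            loco = behaviors[behaviors["category"] == "locomotor"]

            bundle = SessionBundle(subject=subject, pnd=pnd, session_id=sid,
                                   duration_s=config.session_duration_s)
            if k in audio_idx:
                bundle.calls = calls
                gt.call_types[sid] = list(calls["call_type"])
                if with_audio:
                    bundle.audio = render_audio(calls, config.session_duration_s,
                                                rng=rng)
            if k in video_idx:
                bundle.behaviors = behaviors
                if with_motion:
                    bundle.motion_raw = simulate_motion(
                        calls, config, rng, locomotor_events=loco)
            if k in ecg_idx and with_beats:
                true_beats, _ = _simulate_beats(pnd, calls, loco, config, rng)
                gt.beat_times[sid] = true_beats
                mask = _artifact_intervals(config.session_duration_s,
                                           config.artifact_fraction, rng)
                keep = np.ones(len(true_beats), dtype=bool)
                for a, b in mask:
                    keep &= ~((true_beats >= a) & (true_beats < b))
                bundle.beat_times = true_beats[keep]
                bundle.qc["artifact_mask"] = mask
            bundles.append(bundle)
    return bundles, gt


def write_study(bundles, ground_truth, directory):
    """Write a study directory: manifest.csv, per-session CSV/NPZ, ground_truth.json."""
    import json
    from pathlib import Path
    from scipy.io import wavfile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for b in bundles:
        sdir = directory / b.session_id
        sdir.mkdir(exist_ok=True)
        paths = {"calls": "", "behaviors": "", "motion": "", "ecg": "", "audio": ""}
        if b.calls is not None:
            b.calls.to_csv(sdir / "calls.csv", index=False)
            paths["calls"] = f"{b.session_id}/calls.csv"
        if b.behaviors is not None:
            b.behaviors.to_csv(sdir / "behaviors.csv", index=False)
            paths["behaviors"] = f"{b.session_id}/behaviors.csv"
        if b.motion_raw is not None:
            pd.DataFrame({"t_s": np.arange(len(b.motion_raw)) + 0.5,
                          "raw": b.motion_raw}).to_csv(sdir / "motion_raw.csv", index=False)
            paths["motion"] = f"{b.session_id}/motion_raw.csv"
        if b.beat_times is not None:
            np.savez(sdir / "ecg.npz", beat_times=b.beat_times,
                     artifact_mask=np.asarray(b.qc.get("artifact_mask", []), float))
            paths["ecg"] = f"{b.session_id}/ecg.npz"
        if b.audio is not None:
            wav, fs = b.audio
            wavfile.write(sdir / "audio.wav", int(fs), wav.astype(np.float32))
            paths["audio"] = f"{b.session_id}/audio.wav"
        rows.append({"subject": b.subject, "pnd": b.pnd, "session_id": b.session_id,
                     "duration_s": b.duration_s, **paths})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    gt = {
        "transition_days": ground_truth.transition_days,
        "coupling": ground_truth.coupling,
        "rng_seed": ground_truth.config.rng_seed if ground_truth.config else None,
    }
    (directory / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    return directory / "manifest.csv"
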