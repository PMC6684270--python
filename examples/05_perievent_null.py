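"""Peri-event arousal dynamics with a timing-scramble significance test.

Builds sessions whose heart-rate percentile is elevated around mature-call
onsets, fits session (p=0.1) and population (p=0.3) splines on the
[-10, +5] s onset window, and compares the observed curve against (a) a
bootstrap confidence band (resampling 10 traces per session) and (b) a
null band built by scrambling each session's call durations and inter-call
gaps — destroying timing while preserving event number and lengths.
"""

import numpy as np

from vocloco import ecg, perievent as pe, synth

cfg = synth.StudyConfig(n_subjects=2, sessions_per_subject=(3, 3),
                        session_duration_s=300.0, artifact_fraction=0.0,
                        rng_seed=5)
bundles, _ = synth.simulate_study(cfg, with_motion=False)

sessions = []
for b in bundles:
    if b.beat_times is None or b.calls is None:
        continue
    hr = ecg.rate_from_beats(ecg.correct_intervals(b.beat_times), b.duration_s)
    if not ecg.coverage_ok(hr):
        continue
    pct = ecg.to_percentiles(hr).percentile
    phees = b.calls[b.calls["call_type"] == "phee"].reset_index(drop=True)
    if len(phees) >= 2:
        sessions.append(pe.SessionSignal(pct, phees, b.duration_s, b.pnd))

band = pe.perievent_band(sessions, kind="heartrate", anchor="onset",
                         n_rep=1000, seed=1)
print(f"{len(sessions)} sessions with ECG and phees")
print(f"{'rel_t':>6} {'observed':>9} {'null_lo':>8} {'null_hi':>8} flag")
for g, o, lo, hi, f in zip(band.grid, band.observed, band.null_lo,
                           band.null_hi, band.exceed):
    print(f"{g:6.0f} {o:9.1f} {lo:8.1f} {hi:8.1f} {f}")
above = band.grid[band.exceed == "above"]
print(f"\nabove-null grid points: {above}")
print("Arousal percentiles climb above the scramble null around call "
      "onset (rel_t near 0): heart rate is genuinely elevated when mature "
      "calls are produced, beyond what the session's overall call load "
      "explains.")
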