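"""Per-call acoustic features: duration and Wiener entropy.

Cries (the immature infant contact call) are short and spectrally noisy —
Wiener entropy near zero — while phees (the mature contact call) are long
and tonal — strongly negative entropy.  Call tables arrive externally
scored; this module attaches the two acoustic measurements.

Conventions (recorded in :data:`SPECTRUM_META`): single-taper periodogram
with a Hann window over the whole call, DC bin excluded, natural logarithm
for the entropy, zero-power bins floored at machine epsilon times the
spectral maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps


__all__ = [
    "PowerSpectrum",
    "SPECTRUM_META",
    "power_spectrum",
    "wiener_entropy",
    "annotate_calls",
    "segment_calls",
]

#: Estimator conventions attached to every output table.
SPECTRUM_META = {
    "estimator": "hann-windowed periodogram, whole call, DC bin excluded",
    "log_base": "e",
    "zero_floor": "eps * max(power)",
}

CALL_COLUMNS = [
    "subject", "session", "pnd", "onset_s", "offset_s",
    "call_type", "duration_s", "wiener_entropy",
]


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        if len(self.power) < 2:
            raise ValueError("spectrum needs at least 2 bins")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def power_spectrum(segment, fs) -> PowerSpectrum:
    """Hann-windowed periodogram over positive frequencies (DC excluded)."""
    segment = np.asarray(segment, dtype=float).ravel()
    if segment.size < 2:
        raise ValueError("audio segment must contain at least 2 samples")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    f, pxx = sps.periodogram(segment, fs=fs, window="hann", detrend=False)
    return PowerSpectrum(frequencies=f[1:], power=pxx[1:])


def wiener_entropy(spectrum) -> float:
    """log(geometric mean / arithmetic mean) of the power spectrum.

    Always <= 0; equals 0 iff every bin is equal (perfectly flat, i.e.
    white-noise-like).  Scale-invariant.  Zero bins are floored at
    ``eps * max(power)`` so pure tones return a large negative value rather
    than ``-inf``.
    """
    power = spectrum.power if isinstance(spectrum, PowerSpectrum) else np.asarray(spectrum, float)
    if power.ndim != 1 or len(power) < 2:
        raise ValueError("need a 1-d spectrum with >= 2 bins")
    if np.any(power < 0):
        raise ValueError("power must be nonnegative")
    pmax = power.max()
    if pmax == 0:
        raise ValueError("all-zero spectrum: entropy undefined")
    floored = np.maximum(power, np.finfo(float).eps * pmax)
    log_gm = np.mean(np.log(floored))
    log_am = np.log(np.mean(floored))
    return float(min(log_gm - log_am, 0.0))


def annotate_calls(events: pd.DataFrame, audio, fs) -> pd.DataFrame:
    """Attach ``duration_s`` and ``wiener_entropy`` to each scored call.

    Each event is measured over its [onset, offset) samples.  Events that
    fall outside the recording are kept but flagged with NaN features and an
    ``error`` note; event count and order are always preserved.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    out = events.copy().reset_index(drop=True)
    dur = np.full(len(out), np.nan)
    ent = np.full(len(out), np.nan)
    err = [""] * len(out)
    for i, row in out.iterrows():
        on, off = float(row["onset_s"]), float(row["offset_s"])
        if off <= on:
            err[i] = "offset <= onset"
            continue
        dur[i] = off - on
        i0, i1 = int(round(on * fs)), int(round(off * fs))
        if i0 < 0 or i1 > len(audio):
            err[i] = "event outside audio extent"
            continue
        if i1 - i0 < 2:
            err[i] = "segment too short"
            continue
        try:
            ent[i] = wiener_entropy(power_spectrum(audio[i0:i1], fs))
        except ValueError as exc:
            err[i] = str(exc)
    out["duration_s"] = dur
    out["wiener_entropy"] = ent
    if any(err):
        out["error"] = err
    return out


def segment_calls(audio, fs, threshold_db=-30.0, min_gap_s=0.1, min_dur_s=0.05,
                  smooth_s=0.01) -> pd.DataFrame:
    """Envelope-threshold call segmentation (convenience stand-in).

    Maximal runs of the smoothed amplitude envelope above ``threshold_db``
    (relative to the session's peak envelope), closed over gaps shorter than
    ``min_gap_s``, dropped when shorter than ``min_dur_s``.  Half-open
    [onset_s, offset_s) intervals.  The pipeline's canonical input is a
    scored call table; this exists for unscored audio.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        raise ValueError("audio is empty")
    win = max(1, int(round(smooth_s * fs)))
    env = np.convolve(np.abs(audio), np.ones(win) / win, mode="same")
    peak = env.max()
    if peak == 0:
        return pd.DataFrame(columns=["onset_s", "offset_s"])
    above = env > peak * 10 ** (threshold_db / 20.0)

    # runs of True
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(above))

    # close short gaps, then apply the duration filter
    merged = []
    for s, e in zip(starts, stops):
        if merged and (s - merged[-1][1]) < min_gap_s * fs:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    rows = [(s / fs, e / fs) for s, e in merged if (e - s) >= min_dur_s * fs]
    return pd.DataFrame(rows, columns=["onset_s", "offset_s"])
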