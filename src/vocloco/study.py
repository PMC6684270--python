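"""In-memory study containers shared by the generator, loaders and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


CALL_TYPES = ("cry", "phee")

#: Immature/mature pairs per motor domain; remaining behaviors are
#: developmentally flat controls.
POSTURAL_BEHAVIORS = ("forelimb support", "hanging", "hindlimb support",
                      "raising head", "righting reflex")
LOCOMOTOR_BEHAVIORS = ("climbing", "crawling", "digging", "jumping", "walking")
IMMATURE = {"vocal": "cry", "postural": "righting reflex", "locomotor": "crawling"}
MATURE = {"vocal": "phee", "postural": "hindlimb support", "locomotor": "walking"}


@dataclass
class SessionBundle:
    """One observation session's aligned streams plus metadata.

    Tables use seconds from session start and half-open [onset, offset)
    intervals.  Modalities the session lacks are ``None`` with the matching
    availability flag False (real studies record each modality for only a
    subset of sessions).
    """

    subject: str
    pnd: int
    session_id: str
    duration_s: float
    calls: pd.DataFrame | None = None          # onset_s, offset_s, call_type
    behaviors: pd.DataFrame | None = None      # onset_s, offset_s, category, behavior
    motion_raw: np.ndarray | None = None       # 1 Hz luminance-difference series
    beat_times: np.ndarray | None = None       # observed (artifact-censored) beats, s
    ecg: object | None = None                  # EcgRecording when waveforms exist
    audio: tuple | None = None                 # (waveform, fs)
    qc: dict = field(default_factory=dict)

    @property
    def has_audio(self) -> bool:
        return self.calls is not None

    @property
    def has_video(self) -> bool:
        return self.motion_raw is not None or self.behaviors is not None

    @property
    def has_ecg(self) -> bool:
        return self.beat_times is not None or self.ecg is not None
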