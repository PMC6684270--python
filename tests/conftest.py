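import numpy as np
import pandas as pd
import pytest

from vocloco import synth
from vocloco.perievent import SessionSignal


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 3 subjects, 15 sessions each, 5-minute sessions."""
    return synth.StudyConfig(
        n_subjects=3, sessions_per_subject=(15, 15, 15),
        session_duration_s=300.0, rng_seed=1234,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synth.simulate_study(small_config)


def make_arousal_sessions(seed, n_sessions=4, dur=240, n_events=12,
                          effect=0.0, event_dur=(1.0, 3.0)):
    """Percentile-like AR(1) sessions with optional elevation during events."""
    rng = np.random.default_rng(seed)
    sessions = []
    for s in range(n_sessions):
        e = rng.normal(0, 10, dur)
        sig = np.empty(dur)
        acc = 0.0
        for i in range(dur):
            acc = 0.8 * acc + e[i]
            sig[i] = acc
        sig = 50 + sig
        on = np.sort(rng.uniform(5, dur - 10, n_events))
        off = on + rng.uniform(*event_dur, n_events)
        if effect:
            for a, b in zip(on, off):
                sig[max(int(a - 1), 0):min(int(b + 1), dur)] += effect
        sessions.append(SessionSignal(
            sig, pd.DataFrame({"onset_s": on, "offset_s": off}),
            float(dur), pnd=s + 1))
    return sessions
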