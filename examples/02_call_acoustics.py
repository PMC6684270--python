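"""Measure call duration and Wiener entropy from synthetic session audio.

Renders one session's audio (noisy cries, tonal phees), annotates the
scored call table, and shows that the two call types separate on both
features: phees are longer and more tonal (more negative entropy).
"""

import numpy as np

from vocloco import synth
from vocloco.acoustics import annotate_calls

cfg = synth.StudyConfig(rng_seed=7, session_duration_s=120.0)
rng = np.random.default_rng(0)
calls = synth.simulate_session_calls(pnd=10, config=cfg, rng=rng)
wav, fs = synth.render_audio(calls, cfg.session_duration_s, rng=rng)

annotated = annotate_calls(calls, wav, fs)
summary = annotated.groupby("call_type")[["duration_s", "wiener_entropy"]].mean()
print(annotated.head().to_string())
print("\nper-type means:")
print(summary.to_string())
print("\nWiener entropy is log(geometric/arithmetic mean) of the power "
      "spectrum: 0 for white noise, strongly negative for tones. The tonal "
      "phee sits well below the noisy cry, and phees last longer.")
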