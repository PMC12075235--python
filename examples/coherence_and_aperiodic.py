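"""Wavelet coherence between channels and the aperiodic (1/f) exponent.

Two EEG channels sharing an 8 Hz component are coherent at that frequency;
the aperiodic exponent is the 1/f slope of the Welch PSD after robustly
ignoring oscillatory peaks.
"""

import numpy as np

from vigilscore import (
    StateSchedule,
    aperiodic_exponent,
    coherence_profile,
    colored_noise,
    synth_recording,
    welch_psd,
)

rec, _ = synth_recording(
    StateSchedule([("a1", 60.0)]), seed=5, shared_freq=8.0, shared_amp=4.0
)
eeg = rec.pick("EEG")
prof = coherence_profile(eeg[0], eeg[1], rec.fs)
at8 = prof.coherence[np.argmin(np.abs(prof.freqs - 8.0))]
print(f"coherence peak  : {prof.peak_value:.2f} at {prof.peak_freq:.1f} Hz; "
      f"coherence at the shared 8 Hz tone = {at8:.2f}")

fs = 200.0
noise = colored_noise(1.5, int(600 * fs), fs, seed=2)
fit = aperiodic_exponent(welch_psd(noise, fs, seg_len=8.0))
print(f"aperiodic slope : {fit.exponent:.2f} (generated with exponent 1.5)")
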