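"""Detect injected sleep spindles in pink-noise background.

Eleven-hertz Hann-windowed bursts are added at known times; the detector
band-passes 8-18 Hz, z-scores, and thresholds the Hilbert envelope (peak
above 3.5 SD, 0.5-2 s between the 1 SD crossings). Bursts shorter than
0.5 s or longer than 2 s must be rejected by the duration rule.
"""

import numpy as np

from vigilscore import colored_noise, detect_spindles, inject_spindles

fs = 128.0
background = colored_noise(1.0, int(600 * fs), fs, seed=8)
amp = 6 * background.std()

times = np.arange(20.0, 580.0, 40.0)
signal = inject_spindles(background, fs, times, freq=11.0, dur=1.0, amp=amp)
signal = inject_spindles(signal, fs, np.array([5.0]), dur=0.2, amp=amp)  # too short
signal = inject_spindles(signal, fs, np.array([590.0]), dur=3.0, amp=amp)  # too long

events = detect_spindles(signal, fs)
hits = sum(any(e.start <= m <= e.end for e in events) for m in times + 0.5)
print(f"injected 1 s bursts : {len(times)}, recalled {hits}")
print(f"total events kept   : {len(events)} (extra events are background noise)")
print("the 0.2 s and 3 s bursts are rejected:",
      not any(e.start <= 5.1 <= e.end or e.start <= 591.5 <= e.end for e in events))
for e in events[:3]:
    print(f"  event {e.start:6.1f}-{e.end:6.1f} s  dur {e.duration:.2f} s  peak {e.peak_z:.1f} SD")
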