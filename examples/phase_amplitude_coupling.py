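"""Phase-amplitude coupling: a 4 Hz phase modulating a 40 Hz amplitude.

PACz is the coupling strength z-scored against 100 circular time-shifts of
the phase series. A coupled signal should peak near the true modulating
frequency with z well above 3; an uncoupled signal should hover near 0.
"""

import numpy as np

from vigilscore import pac_signal, pacz

fs = 256.0
n = int(20 * fs)

coupled = pac_signal(f_phase=4.0, f_amp=40.0, depth=0.8, n=n, fs=fs, seed=0)
res = pacz(coupled, fs, seed=1)
print(f"coupled fixture : max PACz = {res.max_value:.1f} at phase {res.max_phase_freq:g} Hz")

zs = []
for s in range(10):
    uncoupled = pac_signal(4.0, 40.0, depth=0.0, n=n, fs=fs, seed=100 + s)
    r = pacz(uncoupled, fs, phase_freqs=np.array([4.0]), amp_freqs=np.array([40.0]), seed=s)
    zs.append(r.pacz[0, 0])
print(f"uncoupled       : PACz at 4 Hz/40 Hz = {np.mean(zs):.2f} +- {np.std(zs):.2f} "
      "(10 repeats; near standard normal)")
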