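"""Calibrate the detrended fluctuation analysis on known noise classes.

The DFA exponent alpha reads 0.5 for white noise (no memory), about 1 for
pink noise (long-range correlations, as near criticality), and below 0.5 for
anti-correlated series. These reference values anchor the interpretation of
alpha measured on EEG band envelopes.
"""

import numpy as np

from vigilscore import colored_noise, dfa_alpha

n = 100_000
for name, make in [
    ("white noise        ", lambda s: colored_noise(0.0, n, seed=s)),
    ("pink (1/f) noise    ", lambda s: colored_noise(1.0, n, seed=s)),
    ("diff'd white (anti) ", lambda s: np.diff(colored_noise(0.0, n + 1, seed=s))),
]:
    alphas = [dfa_alpha(make(s)).alpha for s in range(10)]
    print(f"{name} alpha = {np.mean(alphas):.3f} +- {np.std(alphas):.3f}  (10 seeds)")
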