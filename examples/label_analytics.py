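"""Label-sequence analytics: transitions, hourly distribution, CV, curves.

Works entirely from the hypnogram (the per-epoch label string): transition
pairs count consecutive-epoch combinations (64 ordered pairs over the eight
scoring labels), the hourly table distributes labels over the light/dark
cycle, and the difference-wave test compares per-frequency curves between
two groups with a Bonferroni-corrected confidence interval.
"""

from datetime import datetime

import numpy as np

from vigilscore import (
    coefficient_of_variance,
    default_schedule,
    difference_wave_test,
    hourly_distribution,
    score_recording,
    synth_recording,
    transition_pair_counts,
)

rec, _ = synth_recording(default_schedule(600.0), seed=7)
labels = score_recording(rec)

pairs = transition_pair_counts(labels)
persist = int(np.trace(pairs.to_numpy()))
print(f"consecutive pairs : {pairs.to_numpy().sum()} total over {pairs.size} cells")
print(f"within-state pairs: {persist}, transitions: {pairs.to_numpy().sum() - persist}")

table = hourly_distribution(labels, start_time=datetime(2024, 5, 1, 9, 0))
print("first hour label counts:", dict(table.iloc[0].drop("phase").pipe(lambda s: s[s > 0])))

print(f"CV of [1, 3]      : {coefficient_of_variance([1.0, 3.0]):.4f} (sd/mean)")

rng = np.random.default_rng(0)
group_a = rng.standard_normal((10, 65))
group_b = group_a + np.where(np.arange(65) == 30, 5.0, 0.0)  # one shifted frequency
mask = difference_wave_test(group_a, group_b)
print(f"difference wave   : {mask.sum()} of 65 frequencies significant "
      f"(index {np.flatnonzero(mask)})")
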