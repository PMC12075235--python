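"""Simulate a 10-minute EEG+EMG recording and score it back.

A known schedule of wake and sleep states drives the generator; the scorer
then works only from the signal. The printed accuracy is the fraction of 1 s
epochs whose label matches the schedule's ground truth, and the proportions
show how much of the recording each state occupies.
"""

import numpy as np

from vigilscore import default_schedule, score_recording, state_proportions, synth_recording

schedule = default_schedule(600.0)
recording, truth = synth_recording(schedule, seed=42)
labels = score_recording(recording)

accuracy = np.mean([a == b for a, b in zip(labels.labels, truth.labels)])
print(f"epochs scored : {labels.n_epochs}")
print(f"label accuracy: {accuracy:.3f}   (fraction of epochs matching ground truth)")
print("state proportions (fraction of recording time):")
for code, frac in state_proportions(labels).items():
    if frac > 0:
        print(f"  {code}: {frac:.3f}")
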