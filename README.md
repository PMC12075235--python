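# vigilscore

Rule-based, semi-automatic scoring of rodent EEG/EMG recordings into seven
vigilance states, with the per-state analysis battery used to validate that
the states are physiologically distinct, and a synthetic-recording generator
that makes the whole pipeline testable without animal data.

Manual sleep scoring is slow, and supervised classifiers must be retrained
per dataset. `vigilscore` instead treats the frequency profile of each state
as fixed: every 1 s epoch's FFT power spectrum is matched against printed
band rules, and only the wake/sleep boundary (from EMG muscle tone) and the
noise bounds are recording-specific. The same rules therefore produce the
same labels on every dataset.

## The states and their rules

Each epoch is first checked against absolute noise bounds, then gated by
muscle tone (tense = awake, relaxed = asleep), then classified:

| state | label | rule (summed power over half-open bands) |
|-------|-------|------------------------------------------|
| a1 (active wake)   | `a` | max of the awake bands is delta, 0.2–3 Hz |
| a2 (theta wake)    | `b` | max is theta, 3.2–6 Hz |
| a3 (resting state) | `c` | max is alpha, 6.2–12 Hz |
| REM                | `l` | P[6,10) > P[0.2,6) |
| nREM1 (slow-wave)  | `m` | r = P[0.2,12)/P[20,24) > 20 |
| nREM2              | `n` | 10 < r ≤ 20 |
| nREM3 (spindles)   | `o` | r ≤ 10 |
| noise              | `N` | total power too large or too small |

Labels are single ASCII characters; `U` (unscored) exists for development
and never appears in finished scorings. On top of the labels the package
computes state proportions, the 64 ordered consecutive-epoch label pairs,
hourly and cumulative distributions over the light/dark cycle, and
group-comparison statistics (correlograms with Bonferroni-adjusted
significance, difference-wave tests on per-frequency curves).

The per-state battery comprises time-averaged wavelet coherence profiles
(0.5–70 Hz), phase-amplitude coupling z-scored against 100 circular phase
permutations (PACz), detrended fluctuation analysis (α exponent, 20 scales
spanning 1–20 % of the segment), the functional excitation–inhibition ratio
fE/I = 1 − corr(windowed fluctuation, windowed amplitude) (undefined when
α < 0.6), the aperiodic 1/f exponent from a robust log-log PSD fit, and
sleep-spindle detection (8–18 Hz FIR, Hilbert envelope of z-scores, peak
> 3.5 SD, duration 0.5–2 s).

## Worked example

```
python examples/score_synthetic_recording.py
```

```
epochs scored : 600
label accuracy: 1.000   (fraction of epochs matching ground truth)
state proportions (fraction of recording time):
  a: 0.200
  b: 0.100
  c: 0.100
  l: 0.067
  m: 0.267
  n: 0.133
  o: 0.133
```

A 10-minute synthetic recording follows a known wake → nREM → REM schedule;
the scorer recovers every epoch's label from the signal alone, and the
proportions match the schedule (120 s of a1 = 0.200, and so on). The other
scripts in `examples/` each demonstrate one analysis: DFA calibration on
known noise classes, PACz on a coupled fixture, spindle injection and
recall, coherence between channels sharing an oscillation, and the label
analytics.

## Command line

```
vigilscore simulate --seed 3 --out rec.edf --truth-out truth.txt
vigilscore score --in rec.edf --epoch-len 1 --out labels.txt
vigilscore analyze --in rec.edf --labels labels.txt --metrics dfa,pacz,spindles
```

Recordings are EDF or CSV with a JSON sidecar (sampling rate, channel
roles); label files hold one byte per epoch. All thresholds in the scoring
config (TOML) can be overridden by CLI flags, and every manual override is
logged.

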