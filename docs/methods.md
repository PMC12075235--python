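# Methods

## Scoring model

The scorer assumes each vigilance state has a fixed spectral fingerprint:
classification reads nothing but the per-epoch FFT power profile plus a
binary muscle-tone state. Epochs are contiguous, non-overlapping, default
1 s (0.5 and 5 s supported); a trailing partial epoch is dropped. Each epoch
is mean-removed and zero-padded to the 5 s equivalent before the FFT so that
spectral bins land on a 0.2 Hz grid at every supported epoch length — the
printed band edges (0.2, 3, 3.2, 6, 6.2, 12, 20, 24 Hz) then fall exactly on
bin boundaries. No taper is applied: the rules compare summed band powers,
where the sidelobe variance a taper would suppress is immaterial, and the
profile shape is what matters. Bands are half-open `[lo, hi)`, so adjacent
printed bands never double-count a bin and a disjoint partition of a range
sums exactly to the range's power. The printed gaps (3–3.2, 6–6.2 Hz) belong
to no band.

Rule precedence is noise → macro gate → sub-rules. The noise test is the
only scale-sensitive rule (total 0.5–70 Hz power outside configured bounds,
or any non-finite value); all sub-rules are ratios or argmaxes, so an
epoch's sub-label is invariant under positive rescaling of the signal. REM
is tested before the non-REM ladder because a REM epoch can also satisfy
r > 10. Boundary handling: the awake argmax resolves ties toward the higher
band (a3 over a2 over a1 — dominance of the faster rhythm is the stronger
claim); in the non-REM ladder, r exactly 20 falls to nREM2 and r exactly 10
to nREM3 (exact boundaries go to the deeper-sleep label); a zero denominator
reads as infinite r (nREM1). Every epoch receives exactly one label; a
failed epoch becomes noise, never unscored.

Noise bounds default to 10⁻³× and 10³× the median per-epoch total power of
the recording, because absolute power varies across subjects and hardware;
explicit bounds (config or CLI) override the default and both are logged.

## EMG gate

Wake and sleep are separated by muscle tone, not by the EEG: the EMG is
high-pass filtered at 10 Hz, squared, and summed per 1 s window across EMG
channels; change points of this envelope are found by exact penalized
mean-shift segmentation (PELT, L2 cost). The default penalty
3·log(n)·var(envelope) scales with the envelope's variance, making detection
invariant to rescaling. Segments shorter than 10 s are merged into the
neighbor with the closer mean — envelope noise otherwise splinters
transitions. Segment means are clustered two-ways; the tense/relaxed
threshold is the cluster midpoint. If the two clusters differ by less than
2× in summed power the envelope is treated as single-level (physiological
tone contrast is larger), and the single level is compared against an
optional noise floor — without a floor, a positive-mean envelope reads as
tense, with a logged warning. This single-level fallback cannot tell an
all-sleep recording from an all-wake one; that ambiguity is intrinsic to a
scale-free gate and is the main reason transitions deserve a visual check.

Manual overrides implement that check: an edit `(t, state)` inserts a
boundary at `t` and holds `state` until the next boundary of the original
segmentation; shifting a boundary is two edits (restate the old state up to
the new boundary, start the new state there). Overrides are logged verbatim
and the result is flagged `manual`. Without any EMG channel the gate falls
back to two-means clustering of per-epoch log total power (sleep is the
high-power cluster in cortical recordings), which cannot separate REM from
theta-dominated wakefulness; that ambiguity resolves toward wake and is a
documented limitation.

## Analysis battery

**Wavelet coherence** — complex Morlet CWT (PyWavelets, `cmor1.5-1.0`,
12 voices/octave, 0.5–70 Hz); cross- and auto-spectra smoothed with a
per-scale boxcar of ~12 cycles in time and 5 bins across scale before
forming |S(WxWy*)|²/(S|Wx|²·S|Wy|²); cone-of-influence edges trimmed; the
time axis averaged out. Smoothing sets the null level: independent white
noise averages ≈ 0.1, self-coherence is exactly 1. When both channels carry
strong independent oscillations near a shared one, coherence saturates into
a plateau and the argmax may sit one or two grid bins off the shared
frequency.

**PACz** — coupling is the mean-vector modulation index |mean(A·e^{iφ})|,
with φ from a narrow, steep phase band (half-width max(0.5, f/4),
order-6 Butterworth — wide or shallow phase bands let a neighboring
frequency's oscillation leak in and smear the comodulogram) and A from an
amplitude band wide enough to carry the modulation sidebands (half-width
f_phase + 2 Hz, order 4). The null is 100 seeded circular time-shifts of the
phase series (≥ 1 s), preserving both marginals; PACz is the z-score against
that null. Defaults: phase 1–15 Hz in 1 Hz steps, amplitude
{30, 35, 40, 45, 50} Hz. At least five cycles of the slowest phase frequency
are required. Note the surrogate logic presumes physiological phase
diffusion: for a strictly periodic modulator, circular shifts only rotate
the mean vector without changing its magnitude, so the test fixture
generator gives its modulator a phase random walk (1 rad²/s by default).

**DFA** — profile = cumulative sum of the mean-removed series; 20
log-spaced scales from 1 % to 20 % of the series length; per scale,
non-overlapping windows are linearly detrended and the pooled RMS residual
is F(s); α is the slope of log F vs log s, *weighted by the number of
windows per scale*. The weights matter: the largest scales hold only five
windows, whose noisy F estimates enter the log fit with a downward Jensen
bias; the weighted fit recovers white noise at α = 0.48 ± 0.04 and pink
noise at 0.97 ± 0.07 (10 × 10⁵ samples), versus 0.47/0.95 unweighted.
Series shorter than 2500 samples are rejected (20 distinct scales down to
1 % do not exist). Per-frequency DFA filters the signal into ±20 % relative
bands, takes the Hilbert envelope, and runs DFA on the envelope; bands above
Nyquist are skipped and logged. Envelope DFA is only meaningful at scales
above the band filter's own correlation time (~1/bandwidth), which is why
low-frequency bands need long segments.

**fE/I** — per non-overlapping 5 s window (configurable): mean envelope
amplitude, and the DFA fluctuation of the window after the envelope profile
is divided by that window's mean amplitude (size-normalized shape
variation). fE/I = 1 − Pearson r(fluctuation, amplitude); values above 1
read excitation-dominated, below 1 inhibition-dominated. fE/I is not
computed when the band's α < 0.6 — without long-range correlations the
quantity is undefined — and the result is returned as invalid rather than a
number. At least 10 windows are required.

**Aperiodic exponent** — robust fit of log₁₀ power vs log₁₀ frequency over
0.5–65 Hz (≥ 10 points, strictly positive PSD): ordinary least squares,
then 10 iterations in which points above the current fit are down-weighted
by exp(−(r/σ)²) (σ from the negative residuals) while points on or below it
keep weight 1. Oscillatory peaks only ever add power, so one-sided
down-weighting removes them without biasing the background; a pure power law
is recovered exactly and a single additive Gaussian peak perturbs the
exponent by < 0.1.

**Spindles** — FIR band-pass 8–18 Hz (~1 s, Hamming-windowed `firwin`,
zero-phase), z-score, Hilbert envelope of the z-scores; an event runs from
the envelope's upward 1 SD crossing to its downward crossing and is kept if
the envelope peak exceeds 3.5 SD and the duration is 0.5–2 s. On pink-noise
background the false-positive rate under these thresholds is ≤ 0.5 events
per minute (asserted in the tests). A flat signal has undefined z-scores and
yields zero events with a warning. `state_average_psd` concatenates the
epochs of one state and reports the Welch PSD over 9–16 Hz for between-state
spindle-band comparisons; concatenation seams add a small broadband floor,
acceptable for the narrow band compared.

**Label analytics** — proportions over the eight scoring labels (sum to 1);
an 8×8 ordered-pair matrix over consecutive epochs (64 cells; the total is
n−1; pairs containing noise can be excluded from display); hourly label
counts aligned to wall clock with a light/dark flag (12 h/12 h cycle, lights
off at 14:00 by default); nondecreasing cumulative per-state curves with one
step per hour. CV uses the sample (n−1) standard deviation over the mean —
group sizes in animal work are small. The correlogram is pairwise Pearson
over per-subject columns with Bonferroni adjustment over the unique
off-diagonal cells; constant columns are undefined and masked. The
difference-wave test builds a Welch t-interval on the difference of group
means per frequency, Bonferroni-corrected across frequencies, and flags
frequencies whose interval excludes zero; under a simulated null
(1000 replicates, 65 frequencies, n = 10 per group) the family-wise error
is ≤ 5 % up to Monte-Carlo resolution (the test allows two binomial
standard errors, ≈ 1.4 points, above the nominal rate — the estimator of a
true rate of ≈ 4.9 % lands above 5.0 % in roughly four runs out of ten).

## Synthetic generator

The generator emulates spectral content, not waveform morphology: per state,
a 1/f^β Gaussian background plus sinusoidal peaks with random phase and
±10 % amplitude jitter; EMG channels are white noise scaled by the state's
muscle tone (5:1 tense:relaxed by default — the ordering is physiological,
the ratio a choice); transitions are instantaneous at epoch boundaries, as
rodent state switches effectively are. Default recipes: a1 = 1/f + 2 Hz
peak (plus a weaker 10 Hz bump), a2 = 5 Hz peak, a3 = 10 Hz peak (plus a
weak delta bump), REM = 7.5 Hz peak over a shallow background, nREM1 =
strong 1.5 Hz peak over a steep (β = 2) background. The a2 peak sits at
5 Hz rather than on the 6 Hz band edge: 6.0 Hz falls in the half-open gap
between the printed theta band [3.2, 6) and alpha band [6.2, 12), feeding
neither.

For nREM2/nREM3 the depth rule constrains a *ratio* of band sums, and slow
tones in 1 s windows have strongly phase-dependent band power, so free
recipe weights leave the realized ratio spread across the rule boundary.
The generator instead pins the ratio: after drawing the epoch's low-band
content it measures P[0.2,12) and scales a 22 Hz floor tone so that
P[0.2,12)/P[20,24) lands on a target (14.5 for nREM2, 4 for nREM3, ±5 %
jitter) well inside the rule interval. A self-check (`check_recipe`)
verifies each recipe satisfies its own rule in ≥ 95 of 100 draws; the
defaults pass at ≥ 99 % for epoch lengths 0.5–5 s. Spindles are injected
into nREM2/nREM3 at 2 and 5 events/min (0.8 s, 11 Hz). All operations are
deterministic under a fixed seed.

What passing tests on these recordings show: the rule engine, gate,
analytics and metrics behave correctly on signals whose spectral content
matches the states' definitions. What they do not show: robustness to
artifacts, K-complexes, epileptiform activity, electrode drift, or states
whose real spectra straddle the printed boundaries — real recordings blur
the rules in ways the generator deliberately does not.

## Problem sizes in tests

The default suite simulates 10-minute recordings at 256 Hz for end-to-end
scoring, 10⁵-sample series for DFA calibration, 20 s segments for PACz
(50-repeat null calibration), 10-minute fixtures for spindle injection, and
1000 replicates for the difference-wave null — sizes at which every
calibration quantity is stable to well within its asserted tolerance.

## Known limitations

- The EMG gate's absolute ambiguity for recordings without tone transitions
  (see above); the EMG-free fallback cannot separate REM from a2.
- Epochs mixing two states get whichever label the mixture's band sums
  favor; at 5 s epochs boundary epochs are common.
- EDF writing quantizes to 16 bits over the per-channel amplitude range
  (relative error ~3×10⁻⁵); scoring is unaffected.
- The aperiodic fit assumes a single power-law background over the fit
  range; a spectral knee would need a different model.
- PACz presumes the modulating rhythm drifts in phase; on strictly periodic
  signals the circular-shift null is degenerate and PACz is conservative.
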