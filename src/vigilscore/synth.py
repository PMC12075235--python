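"""Synthetic EEG+EMG recordings with known ground truth.

Every other part of the package is testable against recordings generated
here: each vigilance state gets a spectral recipe (a 1/f background plus
oscillatory peaks and, for the deeper non-REM states, a raised 20-24 Hz
floor and injected spindles) built so that the epoch band sums satisfy that
state's scoring rule with high probability. EMG channels carry white noise
scaled by the state's muscle tone (high while awake, low in sleep), which is
what the change-point gate consumes. Transitions are instantaneous at epoch
boundaries, matching how abruptly rodent vigilance states switch.

The recipes emulate spectral content only: no K-complexes, no waveform
morphology, no volume-conduction structure beyond an optional shared
sinusoid between EEG channels for coherence tests.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .recording import ChannelMeta, Recording
from .scorer import MEANING_LABEL, LabelSequence


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def colored_noise(beta: float, n: int, fs: float = 1.0, seed=None) -> np.ndarray:
    """Gaussian noise with PSD proportional to 1/f**beta, unit variance.

    Spectral shaping of white noise; beta=0 gives white, beta=1 pink,
    beta=2 Brownian-like.
    """
    if not -1.0 <= beta <= 3.0:
        raise ValueError("beta must be in [-1, 3]")
    if n < 16:
        raise ValueError("need at least 16 samples")
    rng = _rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass(frozen=True)
class StateRecipe:
    """Spectral fingerprint of one state.

    peaks: (center Hz, amplitude) sinusoids with random phase and mild
    amplitude jitter. target_ratio: when set, a 22 Hz floor tone is scaled
    per epoch so the ratio P[0.2,12)/P[20,24) lands near the target (with a
    small multiplicative jitter); slow tones in short windows have strongly
    phase-dependent band power, so pinning the realized ratio is what keeps
    the non-REM depth rule satisfied draw after draw. emg_tone: EMG noise
    amplitude (tense is about 5x relaxed). spindle_rate: injected 11 Hz
    bursts per minute.
    """

    background_beta: float
    background_amp: float
    peaks: tuple = ()
    target_ratio: float | None = None
    ratio_jitter: float = 0.05
    emg_tone: float = 1.0
    spindle_rate: float = 0.0


_FLOOR_FREQ = 22.0  # center of the 20-24 Hz non-REM denominator band

#: Default recipes. Peak placements keep each state's dominant band sum the
#: deciding one under the printed rules: the a2 peak sits at 5 Hz, inside the
#: half-open theta band [3.2, 6) (a peak at exactly 6 Hz would fall in the
#: unassigned gap between the printed theta and alpha edges). Non-REM depth
#: targets sit well inside their rule intervals: nREM1 leaves the 20-24 Hz
#: floor empty (r far above 20), nREM2 targets r=14.5 (10 < r <= 20) and
#: nREM3 targets r=4 (r <= 10).
DEFAULT_RECIPES: dict[str, StateRecipe] = {
    "a1": StateRecipe(1.0, 0.5, peaks=((2.0, 2.0), (10.0, 0.8)), emg_tone=5.0),
    "a2": StateRecipe(1.0, 0.5, peaks=((5.0, 2.0),), emg_tone=5.0),
    "a3": StateRecipe(1.0, 0.5, peaks=((10.0, 2.0), (2.0, 0.8)), emg_tone=5.0),
    "REM": StateRecipe(0.3, 0.4, peaks=((7.5, 2.5),), emg_tone=1.0),
    "nREM1": StateRecipe(2.0, 0.5, peaks=((1.5, 4.0),), emg_tone=1.0),
    "nREM2": StateRecipe(2.0, 0.3, peaks=((1.8, 3.0),), target_ratio=14.5,
                         emg_tone=1.0, spindle_rate=2.0),
    "nREM3": StateRecipe(2.0, 0.3, peaks=((2.2, 2.0),), target_ratio=4.0,
                         emg_tone=1.0, spindle_rate=5.0),
}


@dataclass
class StateSchedule:
    """Ordered (state meaning, duration s) entries; the ground-truth hypnogram."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        for state, dur in self.entries:
            if state not in MEANING_LABEL:
                raise ValueError(f"unknown state {state!r}")
            if dur <= 0:
                raise ValueError("durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.entries)

    def labels(self, epoch_len: float) -> LabelSequence:
        """Ground-truth label per epoch (state at the epoch midpoint)."""
        n = int(self.total_duration / epoch_len)
        bounds = np.cumsum([0.0] + [d for _, d in self.entries])
        states = [s for s, _ in self.entries]
        out = []
        for i in range(n):
            mid = (i + 0.5) * epoch_len
            j = int(np.searchsorted(bounds, mid, side="right")) - 1
            out.append(MEANING_LABEL[states[min(j, len(states) - 1)]])
        return LabelSequence(labels="".join(out), epoch_len=epoch_len)

    @classmethod
    def read_csv(cls, path) -> "StateSchedule":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries.append((row["state"], float(row["duration_s"])))
        return cls(entries)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["state", "duration_s"])
            writer.writerows(self.entries)


def default_schedule(total_s: float = 600.0) -> StateSchedule:
    """A wake block followed by a sleep cycle, repeated to ``total_s``.

    Blocks last tens of seconds so the EMG gate sees macro segments well
    above its minimum segment duration.
    """
    cycle = [
        ("a1", 60.0),
        ("a2", 30.0),
        ("a3", 30.0),
        ("nREM1", 80.0),
        ("nREM2", 40.0),
        ("nREM3", 40.0),
        ("REM", 20.0),
    ]
    cycle_len = sum(d for _, d in cycle)
    entries: list[tuple[str, float]] = []
    remaining = total_s
    while remaining > 0:
        for state, dur in cycle:
            take = min(dur, remaining)
            if take > 0:
                entries.append((state, take))
                remaining -= take
            if remaining <= 0:
                break
    return StateSchedule(entries)


def state_epoch_signal(
    state: str, fs: float, dur: float, recipe: StateRecipe | None = None, seed=None
) -> np.ndarray:
    """One epoch of EEG for ``state`` (background + peaks + optional floor tone)."""
    recipe = recipe or DEFAULT_RECIPES[state]
    rng = _rng(seed)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    x = recipe.background_amp * colored_noise(recipe.background_beta, max(n, 16), fs, rng)[:n]
    for freq, amp in recipe.peaks:
        jitter = 1.0 + 0.1 * rng.standard_normal()
        x += amp * max(jitter, 0.1) * np.cos(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    if recipe.target_ratio is not None:
        from .scorer import RuleThresholds
        from .spectra import band_power, epoch_power_spectrum

        th = RuleThresholds()
        sp = epoch_power_spectrum(x, fs)
        num = band_power(sp, *th.nrem_num).value
        den_bg = band_power(sp, *th.nrem_den).value
        r_t = recipe.target_ratio * (1.0 + recipe.ratio_jitter * rng.standard_normal())
        tone_phase = rng.uniform(0, 2 * np.pi)
        unit = np.cos(2 * np.pi * _FLOOR_FREQ * t + tone_phase)
        unit_den = band_power(epoch_power_spectrum(unit, fs), *th.nrem_den).value
        amp_sq = (num / max(r_t, 1e-9) - den_bg) / unit_den
        if amp_sq > 0:
            x += np.sqrt(amp_sq) * unit
    return x


def check_recipe(state: str, recipe: StateRecipe, fs: float = 256.0, n_draws: int = 100,
                 seed=0, epoch_len: float = 1.0, min_pass: float = 0.95) -> float:
    """Self-check: fraction of draws whose band sums satisfy the state's rule."""
    from .scorer import RuleThresholds, classify_awake, classify_sleep
    from .spectra import epoch_power_spectrum

    th = RuleThresholds()
    rng = _rng(seed)
    want = MEANING_LABEL[state]
    hits = 0
    for _ in range(n_draws):
        x = state_epoch_signal(state, fs, epoch_len, recipe, rng)
        sp = epoch_power_spectrum(x, fs)
        got = classify_awake(sp, th) if want in "abc" else classify_sleep(sp, th)
        hits += got == want
    frac = hits / n_draws
    if frac < min_pass:
        raise ValueError(
            f"recipe for {state} satisfies its rule in only {frac:.0%} of {n_draws} draws"
        )
    return frac


def inject_spindles(
    signal: np.ndarray,
    fs: float,
    times: np.ndarray,
    freq: float = 11.0,
    dur: float = 1.0,
    amp: float = 1.0,
) -> np.ndarray:
    """Add Hann-windowed sinusoidal bursts at ``times`` (burst starts, s)."""
    signal = np.asarray(signal, dtype=float).copy()
    times = np.sort(np.asarray(times, dtype=float))
    if np.any(np.diff(times) < dur):
        raise ValueError("spindle bursts must not overlap")
    n_burst = int(round(dur * fs))
    window = np.hanning(n_burst)
    t = np.arange(n_burst) / fs
    for start in times:
        i0 = int(round(start * fs))
        if i0 < 0 or i0 + n_burst > signal.size:
            raise ValueError(f"burst at {start} s falls outside the signal")
        signal[i0 : i0 + n_burst] += amp * window * np.sin(2 * np.pi * freq * t)
    return signal


def pac_signal(
    f_phase: float,
    f_amp: float,
    depth: float,
    n: int,
    fs: float,
    seed=None,
    noise_amp: float = 0.2,
    phase_diffusion: float = 1.0,
) -> np.ndarray:
    """Carrier at ``f_amp`` amplitude-modulated by the phase of ``f_phase``.

    The slow oscillation itself is included (amplitude 1) so the phase is
    recoverable from the compound signal, plus white background noise. Its
    phase diffuses as a random walk (``phase_diffusion`` rad^2/s), like a
    physiological rhythm and unlike a clock: a strictly periodic modulator
    would make phase-amplitude alignment invariant under the circular-shift
    surrogates that normalize PACz.
    """
    if not 0 < f_phase < f_amp < fs / 2:
        raise ValueError("need 0 < f_phase < f_amp < fs/2")
    if not 0 <= depth <= 1:
        raise ValueError("depth must be in [0, 1]")
    rng = _rng(seed)
    t = np.arange(n) / fs
    jitter = np.cumsum(rng.standard_normal(n)) * np.sqrt(phase_diffusion / fs)
    phase = 2 * np.pi * f_phase * t + rng.uniform(0, 2 * np.pi) + jitter
    slow = np.cos(phase)
    envelope = (1.0 + depth * np.cos(phase)) / 2.0
    fast = envelope * np.cos(2 * np.pi * f_amp * t + rng.uniform(0, 2 * np.pi))
    return slow + fast + noise_amp * rng.standard_normal(n)


def lrtc_oscillation(
    center_freq: float,
    hurst: float,
    n: int,
    fs: float,
    seed=None,
    mod_depth: float = 0.4,
    noise_amp: float = 0.05,
) -> np.ndarray:
    """Carrier whose amplitude envelope carries long-range temporal correlations.

    The envelope is a positive affine transform of 1/f^(2H-1) noise, whose DFA
    exponent is the Hurst parameter ``hurst``; the narrowband amplitude of the
    returned signal therefore shows alpha close to H at ``center_freq``.
    """
    if not 0.5 <= hurst <= 1.0:
        raise ValueError("hurst must be in [0.5, 1]")
    rng = _rng(seed)
    env = 1.0 + mod_depth * colored_noise(2 * hurst - 1, n, fs, rng)
    env = np.clip(env, 0.05, None)
    t = np.arange(n) / fs
    x = env * np.cos(2 * np.pi * center_freq * t + rng.uniform(0, 2 * np.pi))
    return x + noise_amp * rng.standard_normal(n)


def synth_recording(
    schedule: StateSchedule,
    recipes: dict[str, StateRecipe] | None = None,
    fs: float = 256.0,
    seed=0,
    epoch_len: float = 1.0,
    n_eeg: int = 2,
    shared_freq: float | None = None,
    shared_amp: float = 1.0,
    noise_epochs: tuple[int, ...] = (),
) -> tuple[Recording, LabelSequence]:
    """Generate an EEG+EMG recording following ``schedule``, with ground truth.

    EEG channels are independent draws from the per-state recipes (optionally
    sharing one sinusoid at ``shared_freq`` for coherence tests); the single
    EMG channel is white noise scaled by the state's muscle tone. Epochs
    listed in ``noise_epochs`` are replaced by huge-amplitude spikes on every
    channel and ground-truthed as noise.
    """
    recipes = recipes or DEFAULT_RECIPES
    rng = _rng(seed)
    truth = schedule.labels(epoch_len)
    n_ep = truth.n_epochs
    spe = int(round(epoch_len * fs))
    n_samp = n_ep * spe

    eeg = np.zeros((n_eeg, n_samp))
    emg = np.zeros(n_samp)
    from .scorer import LABEL_MEANING

    spindle_lists: dict[int, list[float]] = {c: [] for c in range(n_eeg)}
    for i, code in enumerate(truth.labels):
        meaning = LABEL_MEANING[code]
        recipe = recipes[meaning]
        sl = slice(i * spe, (i + 1) * spe)
        for c in range(n_eeg):
            eeg[c, sl] = state_epoch_signal(meaning, fs, epoch_len, recipe, rng)
        emg[sl] = recipe.emg_tone * rng.standard_normal(spe)
        if recipe.spindle_rate > 0:
            # one burst per epoch with probability rate/60 * epoch_len
            if rng.random() < recipe.spindle_rate * epoch_len / 60.0 and epoch_len >= 1.0:
                start = i * epoch_len + rng.uniform(0.0, epoch_len - 0.9)
                for c in range(n_eeg):
                    spindle_lists[c].append(start)

    for c, starts in spindle_lists.items():
        if starts:
            keep = [starts[0]]
            for s in starts[1:]:
                if s - keep[-1] >= 0.9:
                    keep.append(s)
            eeg[c] = inject_spindles(eeg[c], fs, np.array(keep), freq=11.0, dur=0.8, amp=2.0)

    if shared_freq is not None:
        t = np.arange(n_samp) / fs
        common = shared_amp * np.cos(2 * np.pi * shared_freq * t + rng.uniform(0, 2 * np.pi))
        eeg += common[None, :]

    labels = list(truth.labels)
    for i in noise_epochs:
        sl = slice(i * spe, (i + 1) * spe)
        spike = 1e5 * rng.standard_normal(spe)
        eeg[:, sl] = spike[None, :]
        emg[sl] = spike
        labels[i] = "N"
    truth = LabelSequence(labels="".join(labels), epoch_len=epoch_len)

    channels = [ChannelMeta(name=f"eeg{c + 1}", role="EEG", site="cortex") for c in range(n_eeg)]
    channels.append(ChannelMeta(name="emg1", role="EMG", site="neck"))
    signal = np.vstack([eeg, emg[None, :]])
    return Recording(signal=signal, fs=fs, channels=channels), truth
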