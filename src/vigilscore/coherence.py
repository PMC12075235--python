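"""Time-averaged wavelet coherence between two channels.

Magnitude-squared wavelet coherence on a logarithmic 0.5-70 Hz grid
(12 voices per octave, analytic Morlet): the cross- and auto-spectra of the
continuous wavelet transforms are smoothed over time (window proportional to
scale) and across scales (one third of an octave) before forming
``|S(WxWy*)|^2 / (S|Wx|^2 S|Wy|^2)``. Coherence within a vigilance state is
stable over time, so the time axis is averaged out and the per-frequency
profile with its peak is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

WAVELET = "cmor1.5-1.0"
VOICES_PER_OCTAVE = 12
FREQ_RANGE = (0.5, 70.0)


@dataclass
class CoherenceProfile:
    freqs: np.ndarray
    coherence: np.ndarray  # time-averaged, in [0, 1]

    @property
    def peak_freq(self) -> float:
        return float(self.freqs[int(np.argmax(self.coherence))])

    @property
    def peak_value(self) -> float:
        return float(np.max(self.coherence))


def log_freq_grid(lo: float = FREQ_RANGE[0], hi: float = FREQ_RANGE[1],
                  voices: int = VOICES_PER_OCTAVE) -> np.ndarray:
    n = int(np.ceil(np.log2(hi / lo) * voices)) + 1
    return lo * 2 ** (np.arange(n) / voices)


def _cwt(x: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    fc = pywt.central_frequency(WAVELET)
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, WAVELET, sampling_period=1.0 / fs, method="fft")
    return coeffs


_TIME_SMOOTH_CYCLES = 12
_SCALE_SMOOTH_BINS = 5


def _smooth(field: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    """Boxcar over ~12 cycles in time per row, then a 5-bin scale smoothing."""
    out = np.empty_like(field)
    for i, f in enumerate(freqs):
        width = max(5, int(round(_TIME_SMOOTH_CYCLES * fs / f)))
        width = min(width, field.shape[1])
        kernel = np.ones(width) / width
        out[i] = np.convolve(field[i], kernel, mode="same")
    return ndimage.uniform_filter1d(out, size=_SCALE_SMOOTH_BINS, axis=0, mode="nearest")


def coherence_profile(
    x: np.ndarray, y: np.ndarray, fs: float, freqs: np.ndarray | None = None
) -> CoherenceProfile:
    """Time-averaged magnitude-squared wavelet coherence of ``x`` and ``y``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of signal for a coherence profile")
    if freqs is None:
        freqs = log_freq_grid(FREQ_RANGE[0], min(FREQ_RANGE[1], 0.95 * fs / 2))
    wx = _cwt(x, fs, freqs)
    wy = _cwt(y, fs, freqs)
    sxy_r = _smooth((wx * np.conj(wy)).real, fs, freqs)
    sxy_i = _smooth((wx * np.conj(wy)).imag, fs, freqs)
    sxx = _smooth(np.abs(wx) ** 2, fs, freqs)
    syy = _smooth(np.abs(wy) ** 2, fs, freqs)
    coh = (sxy_r**2 + sxy_i**2) / np.clip(sxx * syy, 1e-300, None)
    # trim the cone-of-influence edges (one smoothing window at each end)
    n = coh.shape[1]
    trim = min(n // 4, int(round(3 * fs / freqs.min())))
    profile = np.clip(coh[:, trim : n - trim].mean(axis=1), 0.0, 1.0)
    return CoherenceProfile(freqs=freqs, coherence=profile)
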