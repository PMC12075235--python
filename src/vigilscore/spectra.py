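"""Per-epoch FFT power profiles and band sums.

The scorer sees nothing but these spectra: the signal is cut into contiguous,
non-overlapping epochs, each epoch is mean-removed, zero-padded and Fourier
transformed, and summed band powers drive the state rules. Welch PSD
estimation is provided separately for the analyses that need a density
(aperiodic fit, spindle-band PSD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import Recording

logger = logging.getLogger("vigilscore")

#: target spectral resolution (Hz). Band edges are printed with one decimal
#: (0.2, 3.2, 6.2 ...), so bins must land on a 0.2 Hz grid for every epoch
#: length in routine use (0.5, 1, 5 s). 1 s epochs are zero-padded to the
#: 5 s equivalent.
RESOLUTION_HZ = 0.2

_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class EpochGrid:
    """Contiguous, non-overlapping tiling of a recording into epochs."""

    epoch_len: float
    n_epochs: int
    samples_per_epoch: int

    @property
    def offsets(self) -> np.ndarray:
        """Start offset (samples) of each epoch."""
        return np.arange(self.n_epochs) * self.samples_per_epoch


@dataclass
class EpochSpectrum:
    """A frequency/power pair; the scorer's sole per-epoch input."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have identical shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


@dataclass(frozen=True)
class BandPower:
    """Power summed over the half-open band [lo, hi)."""

    lo: float
    hi: float
    value: float


def segment_epochs(rec: Recording, epoch_len: float) -> EpochGrid:
    """Tile the recording into epochs of ``epoch_len`` seconds from sample 0.

    A trailing partial epoch is dropped (and logged); an epoch longer than
    the recording is an error.
    """
    spe = int(round(epoch_len * rec.fs))
    if spe < 2:
        raise ValueError("epoch_len x fs must cover at least 2 samples")
    n_epochs = rec.n_samples // spe
    if n_epochs == 0:
        raise ValueError(
            f"recording of {rec.duration:.3f} s is shorter than one {epoch_len} s epoch"
        )
    dropped = rec.n_samples - n_epochs * spe
    if dropped:
        logger.info("segment_epochs: dropped trailing partial epoch (%d samples)", dropped)
    return EpochGrid(epoch_len=epoch_len, n_epochs=n_epochs, samples_per_epoch=spe)


def _nfft(n: int, fs: float) -> int:
    """FFT length giving resolution <= RESOLUTION_HZ (zero-pad short epochs)."""
    return max(n, int(round(fs / RESOLUTION_HZ)))


def epoch_power_spectrum(epoch: np.ndarray, fs: float) -> EpochSpectrum:
    """Magnitude-squared FFT of the mean-removed, zero-padded epoch.

    No taper is applied: the rules compare summed band powers, so the profile
    shape matters, not variance efficiency.
    """
    epoch = np.asarray(epoch, dtype=float)
    if not np.any(np.isfinite(epoch)):
        raise ValueError("epoch contains no finite samples")
    x = epoch - np.nanmean(epoch)
    x = np.nan_to_num(x)
    nfft = _nfft(x.size, fs)
    spec = np.fft.rfft(x, n=nfft)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return EpochSpectrum(freqs=freqs, power=power)


def epoch_spectra(rec: Recording, grid: EpochGrid, channel: int = 0) -> list[EpochSpectrum]:
    """Spectrum of every epoch of one channel (vectorised over epochs)."""
    spe = grid.samples_per_epoch
    mat = rec.signal[channel, : grid.n_epochs * spe].reshape(grid.n_epochs, spe)
    mat = mat - np.nanmean(mat, axis=1, keepdims=True)
    mat = np.nan_to_num(mat)
    nfft = _nfft(spe, rec.fs)
    power = np.abs(np.fft.rfft(mat, n=nfft, axis=1)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)
    return [EpochSpectrum(freqs=freqs, power=p) for p in power]


def band_power(sp: EpochSpectrum, lo: float, hi: float) -> BandPower:
    """Sum of power over bins with lo <= f < hi (half-open).

    Half-open membership means adjacent printed bands such as 0.2-3 and
    3.2-6 Hz never double-count a bin, and a disjoint partition of a range
    sums exactly to the power of the full range.
    """
    if hi <= lo:
        raise ValueError("band requires lo < hi")
    mask = (sp.freqs >= lo - _EDGE_TOL) & (sp.freqs < hi - _EDGE_TOL)
    if not mask.any():
        raise ValueError(f"no frequency bins inside [{lo}, {hi}) Hz")
    return BandPower(lo=lo, hi=hi, value=float(np.sum(sp.power[mask])))


def welch_psd(x: np.ndarray, fs: float, seg_len: float = 4.0) -> EpochSpectrum:
    """Welch power spectral density (Hann, 50% overlap), units power/Hz."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(seg_len * fs))
    if x.size < 2 * nperseg:
        raise ValueError(
            f"signal of {x.size} samples is too short for two {seg_len} s Welch segments"
        )
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    return EpochSpectrum(freqs=freqs, power=psd)
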