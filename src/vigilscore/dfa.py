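"""Detrended fluctuation analysis and the functional E/I ratio.

DFA quantifies long-range temporal correlations: the series is integrated,
split into non-overlapping windows at each of 20 scales spanning 1-20% of
its length, linearly detrended per window, and the pooled RMS residual F(s)
is fit against scale on log-log axes. The slope alpha reads: 0.5 white
noise, about 1 pink noise / criticality, below 0.5 anti-correlated, above 1
usually insufficient data.

The functional excitation-inhibition ratio (fE/I) couples the windowed,
amplitude-normalized DFA fluctuation of a narrowband envelope to the
windowed amplitude itself: fE/I = 1 - corr(fluctuation, amplitude). Values
above 1 read excitation-dominated, below 1 inhibition-dominated. It is only
defined where the band shows genuine long-range correlations (alpha >= 0.6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

logger = logging.getLogger("vigilscore")

N_SCALES = 20
SCALE_RANGE = (0.01, 0.20)  # fraction of the analyzed segment
ALPHA_MIN_FEI = 0.6
REL_BANDWIDTH = 0.2  # half-bandwidth of the per-frequency band, fraction of center


@dataclass
class DFAResult:
    scales: np.ndarray  # window sizes, samples
    fluctuation: np.ndarray  # F(s), RMS of detrended windows
    alpha: float
    center_freq: float | None = None


@dataclass
class FEIResult:
    center_freq: float
    fei: float | None
    alpha: float
    valid: bool


def _dfa_fluctuations(x: np.ndarray, scales: np.ndarray) -> np.ndarray:
    profile = np.cumsum(x - x.mean())
    out = np.empty(scales.size)
    for i, s in enumerate(scales):
        n_win = profile.size // s
        seg = profile[: n_win * s].reshape(n_win, s)
        t = np.arange(s, dtype=float)
        t -= t.mean()
        denom = (t * t).sum()
        slope = seg @ t / denom
        mean = seg.mean(axis=1)
        resid = seg - mean[:, None] - slope[:, None] * t[None, :]
        out[i] = np.sqrt(np.mean(resid**2))
    return out


MIN_SAMPLES = 2500  # below this, 20 distinct scales down to 1% do not exist


def dfa_scales(n: int, n_scales: int = N_SCALES, scale_range=SCALE_RANGE) -> np.ndarray:
    """20 log-spaced window sizes spanning 1-20% of the series."""
    lo = max(4, int(round(scale_range[0] * n)))
    hi = n // int(round(1 / scale_range[1]))
    if hi <= lo:
        raise ValueError(f"series of {n} samples is too short for DFA scales")
    return np.unique(np.round(np.geomspace(lo, hi, n_scales)).astype(int))


def dfa_alpha(series: np.ndarray, scales: np.ndarray | None = None) -> DFAResult:
    """Fit the DFA scaling exponent of ``series``.

    The log-log fit is weighted by the number of windows entering each
    scale's fluctuation: the largest scales hold only a handful of windows,
    whose noisy F estimates would otherwise tilt the slope.
    """
    x = np.asarray(series, dtype=float)
    if x.size < MIN_SAMPLES:
        raise ValueError(
            f"series of {x.size} samples is insufficient for {N_SCALES} scales "
            f"down to {SCALE_RANGE[0]:.0%} of its length"
        )
    if np.ptp(x) == 0:
        raise ValueError("constant series: DFA fluctuation is zero, alpha undefined")
    scales = dfa_scales(x.size) if scales is None else np.asarray(scales, dtype=int)
    if scales.max() > x.size // 4:
        raise ValueError("largest DFA scale must not exceed a quarter of the series")
    fluct = _dfa_fluctuations(x, scales)
    if np.any(fluct <= 0):
        raise ValueError("zero fluctuation at some scale; alpha undefined")
    lx, ly = np.log(scales), np.log(fluct)
    w = (x.size // scales).astype(float)
    xm = (w * lx).sum() / w.sum()
    ym = (w * ly).sum() / w.sum()
    alpha = float((w * (lx - xm) * (ly - ym)).sum() / (w * (lx - xm) ** 2).sum())
    return DFAResult(scales=scales, fluctuation=fluct, alpha=alpha)


def _narrowband_envelope(signal: np.ndarray, fs: float, center_freq: float) -> np.ndarray:
    lo = center_freq * (1 - REL_BANDWIDTH)
    hi = center_freq * (1 + REL_BANDWIDTH)
    if hi >= fs / 2:
        raise ValueError(f"band around {center_freq} Hz exceeds Nyquist ({fs / 2} Hz)")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, signal)
    return np.abs(sps.hilbert(band))


def banded_dfa(
    signal: np.ndarray, fs: float, center_freqs: np.ndarray
) -> list[DFAResult]:
    """DFA alpha of the narrowband amplitude envelope at each center frequency.

    Bands above Nyquist are skipped with a log entry.
    """
    signal = np.asarray(signal, dtype=float)
    results = []
    for f in np.asarray(center_freqs, dtype=float):
        if f * (1 + REL_BANDWIDTH) >= fs / 2:
            logger.info("banded_dfa: skipping %.3g Hz (band above Nyquist)", f)
            continue
        env = _narrowband_envelope(signal, fs, f)
        res = dfa_alpha(env)
        res.center_freq = float(f)
        results.append(res)
    return results


def windowed_fluctuation_amplitude(
    signal: np.ndarray, fs: float, center_freq: float, window_len: float = 5.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-window (amplitude-normalized DFA fluctuation, mean amplitude) pairs.

    The envelope profile is normalized by each window's mean amplitude before
    detrending, so the fluctuation measures shape, not size; the window size
    doubles as the single DFA scale.
    """
    env = _narrowband_envelope(signal, fs, center_freq)
    alpha = dfa_alpha(env).alpha
    w = int(round(window_len * fs))
    n_win = env.size // w
    if n_win < 10:
        raise ValueError(f"need at least 10 windows of {window_len} s, got {n_win}")
    profile = np.cumsum(env - env.mean())
    amp = env[: n_win * w].reshape(n_win, w).mean(axis=1)
    seg = profile[: n_win * w].reshape(n_win, w) / amp[:, None]
    t = np.arange(w, dtype=float)
    t -= t.mean()
    slope = seg @ t / (t * t).sum()
    resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t[None, :]
    fluct = np.sqrt(np.mean(resid**2, axis=1))
    return fluct, amp, alpha


def fei_from_windows(fluctuation: np.ndarray, amplitude: np.ndarray) -> float:
    """1 minus the Pearson correlation of windowed fluctuation and amplitude."""
    r = stats.pearsonr(fluctuation, amplitude).statistic
    return float(1.0 - r)


def fei(
    signal: np.ndarray, fs: float, center_freq: float, window_len: float = 5.0
) -> FEIResult:
    """Functional E/I ratio in the band around ``center_freq``.

    Returns an invalid result (fei=None) when the band's DFA alpha is below
    0.6: without long-range correlations the measure is undefined.
    """
    fluct, amp, alpha = windowed_fluctuation_amplitude(signal, fs, center_freq, window_len)
    if alpha < ALPHA_MIN_FEI:
        return FEIResult(center_freq=center_freq, fei=None, alpha=alpha, valid=False)
    return FEIResult(
        center_freq=center_freq, fei=fei_from_windows(fluct, amp), alpha=alpha, valid=True
    )
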