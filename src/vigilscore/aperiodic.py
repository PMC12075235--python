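"""Aperiodic (1/f) component of a power spectrum.

The exponent is the negative slope of log-power vs log-frequency, fit
robustly so that oscillatory peaks riding on the 1/f background do not bias
it: points lying above the current fit are iteratively down-weighted, points
on or below it keep full weight. A pure power-law spectrum is recovered
exactly; one additive Gaussian peak perturbs the estimate by well under 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import EpochSpectrum

DEFAULT_FIT_RANGE = (0.5, 65.0)
MIN_POINTS = 10
_N_ITER = 10


@dataclass
class AperiodicFit:
    exponent: float  # slope magnitude of the 1/f component
    offset: float  # log10 power at 1 Hz
    fit_range: tuple


def aperiodic_exponent(
    psd: EpochSpectrum, fit_range: tuple = DEFAULT_FIT_RANGE
) -> AperiodicFit:
    """Robust log-log fit of the aperiodic component over ``fit_range``."""
    lo, hi = fit_range
    mask = (psd.freqs >= lo) & (psd.freqs <= hi) & (psd.freqs > 0)
    if mask.sum() < MIN_POINTS:
        raise ValueError(f"fewer than {MIN_POINTS} PSD points in {fit_range} Hz")
    p = psd.power[mask]
    if np.any(p <= 0):
        raise ValueError("PSD must be strictly positive over the fit range")
    x = np.log10(psd.freqs[mask])
    y = np.log10(p)

    w = np.ones_like(x)
    slope, intercept = np.polyfit(x, y, 1)
    for _ in range(_N_ITER):
        resid = y - (intercept + slope * x)
        neg = resid[resid <= 0]
        sigma = max(float(neg.std()), 1e-9) if neg.size else 1e-9
        w = np.where(resid <= 0, 1.0, np.exp(-((resid / sigma) ** 2)))
        wsum = w.sum()
        xm = (w * x).sum() / wsum
        ym = (w * y).sum() / wsum
        slope = (w * (x - xm) * (y - ym)).sum() / (w * (x - xm) ** 2).sum()
        intercept = ym - slope * xm
    return AperiodicFit(exponent=float(-slope), offset=float(intercept), fit_range=fit_range)
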