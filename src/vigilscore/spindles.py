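"""Sleep spindle detection and per-state spindle-band PSD.

Spindles are transient 11-16 Hz bursts of non-REM sleep. Detection: FIR
band-pass 8-18 Hz, z-score, Hilbert envelope of the z-scores; a candidate
event runs from the envelope rising above 1 SD until it falls back below
1 SD, and is kept when its envelope peak exceeds 3.5 SD and the above-1-SD
stretch lasts 0.5-2 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .scorer import LabelSequence
from .spectra import EpochSpectrum, welch_psd

logger = logging.getLogger("vigilscore")

BAND = (8.0, 18.0)
PEAK_SD = 3.5
EDGE_SD = 1.0
DURATION_S = (0.5, 2.0)
PSD_BAND = (9.0, 16.0)


@dataclass(frozen=True)
class SpindleEvent:
    start: float
    end: float
    duration: float
    peak_z: float
    channel: str = ""

    def __post_init__(self) -> None:
        if not DURATION_S[0] <= self.duration <= DURATION_S[1]:
            raise ValueError(f"spindle duration {self.duration} s outside {DURATION_S}")
        if self.peak_z <= PEAK_SD:
            raise ValueError(f"spindle peak {self.peak_z} SD not above {PEAK_SD}")


def detect_spindles(signal: np.ndarray, fs: float, channel: str = "") -> list[SpindleEvent]:
    """Detect spindle events in one channel (>= 30 s of signal)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 30 * fs:
        raise ValueError("need at least 30 s of signal for spindle detection")
    numtaps = int(fs) | 1  # ~1 s FIR, odd length
    taps = sps.firwin(numtaps, BAND, pass_zero=False, fs=fs)
    band = sps.filtfilt(taps, [1.0], x)
    sd = band.std()
    if sd == 0:
        logger.warning("flat signal: z-scores undefined, no spindles")
        return []
    z = (band - band.mean()) / sd
    env = np.abs(sps.hilbert(z))

    above = env > EDGE_SD
    step = np.diff(above.astype(int))
    starts = np.flatnonzero(step == 1) + 1
    ends = np.flatnonzero(step == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])

    events = []
    for i0, i1 in zip(starts, ends):
        dur = (i1 - i0) / fs
        peak = float(env[i0:i1].max())
        if peak > PEAK_SD and DURATION_S[0] <= dur <= DURATION_S[1]:
            events.append(
                SpindleEvent(
                    start=i0 / fs, end=i1 / fs, duration=dur, peak_z=peak, channel=channel
                )
            )
    return events


def state_average_psd(
    signal: np.ndarray,
    fs: float,
    labels: LabelSequence,
    state: str,
    band: tuple = PSD_BAND,
) -> EpochSpectrum:
    """Welch PSD of the concatenated epochs of ``state``, restricted to ``band``.

    Used to compare the spindle band (9-16 Hz) between sleep states.
    """
    x = np.asarray(signal, dtype=float)
    spe = int(round(labels.epoch_len * fs))
    idx = [i for i, lab in enumerate(labels.labels) if lab == state]
    if not idx:
        raise ValueError(f"no epochs labeled {state!r}")
    pieces = [x[i * spe : (i + 1) * spe] for i in idx if (i + 1) * spe <= x.size]
    cat = np.concatenate(pieces)
    seg_len = min(4.0, cat.size / fs / 2)
    psd = welch_psd(cat, fs, seg_len=seg_len)
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    return EpochSpectrum(freqs=psd.freqs[mask], power=psd.power[mask])
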