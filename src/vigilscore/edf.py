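"""Minimal European Data Format (EDF) writer.

Writes plain EDF (16-bit) with one data-record duration chosen so that the
sampling rate times the duration is an integer number of samples. Reading is
delegated to MNE elsewhere; this writer exists so simulated recordings can be
exchanged with standard polysomnography tooling.
"""

from __future__ import annotations

import logging
from datetime import datetime

import numpy as np

from .recording import Recording

logger = logging.getLogger("vigilscore")

_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _num8(v: float) -> str:
    """Shortest decimal form of ``v`` fitting the 8-char EDF numeric fields."""
    for prec in range(8, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot represent {v} in 8 characters")


def _record_duration(fs: float) -> float:
    for d in (1, 2, 5, 10):
        if abs(fs * d - round(fs * d)) < 1e-6:
            return float(d)
    raise ValueError(f"no EDF record duration in (1,2,5,10) s gives integer samples at fs={fs}")


def write_edf(path, rec: Recording) -> None:
    """Write the recording as 16-bit EDF; trailing samples beyond the last
    whole data record are dropped (and logged)."""
    dur = _record_duration(rec.fs)
    spr = int(round(rec.fs * dur))  # samples per record per channel
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record")
    dropped = rec.n_samples - n_rec * spr
    if dropped:
        logger.info("write_edf: dropping %d trailing samples (partial record)", dropped)

    n_ch = len(rec.channels)
    phys_min, phys_max, scaled = [], [], []
    for row in rec.signal:
        lo, hi = float(np.min(row)), float(np.max(row))
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (hi - lo) / (2 * _DIG_MAX)
        scaled.append(np.round((row - (hi + lo) / 2) / gain).astype("<i2"))

    start: datetime = rec.start_time
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X", 80),  # patient id
            _ascii("Startdate X", 80),  # recording id
            _ascii(start.strftime("%d.%m.%y"), 8),
            _ascii(start.strftime("%H.%M.%S"), 8),
            _ascii(256 * (n_ch + 1), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(f"{dur:g}", 8),
            _ascii(n_ch, 4),
        ]
    )
    labels = [f"{ch.role} {ch.name}" for ch in rec.channels]
    per_signal = b"".join(
        [
            b"".join(_ascii(lab, 16) for lab in labels),
            b"".join(_ascii(ch.site or "screw electrode", 80) for ch in rec.channels),
            b"".join(_ascii("uV", 8) for _ in rec.channels),
            b"".join(_ascii(_num8(lo), 8) for lo in phys_min),
            b"".join(_ascii(_num8(hi), 8) for hi in phys_max),
            b"".join(_ascii(-_DIG_MAX, 8) for _ in rec.channels),
            b"".join(_ascii(_DIG_MAX, 8) for _ in rec.channels),
            b"".join(_ascii("", 80) for _ in rec.channels),
            b"".join(_ascii(spr, 8) for _ in rec.channels),
            b"".join(_ascii("", 32) for _ in rec.channels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(scaled[ch][r * spr : (r + 1) * spr].tobytes())
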