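"""In-memory representation of a multi-channel electrophysiology recording."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from fractions import Fraction

import numpy as np
from scipy import signal as sps

ROLES = ("EEG", "EMG", "REF")


@dataclass(frozen=True)
class ChannelMeta:
    """Name, role and anatomical site of one channel."""

    name: str
    role: str = "EEG"
    site: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"channel role must be one of {ROLES}, got {self.role!r}")


@dataclass
class Recording:
    """A channels x samples signal matrix with sampling rate and channel roles.

    Amplitudes are in arbitrary units (nominally microvolt). All channels
    share one sampling rate and length; at least one channel must carry the
    EEG role, since the scoring rules read a cortical channel.
    """

    signal: np.ndarray
    fs: float
    channels: list[ChannelMeta]
    start_time: datetime = field(default_factory=lambda: datetime(2000, 1, 1, 9, 0))

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.signal.shape[0]} signal rows but {len(self.channels)} channel entries"
            )
        if not any(ch.role == "EEG" for ch in self.channels):
            raise ValueError("recording needs at least one EEG-role channel")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def pick(self, role: str) -> np.ndarray:
        """Rows of ``signal`` whose channel carries ``role``."""
        idx = [i for i, ch in enumerate(self.channels) if ch.role == role]
        return self.signal[idx]

    def channel_names(self, role: str | None = None) -> list[str]:
        return [ch.name for ch in self.channels if role is None or ch.role == role]


def resample(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias filtered polyphase downsampling to ``target_fs``.

    Duration is preserved to within one output sample. Upsampling is refused:
    the downsampled copy exists to make scoring cheaper, never to fabricate
    bandwidth.
    """
    if target_fs > rec.fs:
        raise ValueError(f"cannot upsample {rec.fs} Hz to {target_fs} Hz")
    if target_fs == rec.fs:
        return Recording(rec.signal.copy(), rec.fs, list(rec.channels), rec.start_time)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.signal, ratio.numerator, ratio.denominator, axis=1)
    actual_fs = rec.fs * ratio.numerator / ratio.denominator
    n_expected = int(round(rec.n_samples * target_fs / rec.fs))
    if abs(out.shape[1] - n_expected) > 1:
        out = out[:, :n_expected]
    return Recording(out, actual_fs, list(rec.channels), rec.start_time)
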