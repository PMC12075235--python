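"""Scoring configuration.

The frequency rules that define the seven vigilance states are fixed, but
noise bounds vary between recordings and are set (or overridden) per run,
mirroring how the scoring is adjusted manually in practice. Every value here
can be loaded from a TOML file and overridden by a CLI flag.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path

logger = logging.getLogger("vigilscore")


@dataclass
class ScoringConfig:
    """Tunable parameters of the scoring pipeline.

    Parameters
    ----------
    epoch_len : float
        Epoch length in seconds (default 1 s; 0.5 and 5 s are also in
        routine use).
    target_fs : float
        Sampling rate (Hz) of the downsampled scoring copy.
    noise_low, noise_high : float or None
        Absolute bounds on per-epoch total power (0.5-70 Hz, a.u.); epochs
        outside the bounds are labeled noise. ``None`` means derive the bound
        from the recording (1e-3x / 1e3x the median per-epoch total power).
    nrem_hi_ratio, nrem_lo_ratio : float
        Cutoffs of the low/high band power ratio that grade non-REM sleep:
        r > hi -> nREM1 (slow-wave), lo < r <= hi -> nREM2, r <= lo -> nREM3.
    seed : int
        Seed for any stochastic step downstream of scoring.
    use_emg : bool
        Gate awake vs sleep with the EMG change-point segmentation when EMG
        channels are present.
    """

    epoch_len: float = 1.0
    target_fs: float = 256.0
    noise_low: float | None = None
    noise_high: float | None = None
    nrem_hi_ratio: float = 20.0
    nrem_lo_ratio: float = 10.0
    seed: int = 0
    use_emg: bool = True
    lights_off_hour: int = 14  # 12 h/12 h cycle, lights off at 14:00
    cp_penalty: float | None = None  # None -> 3*log(n)*var(envelope)
    min_segment_s: float = 10.0

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if self.nrem_lo_ratio >= self.nrem_hi_ratio:
            raise ValueError("nrem_lo_ratio must be < nrem_hi_ratio")
        if (
            self.noise_low is not None
            and self.noise_high is not None
            and not self.noise_low < self.noise_high
        ):
            raise ValueError("noise_low must be < noise_high")


def load_config(path: str | Path | None = None, **overrides) -> ScoringConfig:
    """Build a :class:`ScoringConfig` from an optional TOML file plus overrides.

    Overrides win over file values; both are logged because noise bounds and
    manual adjustments must stay auditable.
    """
    values: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            loaded = tomllib.load(fh)
        known = {f.name for f in fields(ScoringConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    for key, val in overrides.items():
        if val is None:
            continue
        if key in values and values[key] != val:
            logger.info("config override: %s=%r (file had %r)", key, val, values[key])
        values[key] = val
    cfg = ScoringConfig(**values)
    if cfg.noise_low is not None or cfg.noise_high is not None:
        logger.info(
            "manual noise bounds in effect: low=%r high=%r",
            cfg.noise_low,
            cfg.noise_high,
        )
    return cfg
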