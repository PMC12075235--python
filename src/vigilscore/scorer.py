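"""The seven-state rule engine.

Each epoch gets exactly one ASCII label from its FFT power profile plus the
EMG-derived macro state (tense = awake, relaxed = asleep):

==========  =====  =========================================================
state       label  rule (summed band powers, half-open bands)
==========  =====  =========================================================
a1          a      max of the three awake bands is 0.2-3 Hz (delta)
a2          b      max is 3.2-6 Hz (theta)
a3          c      max is 6.2-12 Hz (alpha; resting state)
REM         l      P[6,10) > P[0.2,6)
nREM1       m      r = P[0.2,12)/P[20,24) > 20   (slow-wave sleep)
nREM2       n      10 < r <= 20
nREM3       o      r <= 10                        (spindle-rich)
noise       N      total power outside [noise_low, noise_high]
unscored    U      development only; never emitted by the scorer
==========  =====  =========================================================

Precedence is noise -> macro gate -> (awake argmax | REM test -> nREM
ladder). REM is tested before the nREM ladder because a REM epoch can also
satisfy r > 10. All sub-rules are ratios or argmaxes, so rescaling an epoch
never changes its sub-label; only the noise test sees absolute power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScoringConfig
from .recording import Recording, resample
from .spectra import EpochSpectrum, band_power, epoch_spectra, segment_epochs

logger = logging.getLogger("vigilscore")

#: label characters in canonical order (scoring labels; 'U' excluded).
SCORING_LABELS = "abclmnoN"
ALPHABET = SCORING_LABELS + "U"

LABEL_MEANING = {
    "a": "a1",
    "b": "a2",
    "c": "a3",
    "l": "REM",
    "m": "nREM1",
    "n": "nREM2",
    "o": "nREM3",
    "N": "noise",
    "U": "unscored",
}
MEANING_LABEL = {v: k for k, v in LABEL_MEANING.items()}

TENSE, RELAXED = "tense", "relaxed"


@dataclass(frozen=True)
class RuleThresholds:
    """Band edges and ratio cutoffs of the fixed frequency profiles.

    The bands are fixed by definition; only the noise bounds vary between
    recordings and are adjusted per run.
    """

    awake_bands: tuple = ((0.2, 3.0), (3.2, 6.0), (6.2, 12.0))
    rem_num: tuple = (6.0, 10.0)
    rem_den: tuple = (0.2, 6.0)
    nrem_num: tuple = (0.2, 12.0)
    nrem_den: tuple = (20.0, 24.0)
    hi_ratio: float = 20.0
    lo_ratio: float = 10.0
    noise_band: tuple = (0.5, 70.0)
    noise_low: float = 0.0
    noise_high: float = np.inf


@dataclass
class LabelSequence:
    """One character per epoch over the 9-letter alphabet."""

    labels: str
    epoch_len: float

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(ALPHABET)
        if bad:
            raise ValueError(f"labels outside alphabet {ALPHABET!r}: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


def is_noise(sp: EpochSpectrum, th: RuleThresholds) -> bool:
    """True when total power is too big or too low for any state, or non-finite."""
    if not np.all(np.isfinite(sp.power)):
        return True
    total = band_power(sp, *th.noise_band).value
    return bool(total < th.noise_low or total > th.noise_high)


def classify_awake(sp: EpochSpectrum, th: RuleThresholds) -> str:
    """Argmax over the delta/theta/alpha awake band sums -> a1/a2/a3.

    Ties go to the higher band (a3 over a2 over a1): dominance of the faster
    rhythm is the stronger claim about an awake cortex.
    """
    sums = [band_power(sp, lo, hi).value for lo, hi in th.awake_bands]
    # scan from the alpha band down so the higher band wins exact ties
    best = max(range(len(sums)), key=lambda i: (sums[i], i))
    return "abc"[best]


def classify_sleep(sp: EpochSpectrum, th: RuleThresholds) -> str:
    """REM test first, then the non-REM depth ladder on r = low/high power."""
    if band_power(sp, *th.rem_num).value > band_power(sp, *th.rem_den).value:
        return "l"
    num = band_power(sp, *th.nrem_num).value
    den = band_power(sp, *th.nrem_den).value
    r = np.inf if den == 0 else num / den
    if r > th.hi_ratio:
        return "m"
    if r > th.lo_ratio:
        return "n"
    return "o"


def score_epoch(sp: EpochSpectrum, macro_state: str, th: RuleThresholds) -> str:
    """Label one epoch: noise check first, then the macro-gated sub-rules."""
    if is_noise(sp, th):
        return "N"
    if macro_state == TENSE:
        return classify_awake(sp, th)
    if macro_state == RELAXED:
        return classify_sleep(sp, th)
    raise ValueError(f"macro_state must be {TENSE!r} or {RELAXED!r}, got {macro_state!r}")


def _default_noise_bounds(spectra, th: RuleThresholds) -> tuple[float, float]:
    """1e-3x / 1e3x the median per-epoch total power, used when not set manually."""
    totals = np.array([band_power(sp, *th.noise_band).value for sp in spectra])
    med = float(np.median(totals[np.isfinite(totals)]))
    if med <= 0:
        return 0.0, np.inf
    return 1e-3 * med, 1e3 * med


def _macro_states_from_power(spectra, th: RuleThresholds) -> list[str]:
    """EMG-free fallback: split epochs on log total power (sleep is the
    high-power cluster in cortical recordings). The REM/a2 ambiguity is
    resolved toward awake by construction of this gate; a documented
    limitation, since muscle tone is the real separator."""
    totals = np.array([band_power(sp, *th.noise_band).value for sp in spectra])
    logp = np.log(np.clip(totals, 1e-300, None))
    lo, hi = logp.min(), logp.max()
    if hi - lo < 1e-12:
        return [TENSE] * len(spectra)
    # two-means on the log powers
    c0, c1 = lo, hi
    for _ in range(50):
        assign = np.abs(logp - c0) <= np.abs(logp - c1)
        if assign.all() or (~assign).all():
            break
        n0, n1 = logp[assign].mean(), logp[~assign].mean()
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    thresh = (c0 + c1) / 2
    return [RELAXED if p > thresh else TENSE for p in logp]


def thresholds_from_config(cfg: ScoringConfig) -> RuleThresholds:
    return RuleThresholds(
        hi_ratio=cfg.nrem_hi_ratio,
        lo_ratio=cfg.nrem_lo_ratio,
        noise_low=cfg.noise_low if cfg.noise_low is not None else 0.0,
        noise_high=cfg.noise_high if cfg.noise_high is not None else np.inf,
    )


def score_recording(
    rec: Recording,
    cfg: ScoringConfig | None = None,
    return_diagnostics: bool = False,
):
    """Run the full pipeline: downsample, EMG gate, segment, score per epoch.

    Returns a :class:`LabelSequence`, plus a per-epoch diagnostic
    ``DataFrame`` (band sums, ratio, macro state, label) when
    ``return_diagnostics`` is set. A failed epoch becomes noise ('N'),
    never unscored ('U').
    """
    from .emg import detect_tone_changepoints, emg_summary  # local: avoid cycle

    cfg = cfg or ScoringConfig()
    th = thresholds_from_config(cfg)

    work = resample(rec, cfg.target_fs) if cfg.target_fs < rec.fs else rec
    grid = segment_epochs(work, cfg.epoch_len)
    eeg_idx = next(i for i, ch in enumerate(work.channels) if ch.role == "EEG")
    spectra = epoch_spectra(work, grid, channel=eeg_idx)

    if cfg.noise_low is None or cfg.noise_high is None:
        auto_lo, auto_hi = _default_noise_bounds(spectra, th)
        th = RuleThresholds(
            hi_ratio=th.hi_ratio,
            lo_ratio=th.lo_ratio,
            noise_low=cfg.noise_low if cfg.noise_low is not None else auto_lo,
            noise_high=cfg.noise_high if cfg.noise_high is not None else auto_hi,
        )
        logger.info(
            "noise bounds in use: low=%.4g high=%.4g (auto from median power)",
            th.noise_low,
            th.noise_high,
        )

    emg = work.pick("EMG")
    if cfg.use_emg and emg.shape[0] > 0:
        env = emg_summary(emg, work.fs, window_len=min(1.0, cfg.epoch_len))
        segs = detect_tone_changepoints(
            env, penalty=cfg.cp_penalty, min_segment_s=cfg.min_segment_s
        )
        mids = (np.arange(grid.n_epochs) + 0.5) * cfg.epoch_len
        macro = [segs.state_at(t) for t in mids]
    else:
        if cfg.use_emg:
            logger.warning("no EMG channel: falling back to total-power macro gate")
        macro = _macro_states_from_power(spectra, th)

    labels = []
    for sp, ms in zip(spectra, macro):
        try:
            labels.append(score_epoch(sp, ms, th))
        except Exception:  # noqa: BLE001 - any per-epoch failure is noise
            labels.append("N")
    seq = LabelSequence(labels="".join(labels), epoch_len=cfg.epoch_len)

    if not return_diagnostics:
        return seq
    rows = []
    for i, (sp, ms, lab) in enumerate(zip(spectra, macro, labels)):
        bands = {
            f"P[{lo},{hi})": band_power(sp, lo, hi).value
            for lo, hi in (*th.awake_bands, th.rem_num, th.rem_den, th.nrem_num, th.nrem_den)
        }
        den = bands[f"P[{th.nrem_den[0]},{th.nrem_den[1]})"]
        num = bands[f"P[{th.nrem_num[0]},{th.nrem_num[1]})"]
        rows.append(
            {
                "epoch": i,
                "macro": ms,
                **bands,
                "r": np.inf if den == 0 else num / den,
                "label": lab,
            }
        )
    return seq, pd.DataFrame(rows)
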