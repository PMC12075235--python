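"""EMG-driven macro gate: tense (awake) vs relaxed (asleep).

Muscle tone in the neck EMG separates wakefulness from sleep: the tone is
high while awake (including quiet rest) and low throughout sleep. We reduce
the EMG to a per-window summed-power envelope, find mean-shift change points
with a penalized exact segmentation (PELT, L2 cost), and assign each segment
tense or relaxed by a two-class threshold on the segment means. Detected
transitions can be corrected through manual overrides, which are logged;
noise makes automatic transition detection fallible, so a visual check of
the transitions is part of the intended workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .scorer import RELAXED, TENSE

logger = logging.getLogger("vigilscore")

_HP_CUTOFF_HZ = 10.0  # high-pass edge removing ECG/movement drift from EMG


@dataclass
class ToneEnvelope:
    """Summed rectified EMG power per window (a.u.)."""

    times: np.ndarray  # window centers, s
    values: np.ndarray
    window_len: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("envelope times must be strictly increasing")


@dataclass
class ToneSegments:
    """Alternating tense/relaxed intervals tiling the recording."""

    segments: list[tuple[float, float, str]]
    provenance: str = "auto"

    def __post_init__(self) -> None:
        for start, end, state in self.segments:
            if end <= start:
                raise ValueError(f"zero/negative-length segment [{start}, {end})")
            if state not in (TENSE, RELAXED):
                raise ValueError(f"unknown macro state {state!r}")
        for (_, e0, s0), (b1, _, s1) in zip(self.segments, self.segments[1:]):
            if abs(e0 - b1) > 1e-9:
                raise ValueError("segments must tile the recording without gaps")
            if s0 == s1:
                raise ValueError("adjacent segments must alternate states")

    @property
    def duration(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]

    def state_at(self, t: float) -> str:
        """Macro state at time ``t`` (clamped to the tiled range)."""
        for start, end, state in self.segments:
            if start <= t < end:
                return state
        return self.segments[-1][2] if t >= self.segments[-1][1] else self.segments[0][2]


def emg_summary(emg: np.ndarray, fs: float, window_len: float = 1.0) -> ToneEnvelope:
    """Per-window sum of squared, high-pass-filtered EMG across channels."""
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    if emg.shape[0] == 0:
        raise ValueError("no EMG channel available")
    if window_len < 0.5:
        raise ValueError("envelope window must be at least 0.5 s")
    if fs > 2 * _HP_CUTOFF_HZ:
        sos = sps.butter(4, _HP_CUTOFF_HZ, btype="highpass", fs=fs, output="sos")
        emg = sps.sosfiltfilt(sos, emg, axis=1)
    spw = int(round(window_len * fs))
    n_win = emg.shape[1] // spw
    sq = (emg[:, : n_win * spw] ** 2).reshape(emg.shape[0], n_win, spw)
    values = sq.sum(axis=(0, 2))
    times = (np.arange(n_win) + 0.5) * window_len
    return ToneEnvelope(times=times, values=values, window_len=window_len)


def _pelt_mean_shift(x: np.ndarray, penalty: float) -> list[int]:
    """Exact penalized segmentation of a 1-D series under an L2 cost.

    Returns the sorted interior change-point indices (a change point at i
    splits x[:i] from x[i:]). Linear-ish time through PELT pruning.
    """
    n = x.size
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(a: np.ndarray, b: int) -> np.ndarray:
        length = b - a
        return (s2[b] - s2[a]) - (s1[b] - s1[a]) ** 2 / length

    F = np.empty(n + 1)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    cand = np.array([0])
    for t in range(1, n + 1):
        costs = F[cand] + seg_cost(cand, t) + penalty
        best = int(np.argmin(costs))
        F[t] = costs[best]
        last[t] = cand[best]
        keep = F[cand] + seg_cost(cand, t) <= F[t]
        cand = np.append(cand[keep], t)
    cps = []
    t = n
    while t > 0:
        if last[t] != 0:
            cps.append(int(last[t]))
        t = last[t]
    return sorted(cps)


def detect_tone_changepoints(
    env: ToneEnvelope,
    penalty: float | None = None,
    min_segment_s: float = 10.0,
    noise_floor: float | None = None,
) -> ToneSegments:
    """Segment the tone envelope into tense/relaxed intervals.

    Mean-shift change points (PELT, L2 cost; default penalty
    ``3 * log(n) * var(env)``, which makes detection invariant to positive
    rescaling of the envelope). Segments shorter than ``min_segment_s`` are
    merged into the neighbor with the closer mean, guarding against brief
    noise-driven splits. Each surviving segment is tense when its mean
    exceeds the midpoint of the two segment-mean clusters; if no change point
    is found the single segment is compared against ``noise_floor`` (tense
    above it), or labeled tense whenever its mean is positive if no floor is
    given.
    """
    x = env.values.astype(float)
    n = x.size
    if n < 4:
        raise ValueError("envelope must have at least 4 windows")
    if penalty is None:
        penalty = 3.0 * np.log(n) * float(np.var(x))
    if penalty <= 0:  # constant envelope
        cps = []
    else:
        cps = _pelt_mean_shift(x, penalty)

    bounds = [0, *cps, n]
    # merge segments shorter than the minimum duration into the closer-mean neighbor
    min_win = max(1, int(round(min_segment_s / env.window_len)))
    changed = True
    while changed and len(bounds) > 2:
        changed = False
        for i in range(len(bounds) - 1):
            if bounds[i + 1] - bounds[i] >= min_win:
                continue
            seg_mean = x[bounds[i] : bounds[i + 1]].mean()
            left = x[bounds[i - 1] : bounds[i]].mean() if i > 0 else None
            right = x[bounds[i + 1] : bounds[i + 2]].mean() if i + 2 < len(bounds) else None
            if left is None and right is None:
                break
            if right is None or (left is not None and abs(seg_mean - left) <= abs(seg_mean - right)):
                del bounds[i]  # absorb into left neighbor
            else:
                del bounds[i + 1]  # absorb into right neighbor
            changed = True
            break

    means = np.array([x[a:b].mean() for a, b in zip(bounds, bounds[1:])])
    # two-means on the segment means; threshold at the cluster midpoint
    c0, c1 = means.min(), means.max()
    for _ in range(100):
        lower = np.abs(means - c0) <= np.abs(means - c1)
        n0 = means[lower].mean() if lower.any() else c0
        n1 = means[~lower].mean() if (~lower).any() else c1
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    # physiological tone contrast is >= 2x in amplitude, so >= 4x in summed
    # power; clusters closer than 2x are one level, not a wake/sleep split
    if means.size == 1 or c1 < 2.0 * c0:
        floor = noise_floor if noise_floor is not None else 0.0
        level = means.mean()
        if noise_floor is None:
            logger.warning(
                "tone envelope has a single level; assuming %s (no noise floor given)",
                TENSE if level > floor else RELAXED,
            )
        states = [TENSE if level > floor else RELAXED for _ in means]
    else:
        thresh = (c0 + c1) / 2
        states = [TENSE if m > thresh else RELAXED for m in means]

    # convert window indices to seconds; collapse adjacent same-state segments
    t0 = env.times[0] - env.window_len / 2
    edges = [t0 + b * env.window_len for b in bounds]
    segs: list[tuple[float, float, str]] = []
    for a, b, st in zip(edges, edges[1:], states):
        if segs and segs[-1][2] == st:
            segs[-1] = (segs[-1][0], b, st)
        else:
            segs.append((a, b, st))
    return ToneSegments(segments=segs, provenance="auto")


def apply_manual_overrides(
    seg: ToneSegments, edits: list[tuple[float, str]]
) -> ToneSegments:
    """Apply boundary edits from the visual transition check.

    Each edit ``(t, state)`` inserts a boundary at ``t`` and sets the macro
    state from ``t`` up to the next boundary of the *original* segmentation.
    Shifting a boundary is therefore expressed as two edits (one restating
    the old state up to the new boundary, one starting the new state there).
    All edits are logged verbatim.
    """
    if not edits:
        return seg
    start0, end0 = seg.segments[0][0], seg.segments[-1][1]
    times = [t for t, _ in edits]
    if len(set(times)) != len(times):
        raise ValueError("duplicate override times would create zero-length segments")
    for t, state in edits:
        if not start0 <= t <= end0:
            raise ValueError(f"override time {t} s outside recording [{start0}, {end0}] s")
        if state not in (TENSE, RELAXED):
            raise ValueError(f"unknown macro state {state!r}")
        logger.info("manual override: t=%.3f s -> %s", t, state)

    orig_bounds = [seg.segments[0][0]] + [e for _, e, _ in seg.segments]
    all_bounds = sorted(set(orig_bounds) | {t for t, _ in edits})
    piece_state = {a: seg.state_at(a) for a in all_bounds[:-1]}
    for t, state in sorted(edits):
        nxt = next((b for b in orig_bounds if b > t), end0)
        for a in all_bounds[:-1]:
            if t <= a < nxt:
                piece_state[a] = state

    segs: list[tuple[float, float, str]] = []
    for a, b in zip(all_bounds, all_bounds[1:]):
        st = piece_state[a]
        if segs and segs[-1][2] == st:
            segs[-1] = (segs[-1][0], b, st)
        else:
            segs.append((a, b, st))
    return ToneSegments(segments=segs, provenance="manual")
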