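"""Summaries computed from label sequences alone.

Proportions of time per state, the 64 ordered consecutive-epoch label pairs
(within-state persistence on the diagonal, transitions off it), hourly and
cumulative distributions over the light/dark cycle, the coefficient of
variance, per-subject correlograms with multiplicity-adjusted significance,
and the Bonferroni-corrected difference-wave test used to compare
per-frequency curves between groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .scorer import SCORING_LABELS, LabelSequence


def state_proportions(labels: LabelSequence) -> pd.Series:
    """Fraction of epochs per scoring label; sums to 1."""
    if labels.n_epochs == 0:
        raise ValueError("empty label sequence")
    counts = pd.Series(
        [labels.labels.count(c) for c in SCORING_LABELS],
        index=list(SCORING_LABELS),
        dtype=float,
    )
    return counts / labels.n_epochs


def transition_pair_counts(labels: LabelSequence, exclude_noise: bool = False) -> pd.DataFrame:
    """8x8 matrix of ordered consecutive-epoch pairs (64 cells).

    Before exclusion, the total count equals ``n_epochs - 1``. With
    ``exclude_noise`` any pair containing 'N' is zeroed, matching how
    noise pairs are left out of transition displays.
    """
    if labels.n_epochs < 2:
        raise ValueError("need at least 2 epochs for pairs")
    mat = pd.DataFrame(
        0, index=list(SCORING_LABELS), columns=list(SCORING_LABELS), dtype=int
    )
    for a, b in zip(labels.labels, labels.labels[1:]):
        mat.loc[a, b] += 1
    if exclude_noise:
        mat.loc["N", :] = 0
        mat.loc[:, "N"] = 0
    return mat


def hourly_distribution(
    labels: LabelSequence,
    start_time: datetime,
    lights_off_hour: int = 14,
) -> pd.DataFrame:
    """Per wall-clock hour label counts, with a light/dark phase column.

    Rows are hour bins from the recording start (the first bin may be
    partial); row sums equal the epochs falling in that hour.
    """
    times = [
        start_time + timedelta(seconds=(i + 0.5) * labels.epoch_len)
        for i in range(labels.n_epochs)
    ]
    df = pd.DataFrame({"label": list(labels.labels), "time": times})
    df["hour_bin"] = df["time"].apply(lambda t: t.replace(minute=0, second=0, microsecond=0))
    table = (
        df.groupby(["hour_bin", "label"]).size().unstack(fill_value=0)
        .reindex(columns=list(SCORING_LABELS), fill_value=0)
    )
    # 12 h/12 h cycle: dark phase runs for 12 h from lights-off
    hours = table.index.hour
    table["phase"] = np.where(
        (hours - lights_off_hour) % 24 < 12, "dark", "light"
    )
    return table


def cumulative_state_curve(labels: LabelSequence, state: str) -> np.ndarray:
    """Cumulative epoch count of ``state``, one step per hour (nondecreasing).

    The final value equals the total number of epochs of that state.
    """
    epochs_per_hour = int(round(3600.0 / labels.epoch_len))
    flags = np.array([lab == state for lab in labels.labels], dtype=int)
    n_hours = int(np.ceil(labels.n_epochs / epochs_per_hour))
    out = np.empty(n_hours, dtype=int)
    for h in range(n_hours):
        out[h] = flags[: (h + 1) * epochs_per_hour].sum()
    return out


def coefficient_of_variance(x: np.ndarray) -> float:
    """Sample standard deviation (n-1) divided by the mean."""
    x = np.asarray(x, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean data")
    return float(x.std(ddof=1) / mean)


@dataclass
class Correlogram:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # Bonferroni-adjusted p < 0.05, off-diagonal


def state_correlogram(table: pd.DataFrame, level: float = 0.05) -> Correlogram:
    """Pairwise Pearson correlations between per-subject columns.

    ``table`` holds one row per subject and one column per variable (state
    proportions plus covariates such as genotype). Significance is Bonferroni
    adjusted over the unique off-diagonal cells; pairs involving a constant
    column are undefined and masked.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 subjects for a correlogram")
    cols = list(table.columns)
    k = len(cols)
    n_tests = k * (k - 1) // 2
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = table[cols[i]], table[cols[j]]
            if xi.std(ddof=1) == 0 or xj.std(ddof=1) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(xi, xj)
                rij, pij = res.statistic, res.pvalue
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            s = bool(np.isfinite(pij) and pij * n_tests < level)
            sig.iloc[i, j] = sig.iloc[j, i] = s
    return Correlogram(variables=cols, r=r, p=p, significant=sig)


def difference_wave_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    level: float = 0.95,
) -> np.ndarray:
    """Frequencies where the Bonferroni-corrected CI of mean(A)-mean(B)
    excludes zero.

    ``curves_a``/``curves_b`` are subjects x frequencies on a shared grid.
    The per-frequency confidence interval is a Welch t-interval on the
    difference of group means, corrected across the number of frequencies;
    the returned boolean mask marks significant frequencies.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("curves must share one frequency grid")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 subjects per group for a CI")
    m = a.shape[1]
    diff = a.mean(axis=0) - b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1) / na, b.var(axis=0, ddof=1) / nb
    se = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    df = np.where(np.isfinite(df), df, na + nb - 2)
    alpha = (1.0 - level) / m  # Bonferroni over frequencies
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    half = tcrit * se
    return (diff - half > 0) | (diff + half < 0)
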