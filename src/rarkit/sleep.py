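"""Actigraphic "sleep" estimation from zero-activity runs.

A "sleep" bout (enquoted throughout: it is an estimate, not polysomnographic
sleep) is a maximal run of epochs with exactly zero counts lasting at least
four minutes.  Bouts may cross midnight and are attributed wholly to the day
of onset, keeping durations faithful for the survival curve.

The summary reports mean total daily "sleep" minutes, mean bouts per day, a
bout-duration survival function S(d) = P(duration >= d), and a 24-bin
histogram of bout onsets by clock hour — the quantities used to compare
sleep quantity, fragmentation and timing across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config, SleepConfig
from .io import DayMatrix


@dataclass
class SleepBout:
    onset: pd.Timestamp
    duration_min: float
    onset_day_index: int
    onset_hour: float  # clock hour in [0, 24)


@dataclass
class SleepSummary:
    bouts: list[SleepBout]
    days: int
    total_daily_sleep_min: float
    bouts_per_day: float
    survival: dict[float, float] = field(default_factory=dict)  # d -> P(dur >= d)
    onset_hist: np.ndarray = field(default_factory=lambda: np.zeros(24, dtype=int))


def detect_sleep_bouts(dm: DayMatrix, config: Config | None = None) -> list[SleepBout]:
    """Scan the concatenated retained-day series for qualifying zero runs."""
    cfg: SleepConfig = (config or Config()).sleep
    x = dm.flatten()
    is_rest = x <= cfg.zero_tolerance
    if not is_rest.any():
        return []
    # run-length encode via change points
    padded = np.diff(np.concatenate([[0], is_rest.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive
    min_epochs = int(np.ceil(cfg.min_bout_minutes * 60 / dm.epoch_seconds))
    bouts = []
    per_day = dm.epochs_per_day
    for s, e in zip(starts, ends):
        if e - s < min_epochs:
            continue
        duration_min = (e - s) * dm.epoch_seconds / 60.0
        onset = dm.start + pd.Timedelta(seconds=int(s) * dm.epoch_seconds)
        day_idx = int(s // per_day)
        onset_hour = (s % per_day) * dm.epoch_seconds / 3600.0
        bouts.append(SleepBout(onset, duration_min, day_idx, onset_hour))
    return bouts


def summarize_sleep(bouts: list[SleepBout], days: int) -> SleepSummary:
    """Aggregate bouts into daily totals, survival curve and onset histogram."""
    if days < 1:
        raise ValueError("days must be >= 1")
    hist = np.zeros(24, dtype=int)
    for b in bouts:
        hist[int(b.onset_hour) % 24] += 1
    if not bouts:
        return SleepSummary(bouts, days, 0.0, 0.0, {}, hist)
    durations = np.array([b.duration_min for b in bouts])
    survival = {
        float(d): float(np.mean(durations >= d)) for d in np.unique(durations)
    }
    return SleepSummary(
        bouts=bouts,
        days=days,
        total_daily_sleep_min=float(durations.sum() / days),
        bouts_per_day=len(bouts) / days,
        survival=survival,
        onset_hist=hist,
    )


def survival_quantile(summary: SleepSummary, q: float) -> float:
    """Smallest observed duration d with P(duration > d) <= q: e.g. q=0.10
    gives the duration that at least 90% of bouts do not exceed."""
    if not summary.bouts:
        raise ValueError("no bouts")
    durations = np.sort([b.duration_min for b in summary.bouts])
    for d in np.unique(durations):
        if np.mean(durations > d) <= q:
            return float(d)
    return float(durations[-1])  # unreachable: the maximum always qualifies
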