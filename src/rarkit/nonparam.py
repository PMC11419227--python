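"""Nonparametric circadian metrics: intradaily variability and interdaily
stability, computed on hourly activity totals.

IV (intradaily variability) measures rhythm fragmentation as the normalized
mean square of hour-to-hour first differences:

    IV = [N * sum_{i=2..N} (x_i - x_{i-1})^2] / [(N-1) * sum_i (x_i - xbar)^2]

IV is ~0 for a smooth sinusoid, ~2 for white noise, and can approach 4 for
an alternating series.  Differences run over the concatenated chronological
series — they cross midnights but do not wrap around the recording end.

IS (interdaily stability) is the fraction of variance explained by the
average 24 h profile:

    IS = [N * sum_{h=1..24} (xbar_h - xbar)^2] / [24 * sum_i (x_i - xbar)^2]

where xbar_h is the mean over days of the hour-h totals.  IS = 1 for a
perfectly repeating day; i.i.d. noise over m days gives IS ~ 1/m.

Both metrics are invariant to affine rescaling of the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class NonparamMetrics:
    iv: float
    is_: float
    n_hours: int


def intradaily_variability(hourly: np.ndarray) -> float:
    x = np.asarray(hourly, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 hourly values")
    dev = x - x.mean()
    ss = float(dev @ dev)
    if ss == 0:
        raise ValueError("constant series")
    d = np.diff(x)
    return float(n * (d @ d) / ((n - 1) * ss))


def interdaily_stability(hourly: np.ndarray, days: int) -> float:
    x = np.asarray(hourly, dtype=float)
    n = x.size
    if days < 1 or n != 24 * days:
        raise ValueError("hourly length must equal 24 * days")
    if days == 1:
        warnings.warn("IS is uninformative for a single day; returning 1.0", stacklevel=2)
        return 1.0
    dev = x - x.mean()
    ss = float(dev @ dev)
    if ss == 0:
        raise ValueError("constant series")
    hourly_means = x.reshape(days, 24).mean(axis=0)
    num = float(np.sum((hourly_means - x.mean()) ** 2))
    return float(n * num / (24 * ss))
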