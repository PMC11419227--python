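"""Single-component 24 h cosinor regression.

The cosinor model is the linearized fit

    y(t) = M + beta * cos(2*pi*t/24) + gamma * sin(2*pi*t/24)

solved by ordinary least squares on all epochs, with t measured in clock
hours since the first retained midnight.  Reported parameters are the mesor
M (rhythm-adjusted mean), amplitude A = sqrt(beta^2 + gamma^2) (half the
peak-to-trough excursion) and acrophase phi = atan2(gamma, beta) * 24/(2*pi)
mod 24 (clock time of the fitted peak, in hours).

The period is fixed at 24 h and the fit runs at native epoch resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DayMatrix

_OMEGA = 2.0 * np.pi / 24.0


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_h: float  # clock hours in [0, 24)
    rss: float
    n: int

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.acrophase_h < 24.0:
            raise ValueError("acrophase must lie in [0, 24)")


def _clock_hours(dm: DayMatrix) -> np.ndarray:
    """Epoch midpoint-free grid: hours since the first retained midnight,
    one value per epoch, epoch start convention."""
    n = dm.days * dm.epochs_per_day
    return np.arange(n) * (dm.epoch_seconds / 3600.0)


def fit_cosinor(dm: DayMatrix) -> CosinorFit:
    """Closed-form least-squares cosinor fit on the day-aligned epoch series."""
    y = dm.flatten().astype(float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate cosinor: constant signal")
    t = _clock_hours(dm)
    X = np.column_stack([np.ones_like(t), np.cos(_OMEGA * t), np.sin(_OMEGA * t)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, beta, gamma = coef
    amplitude = float(np.hypot(beta, gamma))
    acrophase = float(np.arctan2(gamma, beta) / _OMEGA % 24.0)
    if acrophase >= 24.0:  # tiny negative angles wrap to exactly 24.0
        acrophase = 0.0
    resid = y - X @ coef
    return CosinorFit(float(mesor), amplitude, acrophase, float(resid @ resid), y.size)


def predict_cosinor(fit: CosinorFit, t: float | np.ndarray) -> float | np.ndarray:
    """Fitted mean activity at clock hour(s) ``t``."""
    out = fit.mesor + fit.amplitude * np.cos(_OMEGA * (np.asarray(t) - fit.acrophase_h))
    return float(out) if np.ndim(t) == 0 else out
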