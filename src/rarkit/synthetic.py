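"""Synthetic actigraphy cohorts with the statistical structure the pipeline
assumes, for end-to-end testing without clinical recordings.

Each subject's mean activity follows the sigmoidally transformed cosine used
by the robustness model, with day-to-day phase and amplitude jitter:

    mu_d(t) = max(0, minimum + amp_d * logistic(beta * (cos(2*pi*(t - phi_d)/24) - alpha)))
    phi_d = acrophase + Normal(0, phase_jitter_sd_h)
    amp_d = amplitude * (1 + Normal(0, amplitude_jitter_cv))

Counts are negative-binomial about mu (variance mu + dispersion * mu^2),
because device counts are overdispersed nonnegative integers.  Low-phase
epochs (where the sigmoid factor is below one half) are zeroed with
probability ``zero_inflation_night`` — the zero runs the 4-minute sleep-bout
rule needs arise naturally, which a Gaussian noise model would almost never
produce.  Optional daytime naps are inserted as forced zero runs (rest), so
they are visible to the bout rule by construction; naps per day are Poisson,
nap lengths Normal.

Phase jitter drives interdaily stability down; dispersion and zero inflation
drive intradaily variability up; beta controls squareness and hence the
pseudo-F.  Three presets emulate the qualitative phenotype clusters seen in
epilepsy-with-intellectual-disability actigraphy — A: hypoactive,
hypersomnic, fragmented; B: intermediate; C: hyper-robust, high amplitude —
plus a robust CONTROL preset for case-control contrasts.  Preset values are
chosen to reproduce the *direction* of the published group differences, not
their cohort-specific magnitudes.

Everything is reproducible: a subject is a pure function of (spec, seed),
with integer RNG streams from numpy's PCG64.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CohortManifest, EpochSeries, write_epoch_csv


@dataclass
class PhenotypeSpec:
    name: str
    mesor_floor: float  # "minimum" of the mean curve, counts/epoch
    amplitude: float  # rise above the floor, counts/epoch
    acrophase_h: float
    sigmoid_beta: float
    sigmoid_alpha: float
    noise_dispersion: float  # NB overdispersion: var = mu + disp * mu^2
    zero_inflation_night: float
    nap_rate_per_day: float
    nap_length_min: tuple[float, float]  # (mean, sd) minutes
    phase_jitter_sd_h: float
    amplitude_jitter_cv: float
    days: int = 11
    epoch_seconds: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.acrophase_h < 24:
            raise ValueError("acrophase_h must be in [0, 24)")
        if self.sigmoid_beta <= 0 or not -1 < self.sigmoid_alpha < 1:
            raise ValueError("invalid sigmoid parameters")
        if min(self.mesor_floor, self.amplitude, self.noise_dispersion) < 0:
            raise ValueError("negative curve/noise parameter")
        if not 0 <= self.zero_inflation_night <= 1:
            raise ValueError("zero_inflation_night must be in [0, 1]")
        if self.nap_rate_per_day < 0 or self.phase_jitter_sd_h < 0 or self.amplitude_jitter_cv < 0:
            raise ValueError("negative rate/jitter parameter")
        if self.days < 1 or self.epoch_seconds not in (30, 60):
            raise ValueError("invalid days/epoch_seconds")


@dataclass
class SyntheticSubject:
    series: EpochSeries
    truth: PhenotypeSpec
    day_phases: np.ndarray  # realized phi_d
    day_amplitudes: np.ndarray  # realized amp_d


# Median recording duration in the emulated study was 11 days; preset
# contrasts are directional (see module docstring), with A the weakest and
# most fragmented rhythms and C the most robust.
PRESETS: dict[str, PhenotypeSpec] = {
    "A": PhenotypeSpec(
        name="A", mesor_floor=2.0, amplitude=120.0, acrophase_h=15.0,
        sigmoid_beta=2.0, sigmoid_alpha=0.0, noise_dispersion=2.0,
        zero_inflation_night=0.75, nap_rate_per_day=6.0, nap_length_min=(30.0, 10.0),
        phase_jitter_sd_h=3.0, amplitude_jitter_cv=0.30,
    ),
    "B": PhenotypeSpec(
        name="B", mesor_floor=5.0, amplitude=350.0, acrophase_h=14.5,
        sigmoid_beta=6.0, sigmoid_alpha=0.0, noise_dispersion=1.0,
        zero_inflation_night=0.60, nap_rate_per_day=2.0, nap_length_min=(20.0, 5.0),
        phase_jitter_sd_h=1.0, amplitude_jitter_cv=0.15,
    ),
    "C": PhenotypeSpec(
        name="C", mesor_floor=8.0, amplitude=800.0, acrophase_h=13.5,
        sigmoid_beta=10.0, sigmoid_alpha=0.0, noise_dispersion=0.5,
        zero_inflation_night=0.55, nap_rate_per_day=0.5, nap_length_min=(15.0, 5.0),
        phase_jitter_sd_h=0.3, amplitude_jitter_cv=0.05,
    ),
    "CONTROL": PhenotypeSpec(
        name="CONTROL", mesor_floor=6.0, amplitude=500.0, acrophase_h=14.0,
        sigmoid_beta=8.0, sigmoid_alpha=0.0, noise_dispersion=0.6,
        zero_inflation_night=0.50, nap_rate_per_day=1.0, nap_length_min=(15.0, 5.0),
        phase_jitter_sd_h=0.6, amplitude_jitter_cv=0.08, days=9,
    ),
}

_START = pd.Timestamp("2024-01-01 00:00:00")


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))


def generate_subject(
    spec: PhenotypeSpec, seed: int, subject_id: str | None = None
) -> SyntheticSubject:
    """Simulate one subject's full-day epoch series from a phenotype spec."""
    rng = np.random.default_rng(seed)
    per_day = 86400 // spec.epoch_seconds
    hours = np.arange(per_day) * spec.epoch_seconds / 3600.0
    omega = 2 * np.pi / 24.0

    phis = spec.acrophase_h + rng.normal(0.0, spec.phase_jitter_sd_h, size=spec.days)
    amps = spec.amplitude * (1.0 + rng.normal(0.0, spec.amplitude_jitter_cv, size=spec.days))
    counts = np.empty((spec.days, per_day), dtype=np.int64)
    for d in range(spec.days):
        cosv = np.cos(omega * (hours - phis[d]))
        sig = _logistic(spec.sigmoid_beta * (cosv - spec.sigmoid_alpha))
        mu = np.maximum(0.0, spec.mesor_floor + amps[d] * sig)
        if spec.noise_dispersion > 0:
            r = 1.0 / spec.noise_dispersion
            with np.errstate(divide="ignore"):
                p = r / (r + mu)
            day = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
        else:
            day = rng.poisson(mu)
        # exact zeros in the low phase (rest)
        low = sig < 0.5
        if spec.zero_inflation_night > 0 and low.any():
            zero_mask = low & (rng.random(per_day) < spec.zero_inflation_night)
            day = np.where(zero_mask, 0, day)
        # daytime naps: forced zero runs
        n_naps = rng.poisson(spec.nap_rate_per_day)
        high_idx = np.flatnonzero(~low)
        for _ in range(n_naps):
            if high_idx.size == 0:
                break
            length_min = max(
                spec.epoch_seconds / 60.0,
                rng.normal(spec.nap_length_min[0], spec.nap_length_min[1]),
            )
            n_ep = int(round(length_min * 60 / spec.epoch_seconds))
            start = int(rng.choice(high_idx))
            day[start : start + n_ep] = 0
        counts[d] = day
    sid = subject_id or f"{spec.name}-s{seed}"
    series = EpochSeries(sid, _START, spec.epoch_seconds, counts.reshape(-1))
    return SyntheticSubject(series, spec, phis, amps)


def generate_cohort(
    specs: list[tuple[PhenotypeSpec, int]],
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[CohortManifest | None, list[SyntheticSubject]]:
    """Generate labeled subjects for each (spec, n) block.

    Subject seeds are spawned deterministically from the master seed.  When
    ``out_dir`` is given, per-subject epoch CSVs and a ``manifest.csv`` with
    the true phenotype labels are written there and a manifest is returned.
    """
    subjects: list[SyntheticSubject] = []
    entries: list[tuple[str, str, str]] = []
    child_seeds = iter(np.random.SeedSequence(seed).generate_state(sum(n for _, n in specs)) % (2**31))
    for spec, n in specs:
        if n < 1:
            raise ValueError("n must be >= 1 per phenotype")
        for i in range(n):
            sid = f"{spec.name}-{i:03d}"
            subj = generate_subject(spec, int(next(child_seeds)), subject_id=sid)
            subjects.append(subj)
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                fpath = out / f"{sid}.csv"
                write_epoch_csv(subj.series, fpath)
                entries.append((sid, str(fpath), spec.name))
    manifest = None
    if out_dir is not None:
        manifest = CohortManifest(entries)
        # manifest file uses paths relative to its own directory, so a cohort
        # folder can be moved or compared byte-for-byte across runs
        rel = CohortManifest(
            [(sid, Path(p).name, g) for sid, p, g in entries]
        )
        rel.to_csv(Path(out_dir) / "manifest.csv")
    return manifest, subjects


def preset(name: str, **overrides) -> PhenotypeSpec:
    """A copy of a named preset, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)
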